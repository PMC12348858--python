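# biomass-tradeoff

Analysis pipeline for **above/belowground biomass allocation trade-offs
along precipitation gradients** in grassland surveys, built for the nested
design common in alpine-grassland campaigns: sites along a mean-annual-
precipitation (MAP) gradient, square plots within sites, quadrats within
plots, with aboveground biomass (AGB), belowground biomass (BGB), specific
leaf area (SLA) and species richness measured per quadrat.  It is aimed at
plant/ecosystem ecologists who want the full chain — from a raw quadrat
table (or a calibrated synthetic one) to trade-off values, allometric
verdicts and driver attribution — as tested, scriptable Python.

## The statistics at its core

**Relative benefit.** Each biomass component is min–max scaled across all
quadrats,

    RB = (x_i − x_min) / (x_max − x_min) ∈ [0, 1],

placing AGB and BGB on a common dimensionless scale.

**Trade-off.** A quadrat's allocation imbalance is the root-mean-square
deviation of its two relative benefits from their mean, signed by the
dominant component:

    T = sign(RB_AGB − RB_BGB) · |RB_AGB − RB_BGB| / √2  ∈ [−1/√2, +1/√2].

Positive values mean aboveground allocation dominance, negative values
belowground prioritisation, zero balanced allocation.

**Allometry.** Per precipitation class (<400, 400–500, 500–600, 600–700,
>700 mm/y), log₁₀ AGB is regressed on log₁₀ BGB by standardized major axis
(SMA), b = sign(r)·s_y/s_x, with the Warton slope test of isometry
(H₀: b = 1).  b > 1 means AGB accrues faster than BGB.

**Drivers.** Pearson/Mantel screening, random-forest permutation
importance (%IncMSE = mean relative increase in out-of-bag MSE when a
predictor is permuted, ×100), and a piecewise path model: each structural
equation fit by OLS on z-scored variables (standardized β), global
topology judged by Fisher's C = −2Σln pᵢ over the d-separation basis set,
plus RMSEA/CFI from the equivalent covariance fit.

Because field campaigns of this kind rarely deposit raw tables, the
package ships a **calibrated synthetic survey generator**: site MAP
uniform on 262–772 mm/y, standardized MAP driving log SLA / log AGB /
log BGB with standardized coefficients 0.28 / 0.53 / 0.60, class-wise
AGB–BGB allometric slopes (isometric only at 600–700 mm/y), a richness
hump at intermediate MAP, and 63 sites × 3 plots × 5 quadrats = 945 rows
by default.  Every downstream stage is tested against the values the data
were generated with.

## Worked example

```python
from biomass_tradeoff import RunConfig, run_pipeline
run_pipeline(RunConfig(output_dir="demo", seeds={"generator": 0, "rf": 0, "mantel": 0}))
```

`demo/allometry.csv` (SMA slope per class, isometry verdict):

```
precip_class   n  slope  ci_lo  ci_hi    r2  isometry_p    verdict
        <400 240  1.182  1.124  1.243 0.843       0.000 faster-AGB
     400-500 180  1.194  1.127  1.265 0.848       0.000 faster-AGB
     500-600 180  1.077  1.016  1.142 0.844       0.013 faster-AGB
     600-700 210  0.991  0.940  1.045 0.852       0.738  isometric
        >700 135  1.164  1.091  1.241 0.858       0.000 faster-AGB
```

AGB outpaces BGB everywhere except the 600–700 mm/y class, where growth is
isometric.  `demo/tradeoff_classes.csv` shows the same story in trade-off
space — positive class means (aboveground dominance) everywhere, except a
mean indistinguishable from zero (balanced allocation) at 600–700 mm/y:

```
precip_class  mean_tradeoff  p_vs_zero   direction
        <400         0.0243     0.0000 aboveground
     400-500         0.0228     0.0000 aboveground
     500-600         0.0202     0.0000 aboveground
     600-700         0.0067     0.0718    balanced
        >700         0.0111     0.0160 aboveground
```

`demo/drivers.json` holds the attribution stage.  The path model recovers
the generating standardized coefficients (MAP→SLA 0.261, MAP→AGB 0.519,
MAP→BGB 0.594) with non-significant direct MAP→trade-off (β = 0.007,
p = 0.70) and SLA→trade-off (β = −0.015, p = 0.31) paths, and the topology
is accepted globally (Fisher's C = 3.13, df = 4, p = 0.54; RMSEA = 0.00,
CFI = 1.00).  The importance forest puts the biomass components first
(%IncMSE: AGB 112.0, BGB 66.7, MAP 17.9, richness 4.6, SLA −0.2) — with
the trade-off computed from the quadrat's own AGB and BGB, permuting those
columns necessarily hurts most, so MAP's influence shows up through the
path model's indirect effects rather than the forest ranking.

The same stages are available as CLI subcommands:

```bash
biomass-tradeoff simulate --seed 0 --out survey.csv
biomass-tradeoff validate --in survey.csv
biomass-tradeoff tradeoff --in survey.csv --out tradeoff.csv
biomass-tradeoff allometry --in survey.csv --out fits.csv
biomass-tradeoff run --seed 0 --out demo
biomass-tradeoff figures --bundle demo
```

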