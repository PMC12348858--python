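"""Synthetic hierarchical grassland survey generator.

Emulates a nested alpine-grassland sampling design — sites along a
precipitation gradient, square plots within sites, quadrats within plots —
and produces quadrat tables with a known, configurable statistical
structure so that every downstream stage (trade-off statistic, allometry,
group comparisons, driver attribution) can be tested against the values it
was generated with.

Generating model
----------------
Site mean annual precipitation (MAP) is uniform over ``map_range``; its
standardized value ``z`` is the single climatic driver.  Log specific leaf
area and log aboveground biomass follow

    logSLA* = b_sla * z + noise_sd * sqrt(1 - b_sla^2) * eps
    logAGB* = b_agb * z + noise_sd * sqrt(1 - b_agb^2) * eps

(unit-variance latents at ``noise_sd = 1``), so the population standardized
regression coefficient on z is exactly the configured one.  Log belowground
biomass is built class by class: within each precipitation class its
variance is chosen analytically so the standardized-major-axis slope of
log AGB on log BGB equals the configured class allometric slope in
expectation, part of its within-class variation is aligned with the AGB
residual (``bgb_agb_coupling``), and the between-class mean profile is
rescaled by solving a quadratic so the *global* standardized MAP -> logBGB
coefficient still equals ``beta_map_bgb``.  Biomass is exponentiated from
the log scale, which guarantees positivity and the right-skewed,
heteroscedastic marginals seen in field biomass data.  Species richness is
a clipped Poisson count whose mean is hump-shaped in MAP, peaking in the
400-500 mm/y class; temperature is weakly negatively coupled to MAP.

One seed sequence is spawned per site, so extending ``n_sites`` never
perturbs the draws of earlier sites, and an identical config + seed yields
a byte-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ClassScheme, write_quadrats

__all__ = ["SurveyDesign", "GeneratorConfig", "generate_survey", "write_fixture"]

_SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class SurveyDesign:
    """Hierarchical sampling layout: sites x plots x quadrats."""

    n_sites: int = 63
    plots_per_site: int = 3
    quadrats_per_plot: int = 5
    map_range: tuple[float, float] = (262.0, 772.0)
    class_edges: tuple[float, ...] = (400.0, 500.0, 600.0, 700.0)

    def __post_init__(self):
        for name in ("n_sites", "plots_per_site", "quadrats_per_plot"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        lo, hi = self.map_range
        if not (0.0 < lo < hi <= 2000.0):
            raise ValueError("map_range must satisfy 0 < lo < hi <= 2000 mm/y")
        if any(b <= a for a, b in zip(self.class_edges, self.class_edges[1:])):
            raise ValueError("class_edges must be strictly increasing")

    @property
    def n_quadrats(self) -> int:
        return self.n_sites * self.plots_per_site * self.quadrats_per_plot

    @property
    def scheme(self) -> ClassScheme:
        return ClassScheme(edges=self.class_edges)


def _default_slopes(scheme: ClassScheme) -> dict[str, float]:
    # AGB accrues faster than BGB (slope > 1) everywhere except the
    # 600-700 mm/y class, which is isometric (slope = 1).
    slopes = {}
    for label, slope in zip(scheme.labels, (1.15, 1.12, 1.10, 1.00, 1.15)):
        slopes[label] = slope
    return slopes


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generating model.

    ``beta_map_*`` are population standardized path coefficients of the
    climate latent on the log-scale responses (defaults follow the
    structural-path strengths the pipeline is meant to recover: SLA 0.28,
    AGB 0.53, BGB 0.60).  ``class_allometric_slopes`` maps each
    precipitation-class label to the expected log-log SMA slope of AGB on
    BGB inside that class.  ``noise_sd`` scales all residual terms;
    1.0 is the calibrated setting at which the standardized coefficients
    are exact — it exists mainly to build degenerate noiseless fixtures.
    """

    design: SurveyDesign = field(default_factory=SurveyDesign)
    beta_map_sla: float = 0.28
    beta_map_agb: float = 0.53
    beta_map_bgb: float = 0.60
    class_allometric_slopes: dict[str, float] | None = None
    richness_range: tuple[int, int] = (1, 12)
    noise_sd: float = 1.0
    seed: int | None = 0

    # scale/shape choices (see docs/methods.md; absolute biomass scales are
    # free choices of the generator, not field-calibrated values)
    log_mu_agb: float = math.log(120.0)   # median AGB ~ 120 g/m2
    log_sd_agb: float = 0.5
    log_mu_bgb: float = math.log(950.0)   # median BGB ~ 950 g/m2 (root-dominated turf)
    log_sd_bgb: float = 0.5
    log_mu_sla: float = math.log(15.0)    # median SLA ~ 15 m2/kg
    log_sd_sla: float = 0.25
    bgb_agb_coupling: float = 0.92        # share of within-class BGB noise aligned with AGB noise
    mat_intercept_c: float = -1.0
    mat_slope_c: float = -2.0             # MAT per unit z(MAP): weak negative coupling
    mat_noise_c: float = 1.0
    richness_peak_mm: float = 450.0
    richness_width_mm: float = 160.0
    richness_base: float = 2.0
    richness_amp: float = 6.0

    def __post_init__(self):
        for name in ("beta_map_sla", "beta_map_agb", "beta_map_bgb"):
            b = getattr(self, name)
            if not (-1.0 < b < 1.0):
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi):
            raise ValueError("richness_range must satisfy 1 <= lo <= hi")
        if not (0.0 <= self.bgb_agb_coupling <= 1.0):
            raise ValueError("bgb_agb_coupling must be in [0, 1]")
        slopes = self.class_allometric_slopes
        if slopes is None:
            slopes = _default_slopes(self.design.scheme)
            object.__setattr__(self, "class_allometric_slopes", slopes)
        else:
            labels = set(self.design.scheme.labels)
            missing = labels - set(slopes)
            if missing:
                raise ValueError(f"class_allometric_slopes missing labels: {sorted(missing)}")
            if any(s <= 0 for s in slopes.values()):
                raise ValueError("allometric slopes must be > 0")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


# --------------------------------------------------------------------------
# analytic class moments of the standardized precipitation latent

def _class_moments(config: GeneratorConfig):
    """Per-class probability, mean and variance of z = standardized MAP.

    MAP is uniform on ``map_range``, so z is uniform on [-sqrt(3), sqrt(3)]
    and every class is a sub-interval on which z stays uniform; classes are
    clipped to the support and empty classes get probability zero.
    """
    lo, hi = config.design.map_range
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / math.sqrt(12.0)
    scheme = config.design.scheme
    bounds = [lo, *[e for e in scheme.edges], hi]
    # z-interval per label, clipped to the support
    out = {}
    cuts = [-math.inf, *scheme.edges, math.inf]
    for i, label in enumerate(scheme.labels):
        a = max(cuts[i], lo)
        b = min(cuts[i + 1], hi)
        if b <= a:
            out[label] = (0.0, 0.0, 0.0)
            continue
        za, zb = (a - mid) / sd, (b - mid) / sd
        p = (b - a) / (hi - lo)
        out[label] = (p, 0.5 * (za + zb), (zb - za) ** 2 / 12.0)
    return out, mid, sd


def _bgb_plan(config: GeneratorConfig):
    """Per-class coefficients for the log-BGB latent.

    Returns ``mean_scale`` m and a dict label -> (E_c[z], b_z, b_eps, b_w)
    such that  B = m*E_c[z] + b_z*(z - E_c[z]) + b_eps*epsA + b_w*w  has
    within-class variance V_c (matching the class SMA slope) and global
    corr(z, B) = beta_map_bgb.
    """
    moments, _, _ = _class_moments(config)
    b_B = config.beta_map_bgb
    ratio2 = (config.log_sd_agb / config.log_sd_bgb) ** 2
    n2 = config.noise_sd**2

    Ev = sum(p * v for p, _, v in moments.values())          # E[Var(z|class)]
    T = sum(p * ez**2 for p, ez, _ in moments.values())      # Var(E[z|class])
    sum_pV = 0.0
    per_class = {}
    for label, (p, ez, v) in moments.items():
        slope = config.class_allometric_slopes[label]
        var_A = config.beta_map_agb**2 * v + n2 * (1 - config.beta_map_agb**2)
        V_c = ratio2 * var_A / slope**2
        resid2 = max(V_c - b_B**2 * v, 0.0)
        b_eps = config.bgb_agb_coupling * math.sqrt(resid2)
        b_w = math.sqrt(max(resid2 - b_eps**2, 0.0))
        per_class[label] = (ez, b_B, b_eps, b_w)
        sum_pV += p * (b_B**2 * v + resid2)

    # solve (b_B*Ev + m*T)^2 = b_B^2 * (sum_pV + m^2*T) for the mean scale m
    if T <= 1e-12:
        m = b_B
    else:
        a2 = T * (T - b_B**2)
        a1 = 2.0 * b_B * Ev * T
        a0 = b_B**2 * (Ev**2 - sum_pV)
        if abs(a2) < 1e-12:
            m = -a0 / a1 if abs(a1) > 1e-12 else b_B
        else:
            disc = a1**2 - 4.0 * a2 * a0
            if disc < 0:  # no exact solution; fall back to uncalibrated means
                m = b_B
            else:
                roots = [(-a1 + s * math.sqrt(disc)) / (2.0 * a2) for s in (+1.0, -1.0)]
                # the calibrated profile is the root near b_B with matching sign
                roots.sort(key=lambda r: abs(r - b_B))
                m = roots[0]
    return m, per_class


# --------------------------------------------------------------------------

def generate_survey(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate one quadrat table under ``config``.

    Returns a validated-shape DataFrame with the canonical columns plus
    ``precip_class``; row count is exactly
    ``n_sites * plots_per_site * quadrats_per_plot``.
    """
    config = config or GeneratorConfig()
    if config.seed is None:
        raise ValueError("GeneratorConfig.seed must be set for a reproducible table")
    design = config.design
    scheme = design.scheme
    lo, hi = design.map_range
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / math.sqrt(12.0)

    mean_scale, bgb_plan = _bgb_plan(config)
    n_sd = config.noise_sd
    b_A, b_S = config.beta_map_agb, config.beta_map_sla
    resid_A = n_sd * math.sqrt(1.0 - b_A**2)
    resid_S = n_sd * math.sqrt(1.0 - b_S**2)
    rich_lo = max(1, config.richness_range[0])
    rich_hi = config.richness_range[1]

    children = np.random.SeedSequence(config.seed).spawn(design.n_sites)
    nq = design.plots_per_site * design.quadrats_per_plot
    rows = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        map_mm = rng.uniform(lo, hi)
        z = (map_mm - mid) / sd
        mat = config.mat_intercept_c + config.mat_slope_c * z + rng.normal(0.0, config.mat_noise_c)
        label = scheme.assign(map_mm)
        ez, b_z, b_eps, b_w = bgb_plan[label]

        eps_A = rng.standard_normal(nq)
        eps_S = rng.standard_normal(nq)
        w = rng.standard_normal(nq)

        a_std = b_A * z + resid_A * eps_A
        s_std = b_S * z + resid_S * eps_S
        b_std = mean_scale * ez + b_z * (z - ez) + n_sd * (b_eps * eps_A + b_w * w)

        agb = np.exp(config.log_mu_agb + config.log_sd_agb * a_std)
        bgb = np.exp(config.log_mu_bgb + config.log_sd_bgb * b_std)
        sla = np.exp(config.log_mu_sla + config.log_sd_sla * s_std)

        hump = math.exp(-0.5 * ((map_mm - config.richness_peak_mm) / config.richness_width_mm) ** 2)
        lam = max(config.richness_base + config.richness_amp * hump - 1.0, 0.0)
        rich = np.clip(1 + rng.poisson(lam, size=nq), rich_lo, rich_hi)

        for q in range(nq):
            plot = q // design.quadrats_per_plot + 1
            quad = q % design.quadrats_per_plot + 1
            rows.append(
                (
                    f"S{s + 1:03d}",
                    f"S{s + 1:03d}-P{plot}",
                    f"S{s + 1:03d}-P{plot}-Q{quad}",
                    map_mm,
                    mat,
                    agb[q],
                    bgb[q],
                    agb[q] + bgb[q],
                    sla[q],
                    int(rich[q]),
                    label,
                )
            )

    df = pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "plot_id",
            "quadrat_id",
            "map_mm",
            "mat_c",
            "agb_gm2",
            "bgb_gm2",
            "total_gm2",
            "sla",
            "richness",
            "precip_class",
        ],
    )
    df["precip_class"] = pd.Categorical(df["precip_class"], categories=list(scheme.labels), ordered=True)
    return df


def write_fixture(table: pd.DataFrame, path) -> None:
    """Write a generated table as a CSV fixture that round-trips losslessly."""
    write_quadrats(table, path)
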