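"""Biomass allocation trade-off statistic.

Two steps.  First each biomass component is min-max rescaled across all
quadrats of the analysis dataset into a *relative benefit*

    RB = (x_i - x_min) / (x_max - x_min)            in [0, 1],

which places aboveground and belowground biomass on a common dimensionless
scale.  Second, each quadrat's deviation from balanced allocation is the
root-mean-square deviation of its two relative benefits from their mean,

    RMSE_i = sqrt( sum_k (RB_k - RBbar_i)^2 / (n - 1) ),   n = 2 components,

signed by which component dominates: positive when RB_AGB > RB_BGB
(aboveground allocation dominance), negative when belowground allocation is
prioritised, zero for balanced allocation.  With two components this
collapses to  |RB_AGB - RB_BGB| / sqrt(2), so values lie in
[-1/sqrt(2), +1/sqrt(2)].

An alternative ``dataset`` mode measures each quadrat against the *dataset
mean* relative benefit instead of the quadrat's own two-component mean;
see docs/methods.md for why the per-quadrat reading is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ClassScheme

__all__ = [
    "BenefitScaling",
    "fit_scaling",
    "relative_benefit",
    "tradeoff_value",
    "tradeoff_table",
    "class_summary",
]

SQRT2 = np.sqrt(2.0)

#: Default quadrat area (m^2); the optional area normalisation divides by it.
QUADRAT_AREA_M2 = 0.25


class DegenerateScalingError(ValueError):
    """All observed values of a component are identical; min-max is undefined."""


@dataclass(frozen=True)
class BenefitScaling:
    """Observed min/max of each biomass component across all quadrats."""

    agb_min: float
    agb_max: float
    bgb_min: float
    bgb_max: float

    def __post_init__(self):
        if not (self.agb_max > self.agb_min):
            raise DegenerateScalingError("AGB max must exceed AGB min")
        if not (self.bgb_max > self.bgb_min):
            raise DegenerateScalingError("BGB max must exceed BGB min")


def fit_scaling(table: pd.DataFrame) -> BenefitScaling:
    """Global min/max of AGB and BGB over all quadrats of the dataset."""
    agb = np.asarray(table["agb_gm2"], dtype=float)
    bgb = np.asarray(table["bgb_gm2"], dtype=float)
    if agb.size < 2:
        raise ValueError("need at least two quadrats to fit a scaling")
    return BenefitScaling(agb.min(), agb.max(), bgb.min(), bgb.max())


def relative_benefit(x, x_min: float, x_max: float):
    """Min-max relative benefit of observed values under a fitted scaling.

    Values outside [x_min, x_max] (possible when scoring data not used to
    fit the scaling) are clamped into [0, 1] with a warning.
    """
    if not x_max > x_min:
        raise DegenerateScalingError("x_max must exceed x_min")
    x = np.asarray(x, dtype=float)
    rb = (x - x_min) / (x_max - x_min)
    if np.any(rb < 0) or np.any(rb > 1):
        warnings.warn(
            "values outside the fitted [min, max] range were clamped to [0, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
        rb = np.clip(rb, 0.0, 1.0)
    return rb if rb.ndim else float(rb)


def tradeoff_value(rb_agb, rb_bgb, mode: str = "per-quadrat", rb_mean: float | None = None):
    """Signed trade-off statistic from paired relative benefits.

    mode="per-quadrat" (default): +-|RB_AGB - RB_BGB| / sqrt(2), the RMS
    deviation of the quadrat's two benefits from their own mean.
    mode="dataset": RMS deviation of the quadrat's two benefits from the
    dataset-wide mean benefit ``rb_mean`` (computed from the inputs when
    not supplied), signed the same way.
    """
    a = np.asarray(rb_agb, dtype=float)
    b = np.asarray(rb_bgb, dtype=float)
    sign = np.sign(a - b)
    if mode == "per-quadrat":
        mag = np.abs(a - b) / SQRT2
    elif mode == "dataset":
        if rb_mean is None:
            rb_mean = float(np.mean(np.concatenate([np.atleast_1d(a), np.atleast_1d(b)])))
        mag = np.sqrt((a - rb_mean) ** 2 + (b - rb_mean) ** 2)
        sign = np.where(a == b, 0.0, sign)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    val = sign * mag
    return val if val.ndim else float(val)


def direction(value) -> np.ndarray:
    """Categorical reading of the sign: aboveground / balanced / belowground."""
    v = np.atleast_1d(np.asarray(value, dtype=float))
    out = np.where(v > 0, "aboveground", np.where(v < 0, "belowground", "balanced"))
    return out


def tradeoff_table(
    table: pd.DataFrame,
    mode: str = "per-quadrat",
    area_normalize: bool = False,
    quadrat_area_m2: float = QUADRAT_AREA_M2,
) -> pd.DataFrame:
    """Score every quadrat: relative benefits, trade-off value and direction.

    The scaling is fit in-sample on the table itself (min/max across all
    quadrats).  ``area_normalize`` divides the statistic by the quadrat
    area; with the constant default area this changes no comparison and is
    off by default.
    """
    scaling = fit_scaling(table)
    out = table.copy()
    out["rb_agb"] = relative_benefit(out["agb_gm2"], scaling.agb_min, scaling.agb_max)
    out["rb_bgb"] = relative_benefit(out["bgb_gm2"], scaling.bgb_min, scaling.bgb_max)
    out["tradeoff"] = tradeoff_value(out["rb_agb"], out["rb_bgb"], mode=mode)
    if area_normalize:
        out["tradeoff"] = out["tradeoff"] / quadrat_area_m2
    out["direction"] = direction(out["tradeoff"].to_numpy())
    return out


def class_summary(scored: pd.DataFrame, scheme: ClassScheme | None = None) -> pd.DataFrame:
    """Per-precipitation-class mean trade-off with a one-sample t test vs 0."""
    if "precip_class" not in scored.columns:
        scheme = scheme or ClassScheme()
        scored = scored.assign(precip_class=scheme.categorical(scored["map_mm"].to_numpy()))
    rows = []
    for label, g in scored.groupby("precip_class", observed=True):
        v = g["tradeoff"].to_numpy()
        t, p = (np.nan, np.nan) if len(v) < 2 else stats.ttest_1samp(v, 0.0)
        rows.append(
            {
                "precip_class": label,
                "n": len(v),
                "mean_tradeoff": v.mean() if len(v) else np.nan,
                "sd_tradeoff": v.std(ddof=1) if len(v) > 1 else np.nan,
                "t_vs_zero": t,
                "p_vs_zero": p,
                "direction": "balanced" if (len(v) < 2 or p >= 0.05) else ("aboveground" if v.mean() > 0 else "belowground"),
            }
        )
    return pd.DataFrame(rows)
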