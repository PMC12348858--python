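"""Quadrat data model: schema, validation, and precipitation-class assignment.

The atomic observation of the whole pipeline is one quadrat (0.5 m x 0.5 m)
nested in a plot (50 m x 50 m) nested in a site.  A quadrat row carries the
site climate (mean annual precipitation and temperature), the measured
biomass pools (aboveground, belowground, total, all g/m2), specific leaf
area and species richness.  Sites are binned into precipitation classes
(mm/y) which stratify every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order of a quadrat table.
COLUMNS = [
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
]

NUMERIC_COLUMNS = ["map_mm", "mat_c", "agb_gm2", "bgb_gm2", "total_gm2", "sla", "richness"]

#: Relative tolerance for the total = AGB + BGB cross-check.
TOTAL_RTOL = 1e-6

#: Default precipitation class edges (mm/y).
DEFAULT_EDGES = (400.0, 500.0, 600.0, 700.0)


class ValidationError(ValueError):
    """A quadrat table violates the schema; carries row-level problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        msg = "invalid quadrat table:\n" + "\n".join(f"  - {p}" for p in self.problems)
        super().__init__(msg)


def _default_labels(edges: tuple[float, ...]) -> tuple[str, ...]:
    def fmt(e: float) -> str:
        return f"{e:g}"

    inner = [f"{fmt(lo)}-{fmt(hi)}" for lo, hi in zip(edges[:-1], edges[1:])]
    return tuple([f"<{fmt(edges[0])}", *inner, f">{fmt(edges[-1])}"])


@dataclass(frozen=True)
class ClassScheme:
    """Partition of the precipitation axis into labelled classes.

    Intervals are left-closed / right-open, ``[lo, hi)``, except the two
    open-ended extremes, so every positive precipitation value falls in
    exactly one class (a value equal to an edge belongs to the class above
    it: 400.0 mm/y is in "400-500").
    """

    edges: tuple[float, ...] = DEFAULT_EDGES
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 1:
            raise ValueError("need at least one class edge")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("class edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)
        labels = self.labels if self.labels is not None else _default_labels(edges)
        labels = tuple(str(l) for l in labels)
        if len(labels) != len(edges) + 1:
            raise ValueError("need exactly len(edges)+1 labels")
        object.__setattr__(self, "labels", labels)

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def assign(self, map_mm):
        """Assign class labels to precipitation values (scalar or array)."""
        arr = np.asarray(map_mm, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("precipitation must be finite and positive")
        idx = np.searchsorted(self.edges, arr, side="right")
        labels = np.asarray(self.labels, dtype=object)[idx]
        if np.isscalar(map_mm) or arr.ndim == 0:
            return str(labels if arr.ndim == 0 else labels[0])
        return labels

    def categorical(self, map_mm) -> pd.Categorical:
        return pd.Categorical(self.assign(map_mm), categories=list(self.labels), ordered=True)


def assign_class(map_mm: float, scheme: ClassScheme | None = None) -> str:
    """Class label for one precipitation value under the half-open convention."""
    return (scheme or ClassScheme()).assign(map_mm)


def validate_quadrats(
    df: pd.DataFrame,
    scheme: ClassScheme | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Validate a quadrat table and attach the ``precip_class`` column.

    Checks: required columns present, numeric columns numeric and finite,
    biomass strictly positive, richness >= 1, and total = AGB + BGB within
    ``TOTAL_RTOL`` (total is computed when absent).  Problems are reported
    with 0-based row numbers; nothing is silently dropped.

    Parameters
    ----------
    strict
        If true (default), raise :class:`ValidationError` on any problem;
        otherwise return the table with a ``valid`` boolean column.
    """
    scheme = scheme or ClassScheme()
    df = df.copy()
    problems: list[str] = []

    missing = [c for c in COLUMNS if c not in df.columns and c != "total_gm2"]
    if missing:
        raise ValidationError([f"missing required column(s): {', '.join(missing)}"])

    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for i in df.index[bad]:
            problems.append(f"row {i}: non-numeric value {df.at[i, col]!r} in {col}")
        df[col] = coerced

    rowbad = pd.Series(False, index=df.index)
    for col in ("agb_gm2", "bgb_gm2"):
        nonpos = df[col].isna() | (df[col] <= 0)
        for i in df.index[nonpos]:
            problems.append(f"row {i}: {col} must be strictly positive, got {df.at[i, col]}")
        rowbad |= nonpos

    if "total_gm2" not in df.columns or df["total_gm2"].isna().all():
        df["total_gm2"] = df["agb_gm2"] + df["bgb_gm2"]
    else:
        expect = df["agb_gm2"] + df["bgb_gm2"]
        off = ~rowbad & ~np.isclose(df["total_gm2"], expect, rtol=TOTAL_RTOL, atol=0.0)
        for i in df.index[off]:
            problems.append(
                f"row {i}: total_gm2={df.at[i, 'total_gm2']} != agb+bgb={expect.loc[i]:.6g}"
            )
        rowbad |= off

    badrich = df["richness"].isna() | (df["richness"] < 1)
    for i in df.index[badrich]:
        problems.append(f"row {i}: richness must be >= 1, got {df.at[i, 'richness']}")
    rowbad |= badrich

    badmap = df["map_mm"].isna() | (df["map_mm"] <= 0)
    for i in df.index[badmap]:
        problems.append(f"row {i}: map_mm must be positive, got {df.at[i, 'map_mm']}")
    rowbad |= badmap

    if strict and problems:
        raise ValidationError(problems)

    ok = ~rowbad
    df["precip_class"] = pd.Categorical([None] * len(df), categories=list(scheme.labels), ordered=True)
    if ok.any():
        df.loc[ok, "precip_class"] = scheme.assign(df.loc[ok, "map_mm"].to_numpy())
    if not strict:
        df["valid"] = ok
    return df


def read_quadrats(path, scheme: ClassScheme | None = None, strict: bool = True) -> pd.DataFrame:
    """Read a delimited quadrat table and validate it (see :func:`validate_quadrats`)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_quadrats(df, scheme=scheme, strict=strict)


def write_quadrats(df: pd.DataFrame, path) -> None:
    """Write a quadrat table as CSV with the canonical column order."""
    cols = [c for c in COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols and c != "precip_class"]
    # shortest round-trip repr, so write->read is lossless
    df.loc[:, cols + extra].to_csv(path, index=False, float_format=lambda v: repr(float(v)))
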