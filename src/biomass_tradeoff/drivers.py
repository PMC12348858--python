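"""Driver attribution for the biomass trade-off.

Three tiers of evidence, mirroring the usual ecological workflow:

1. Screening — pairwise Pearson correlations between the trade-off and its
   candidate drivers, plus a Mantel permutation test between distance
   matrices (Euclidean distance on z-scored variables).
2. Importance — random-forest permutation importance (%IncMSE): per tree,
   the relative increase of the out-of-bag mean squared error when one
   predictor's OOB values are permuted, averaged over trees and expressed
   in percent.  The bootstrap/permutation machinery is explicit here so
   the procedure is exactly reproducible under a fixed seed.
3. Structure — a piecewise (local-estimation) path model: every structural
   equation is fit by least squares on z-scored variables, giving
   standardized path coefficients; the global goodness of the causal
   topology is judged by Fisher's C over the d-separation basis set
   (C = -2 sum ln p_i, chi-square with 2k df), and RMSEA / CFI are
   computed from the covariance chi-square of the equivalent global model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "correlation_screen",
    "mantel_test",
    "MantelResult",
    "rf_importance",
    "ImportanceResult",
    "fit_path_model",
    "PathModel",
    "model_fit_stats",
    "FitStats",
    "DEFAULT_RF_PREDICTORS",
    "DEFAULT_PATH_EDGES",
]

#: Default predictor set for the importance forest (trade-off as target).
DEFAULT_RF_PREDICTORS = ["map_mm", "agb_gm2", "bgb_gm2", "sla", "richness"]

#: Default causal topology: precipitation drives the leaf trait and both
#: biomass pools; those three plus precipitation itself drive the
#: allocation trade-off.
DEFAULT_PATH_EDGES = [
    ("map", "sla"),
    ("map", "agb"),
    ("map", "bgb"),
    ("map", "tradeoff"),
    ("agb", "tradeoff"),
    ("bgb", "tradeoff"),
    ("sla", "tradeoff"),
]

#: Default correlated structural errors: the two biomass pools share
#: unmeasured site drivers (soil, community composition) beyond climate.
DEFAULT_CORRELATED_ERRORS = [("agb", "bgb")]


# --------------------------------------------------------------------------
# correlation screen

@dataclass(frozen=True)
class CorrelationScreen:
    r: pd.DataFrame
    p: pd.DataFrame
    target: str | None


def correlation_screen(table: pd.DataFrame, target: str | None = None, columns: list[str] | None = None) -> CorrelationScreen:
    """Pairwise Pearson r with two-sided p-values over numeric columns.

    Constant columns are excluded with a warning.  No multiplicity
    adjustment is applied across the screen (raw p-values are reported);
    treat it as descriptive.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    keep = []
    for c in columns:
        if np.ptp(np.asarray(table[c], dtype=float)) == 0:
            warnings.warn(f"column {c!r} is constant and was excluded from the screen", RuntimeWarning, stacklevel=2)
        else:
            keep.append(c)
    k = len(keep)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi = stats.pearsonr(table[keep[i]], table[keep[j]])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    rdf = pd.DataFrame(r, index=keep, columns=keep)
    pdf = pd.DataFrame(p, index=keep, columns=keep)
    return CorrelationScreen(r=rdf, p=pdf, target=target)


# --------------------------------------------------------------------------
# Mantel test

@dataclass(frozen=True)
class MantelResult:
    pair: tuple[str, str]
    r: float
    p: float
    n_perm: int
    alternative: str
    exhaustive: bool


def _check_dist(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return m


def mantel_test(
    dist_a,
    dist_b,
    n_perm: int | str = 999,
    seed: int | None = 0,
    alternative: str = "greater",
    names: tuple[str, str] = ("A", "B"),
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the strictly-lower triangles; the null
    distribution permutes rows and columns of the second matrix jointly.
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`` for the one-sided
    "greater" alternative ("two-sided" compares |r|).  With
    ``n_perm="exhaustive"`` all n! relabelings are enumerated (the identity
    included once), giving the exact permutation p-value — intended for
    small matrices (n <= ~8).
    """
    A = _check_dist(dist_a, "dist_a")
    B = _check_dist(dist_b, "dist_b")
    if A.shape != B.shape:
        raise ValueError("matrices must have identical shape")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 objects")
    tri = np.tril_indices(n, k=-1)
    a = A[tri]
    sa = a.std()
    if sa == 0:
        raise ValueError("dist_a has zero variance in its lower triangle")

    def corr_with(Bm):
        b = Bm[tri]
        sb = b.std()
        if sb == 0:
            return 0.0
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))

    r_obs = corr_with(B)

    def extreme(rp):
        return rp >= r_obs if alternative == "greater" else abs(rp) >= abs(r_obs)

    if n_perm == "exhaustive":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            rp = corr_with(B[np.ix_(idx, idx)])
            count += extreme(rp)
            total += 1
        return MantelResult(pair=names, r=r_obs, p=count / total, n_perm=total, alternative=alternative, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        idx = rng.permutation(n)
        count += extreme(corr_with(B[np.ix_(idx, idx)]))
    p = (1 + count) / (int(n_perm) + 1)
    return MantelResult(pair=names, r=r_obs, p=p, n_perm=int(n_perm), alternative=alternative, exhaustive=False)


def distance_matrix(values) -> np.ndarray:
    """Euclidean distances on z-scored columns (1-D input allowed)."""
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


# --------------------------------------------------------------------------
# random-forest permutation importance

@dataclass(frozen=True)
class ImportanceResult:
    variable: str
    pct_inc_mse: float
    rank: int
    n_trees: int
    n_permutations: int
    seed: int


def rf_importance(
    table: pd.DataFrame,
    target: str = "tradeoff",
    predictors: list[str] | None = None,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> list[ImportanceResult]:
    """%IncMSE permutation importance from an explicit OOB bootstrap.

    For each of ``n_trees`` bootstrap samples a regression tree is grown on
    ``mtry`` (default floor(k/3), min 1) candidate features per split; the
    tree's out-of-bag rows give a baseline MSE, and each predictor's OOB
    values are permuted once to give the permuted MSE.  The importance of a
    predictor is ``100 * mean_t[(MSE_perm - MSE_oob) / MSE_oob]``.  Results
    are sorted by importance (rank 1 = most important) and are exactly
    reproducible for a fixed (seed, n_trees).
    """
    predictors = list(predictors) if predictors is not None else [c for c in DEFAULT_RF_PREDICTORS if c in table.columns]
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    y = np.asarray(table[target], dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    X = table.loc[:, predictors].to_numpy(dtype=float)
    n, k = X.shape
    mtry = mtry if mtry is not None else max(k // 3, 1)
    rng = np.random.default_rng(seed)

    inc = np.zeros((n_trees, k))
    used = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        n_oob = int(oob.sum())
        tree_seed = int(rng.integers(0, 2**31 - 1))
        if n_oob < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry, min_samples_leaf=min_samples_leaf, random_state=tree_seed
        ).fit(X[boot], y[boot])
        Xo, yo = X[oob], y[oob]
        base = float(np.mean((tree.predict(Xo) - yo) ** 2))
        if base == 0:
            continue
        used[t] = True
        for j in range(k):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(n_oob), j]
            mse = float(np.mean((tree.predict(Xp) - yo) ** 2))
            inc[t, j] = (mse - base) / base
    if not used.any():
        raise ValueError("no usable out-of-bag samples; increase n or n_trees")
    pct = 100.0 * inc[used].mean(axis=0)
    order = np.argsort(-pct)
    ranks = np.empty(k, dtype=int)
    ranks[order] = np.arange(1, k + 1)
    results = [
        ImportanceResult(
            variable=predictors[j],
            pct_inc_mse=float(pct[j]),
            rank=int(ranks[j]),
            n_trees=int(used.sum()),
            n_permutations=1,
            seed=seed,
        )
        for j in range(k)
    ]
    results.sort(key=lambda r: r.rank)
    return results


# --------------------------------------------------------------------------
# piecewise path model

@dataclass(frozen=True)
class PathModel:
    paths: list[tuple[str, str, float, float]]  # (from, to, standardized beta, p)
    fisher_c: float
    fisher_df: int
    fisher_p: float
    indirect_effects: list[tuple[tuple[str, ...], float]]
    r2: dict[str, float] = field(default_factory=dict)
    n: int = 0
    edges: tuple[tuple[str, str], ...] = ()
    correlated_errors: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class FitStats:
    chi2: float
    df: int
    p: float
    rmsea: float
    cfi: float
    fisher_c: float
    fisher_df: int
    fisher_p: float
    rmsea_ok: bool
    cfi_ok: bool


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def _ols_std(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS with intercept on already z-scored data -> (betas, p-values, R2)."""
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    dof = n - k - 1
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))[1:]
    tvals = coef[1:] / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    tss = y @ y - n * y.mean() ** 2
    r2 = 1.0 - (resid @ resid) / tss if tss > 0 else 1.0
    return coef[1:], pvals, float(r2)


def _basis_set(g: nx.DiGraph, correlated: set[frozenset] = frozenset()) -> list[tuple[str, str, tuple[str, ...]]]:
    """Shipley's d-separation basis: one claim per non-adjacent pair,
    conditioning on the union of both parents; the regressed vertex is the
    non-ancestor (topologically later) one.  Pairs declared as correlated
    errors make no independence claim and are skipped."""
    topo = list(nx.topological_sort(g))
    pos = {v: i for i, v in enumerate(topo)}
    claims = []
    for x, y in itertools.combinations(topo, 2):
        if g.has_edge(x, y) or g.has_edge(y, x) or frozenset((x, y)) in correlated:
            continue
        first, second = (x, y) if pos[x] < pos[y] else (y, x)
        cond = sorted(set(g.predecessors(first)) | set(g.predecessors(second)))
        claims.append((first, second, tuple(cond)))
    return claims


def fit_path_model(
    table: pd.DataFrame,
    model_spec: list[tuple[str, str]] | None = None,
    correlated_errors: list[tuple[str, str]] | None = None,
) -> PathModel:
    """Fit a piecewise path model on z-scored variables.

    ``model_spec`` is a list of directed edges (source, response); every
    response's structural equation is estimated by OLS, so the coefficient
    of a single-predictor equation equals the Pearson correlation.
    ``correlated_errors`` lists unordered pairs whose structural residuals
    are allowed to covary (they contribute no d-separation claim).
    Fisher's C aggregates the d-separation claims of the topology; a
    saturated topology has an empty basis set and C = 0 on 0 df.
    Indirect effects are products of path coefficients along every directed
    path of two or more edges.
    """
    if model_spec is not None:
        edges = list(model_spec)
        corr_err = [tuple(p) for p in (correlated_errors or [])]
    else:
        edges = list(DEFAULT_PATH_EDGES)
        corr_err = [tuple(p) for p in (correlated_errors if correlated_errors is not None else DEFAULT_CORRELATED_ERRORS)]
    g = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("model specification contains a cycle")
    missing = [v for v in g.nodes if v not in table.columns]
    if missing:
        raise ValueError(f"variables missing from table: {missing}")
    z = _zscore(table.loc[:, list(g.nodes)].astype(float))
    n = len(z)

    paths: list[tuple[str, str, float, float]] = []
    beta = {}
    r2 = {}
    for node in g.nodes:
        parents = sorted(g.predecessors(node))
        if not parents:
            continue
        b, p, rr = _ols_std(z[node].to_numpy(), z[parents].to_numpy())
        r2[node] = rr
        for par, bi, pi in zip(parents, b, p):
            paths.append((par, node, float(bi), float(pi)))
            beta[(par, node)] = float(bi)

    claims = _basis_set(g, {frozenset(p) for p in corr_err})
    c_stat = 0.0
    for first, second, cond in claims:
        X = z[[first, *cond]].to_numpy() if cond else z[[first]].to_numpy()
        _, pvals, _ = _ols_std(z[second].to_numpy(), X)
        p_claim = max(float(pvals[0]), np.finfo(float).tiny)
        c_stat += -2.0 * math.log(p_claim)
    fisher_df = 2 * len(claims)
    fisher_p = float(stats.chi2.sf(c_stat, fisher_df)) if fisher_df > 0 else 1.0

    indirect = []
    for src in g.nodes:
        for dst in g.nodes:
            if src == dst:
                continue
            for path in nx.all_simple_paths(g, src, dst):
                if len(path) >= 3:
                    prod = float(np.prod([beta[(a, b)] for a, b in zip(path, path[1:])]))
                    indirect.append((tuple(path), prod))

    return PathModel(
        paths=paths,
        fisher_c=float(c_stat),
        fisher_df=fisher_df,
        fisher_p=fisher_p,
        indirect_effects=indirect,
        r2=r2,
        n=n,
        edges=tuple(edges),
        correlated_errors=tuple(tuple(p) for p in corr_err),
    )


def model_fit_stats(pathmodel: PathModel, table: pd.DataFrame, rmsea_threshold: float = 0.08, cfi_threshold: float = 0.90) -> FitStats:
    """Global covariance-based fit of the fitted topology: chi2, RMSEA, CFI.

    The implied correlation matrix is built from the standardized path
    coefficients via (I - B)^-1 Psi (I - B)^-T with sample correlations
    among exogenous variables and uncorrelated structural residuals; the
    ML discrepancy against the sample correlation matrix gives the
    chi-square.  RMSEA and CFI are compared with the conventional
    thresholds (< 0.08 and > 0.90 respectively).
    """
    g = nx.DiGraph(list(pathmodel.edges))
    nodes = list(nx.topological_sort(g))
    p = len(nodes)
    z = _zscore(table.loc[:, nodes].astype(float))
    S = np.corrcoef(z.to_numpy(), rowvar=False)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise np.linalg.LinAlgError("sample correlation matrix is not positive definite")
    n = pathmodel.n
    idx = {v: i for i, v in enumerate(nodes)}
    B = np.zeros((p, p))
    for src, dst, b, _ in pathmodel.paths:
        B[idx[dst], idx[src]] = b
    exo = [v for v in nodes if g.in_degree(v) == 0]
    Psi = np.zeros((p, p))
    for v in nodes:
        i = idx[v]
        Psi[i, i] = 1.0 - pathmodel.r2.get(v, 0.0) if g.in_degree(v) else S[i, i]
    for a, b in itertools.combinations(exo, 2):
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = S[idx[a], idx[b]]
    # correlated structural errors: residual covariances of the named pairs
    Z = z.to_numpy()
    resid = Z - Z @ B.T  # structural residuals on the standardized scale
    for a, b in pathmodel.correlated_errors:
        ia, ib = idx[a], idx[b]
        cov_ab = float(np.cov(resid[:, ia], resid[:, ib], ddof=1)[0, 1])
        Psi[ia, ib] = Psi[ib, ia] = cov_ab
    Iinv = np.linalg.inv(np.eye(p) - B)
    sigma = Iinv @ Psi @ Iinv.T

    sign_S, logdet_S = np.linalg.slogdet(S)
    sign_M, logdet_M = np.linalg.slogdet(sigma)
    f_ml = logdet_M - logdet_S + float(np.trace(S @ np.linalg.inv(sigma))) - p
    f_ml = max(f_ml, 0.0)
    n_free = len(pathmodel.paths) + p + len(exo) * (len(exo) - 1) // 2 + len(pathmodel.correlated_errors)
    df = p * (p + 1) // 2 - n_free
    chi2 = (n - 1) * f_ml
    p_chi2 = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else 0.0

    chi2_null = (n - 1) * max(-logdet_S, 0.0)
    df_null = p * (p - 1) // 2
    denom = max(chi2_null - df_null, chi2 - df, 0.0)
    cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)

    return FitStats(
        chi2=float(chi2),
        df=int(df),
        p=p_chi2,
        rmsea=float(rmsea),
        cfi=float(cfi),
        fisher_c=pathmodel.fisher_c,
        fisher_df=pathmodel.fisher_df,
        fisher_p=pathmodel.fisher_p,
        rmsea_ok=bool(rmsea < rmsea_threshold),
        cfi_ok=bool(cfi > cfi_threshold),
    )
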