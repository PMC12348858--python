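"""Correlation screen, Mantel test, %IncMSE forest and the path model."""

import itertools

import numpy as np
import pandas as pd
import pytest

from biomass_tradeoff import (
    correlation_screen,
    distance_matrix,
    fit_path_model,
    mantel_test,
    model_fit_stats,
    rf_importance,
)
from biomass_tradeoff.pipeline import analysis_frame

# ---------------------------------------------------------------- screen

def test_screen_self_correlation_and_symmetry(rng):
    df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("xyz"))
    scr = correlation_screen(df)
    assert np.allclose(np.diag(scr.r), 1.0)
    assert np.allclose(scr.r.to_numpy(), scr.r.to_numpy().T)


def test_screen_independent_columns_small_r(rng):
    df = pd.DataFrame(rng.normal(size=(945, 4)), columns=list("abcd"))
    scr = correlation_screen(df)
    off = scr.r.to_numpy()[~np.eye(4, dtype=bool)]
    assert np.abs(off).max() < 0.1


def test_screen_excludes_constant_column_with_warning(rng):
    df = pd.DataFrame({"x": rng.normal(size=50), "c": np.ones(50)})
    with pytest.warns(RuntimeWarning, match="constant"):
        scr = correlation_screen(df)
    assert list(scr.r.columns) == ["x"]


def test_richness_uncorrelated_with_tradeoff(scored_table):
    """Species richness shows no detectable effect on the trade-off."""
    frame = analysis_frame(scored_table)
    scr = correlation_screen(frame, target="tradeoff")
    assert scr.p.loc["tradeoff", "richness"] > 0.05


# ---------------------------------------------------------------- Mantel

def test_mantel_identical_matrices(rng):
    d = distance_matrix(rng.normal(size=12))
    res = mantel_test(d, d, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 100)


def test_mantel_exhaustive_equals_manual_enumeration(rng):
    a = distance_matrix(rng.normal(size=4))
    b = distance_matrix(rng.normal(size=4))
    res = mantel_test(a, b, n_perm="exhaustive")
    tri = np.tril_indices(4, k=-1)
    va = a[tri]
    count = total = 0
    for perm in itertools.permutations(range(4)):
        idx = np.asarray(perm)
        vb = b[np.ix_(idx, idx)][tri]
        rp = np.corrcoef(va, vb)[0, 1]
        count += rp >= res.r - 1e-12
        total += 1
    assert res.n_perm == 24 and total == 24
    assert res.p == pytest.approx(count / 24)


def test_mantel_matches_skbio(rng):
    from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

    x, y = rng.normal(size=15), rng.normal(size=15)
    a, b = distance_matrix(x), distance_matrix(0.7 * x + 0.3 * y)
    mine = mantel_test(a, b, n_perm=999, seed=1)
    r_ref, p_ref, _ = sk_mantel(
        DistanceMatrix(a), DistanceMatrix(b), method="pearson", permutations=999, alternative="greater"
    )
    assert mine.r == pytest.approx(float(r_ref), abs=1e-12)
    assert mine.p == pytest.approx(float(p_ref), abs=0.03)  # independent permutation streams


def test_mantel_null_p_uniform_on_grid(rng):
    """Under independence the permutation p is uniform on its grid."""
    ps = []
    for _ in range(200):
        a = distance_matrix(rng.normal(size=10))
        b = distance_matrix(rng.normal(size=10))
        ps.append(mantel_test(a, b, n_perm=49, seed=int(rng.integers(2**31))).p)
    assert 0.35 < np.mean(ps) < 0.65
    assert np.mean(np.asarray(ps) <= 0.2) == pytest.approx(0.2, abs=0.1)


def test_mantel_input_validation(rng):
    d = distance_matrix(rng.normal(size=5))
    with pytest.raises(ValueError, match="symmetric"):
        mantel_test(d, d + np.triu(np.ones_like(d), 1))
    with pytest.raises(ValueError, match="zero diagonal"):
        mantel_test(d, d + np.eye(5))


# ---------------------------------------------------------------- forest

def _frame_with_noise(scored):
    df = scored.copy()
    df["pure_noise"] = np.random.default_rng(99).normal(size=len(df))
    return df


def test_rf_reproducible_and_ranks_valid(scored_table):
    a = rf_importance(scored_table, n_trees=120, seed=5)
    b = rf_importance(scored_table, n_trees=120, seed=5)
    assert [(r.variable, r.pct_inc_mse) for r in a] == [(r.variable, r.pct_inc_mse) for r in b]
    assert sorted(r.rank for r in a) == list(range(1, len(a) + 1))


def test_rf_pure_noise_importance_near_zero(scored_table):
    df = _frame_with_noise(scored_table)
    res = rf_importance(
        df,
        predictors=["map_mm", "agb_gm2", "bgb_gm2", "sla", "richness", "pure_noise"],
        n_trees=500,
        seed=0,
    )
    noise = next(r for r in res if r.variable == "pure_noise")
    assert abs(noise.pct_inc_mse) < 2.0


def test_rf_duplicated_predictor_splits_importance(scored_table):
    base = rf_importance(scored_table, predictors=["map_mm", "agb_gm2", "bgb_gm2"], n_trees=300, seed=3)
    orig = next(r for r in base if r.variable == "agb_gm2").pct_inc_mse
    df = scored_table.copy()
    df["agb_copy"] = df["agb_gm2"]
    dup = rf_importance(df, predictors=["map_mm", "agb_gm2", "bgb_gm2", "agb_copy"], n_trees=300, seed=3)
    d1 = next(r for r in dup if r.variable == "agb_gm2").pct_inc_mse
    d2 = next(r for r in dup if r.variable == "agb_copy").pct_inc_mse
    assert d1 < orig and d2 < orig


def test_rf_constant_target_errors(scored_table):
    df = scored_table.copy()
    df["tradeoff"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        rf_importance(df)


# ---------------------------------------------------------------- path model

def test_single_predictor_beta_equals_pearson_r(rng):
    x = rng.normal(size=400)
    y = 0.5 * x + rng.normal(size=400)
    df = pd.DataFrame({"x": x, "y": y})
    model = fit_path_model(df, [("x", "y")])
    beta = model.paths[0][2]
    assert beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


def test_saturated_model_has_zero_fisher_c(rng):
    df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
    model = fit_path_model(df, [("a", "b"), ("a", "c"), ("b", "c")])
    assert model.fisher_c == 0.0 and model.fisher_df == 0 and model.fisher_p == 1.0


def test_cyclic_spec_rejected(rng):
    df = pd.DataFrame(rng.normal(size=(50, 2)), columns=list("ab"))
    with pytest.raises(ValueError, match="cycle"):
        fit_path_model(df, [("a", "b"), ("b", "a")])


def test_indirect_effect_is_product_of_betas(rng):
    x = rng.normal(size=500)
    m = 0.6 * x + rng.normal(size=500) * 0.8
    y = 0.5 * m + rng.normal(size=500) * 0.85
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    model = fit_path_model(df, [("x", "m"), ("m", "y")])
    betas = {(a, b): v for a, b, v, _ in model.paths}
    chain, prod = model.indirect_effects[0]
    assert chain == ("x", "m", "y")
    assert prod == pytest.approx(betas[("x", "m")] * betas[("m", "y")], abs=1e-12)


def test_omitted_strong_path_flags_misfit(rng):
    """Data with a strong direct x->y path, modelled only via the mediator,
    fail the d-separation test."""
    x = rng.normal(size=600)
    m = 0.5 * x + rng.normal(size=600)
    y = 0.6 * x + 0.3 * m + rng.normal(size=600)
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    model = fit_path_model(df, [("x", "m"), ("m", "y")])
    assert model.fisher_p < 0.05


def test_true_model_fit_stats_near_perfect(rng):
    n = 2000
    x = rng.normal(size=n)
    a = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
    b = 0.4 * x + 0.3 * a + rng.normal(size=n) * 0.8
    df = pd.DataFrame({"x": x, "a": a, "b": b})
    model = fit_path_model(df, [("x", "a"), ("x", "b"), ("a", "b")])
    # saturated -> chi2 ~ 0
    fs = model_fit_stats(model, df)
    assert fs.rmsea < 0.02 and fs.cfi > 0.99
    assert fs.rmsea_ok and fs.cfi_ok


def test_fit_stats_thresholds_applied(rng):
    n = 1500
    x = rng.normal(size=n)
    m = 0.5 * x + rng.normal(size=n)
    y = 0.6 * x + 0.3 * m + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    model = fit_path_model(df, [("x", "m"), ("m", "y")])
    fs = model_fit_stats(model, df)
    assert fs.rmsea > 0.08 and not fs.rmsea_ok  # strong omitted path


def test_default_model_on_synthetic_data(scored_table):
    frame = analysis_frame(scored_table)
    model = fit_path_model(frame)
    betas = {(a, b): v for a, b, v, _ in model.paths}
    assert betas[("map", "agb")] == pytest.approx(0.53, abs=0.06)
    assert betas[("map", "bgb")] == pytest.approx(0.60, abs=0.06)
    assert betas[("map", "sla")] == pytest.approx(0.28, abs=0.06)
    fs = model_fit_stats(model, frame)
    assert fs.rmsea_ok and fs.cfi_ok
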