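"""Assumption routing, omnibus/post-hoc comparisons, letters and smooths."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biomass_tradeoff import choose_route, compare_groups, fit_smooth
from biomass_tradeoff.groupstats import compact_letter_display, dunn_test


def test_kruskal_wallis_midrank_oracle():
    """H on {1,2,3},{4,5,6},{7,8,9} is 7.2 by the rank-sum formula."""
    comp = compare_groups(
        np.arange(1, 10, dtype=float),
        np.repeat(["a", "b", "c"], 3),
        route="nonparametric",
    )
    assert comp.omnibus_stat == pytest.approx(7.2)


def test_lognormal_routes_nonparametric(default_table):
    groups = default_table["precip_class"].astype(str).to_numpy()
    assert choose_route(default_table["agb_gm2"].to_numpy(), groups) == "nonparametric"


def test_gaussian_equal_variance_routing_joint_type_I(rng):
    """Under jointly valid assumptions the parametric route is kept at
    roughly the joint non-rejection rate of the six checks (five per-group
    Shapiro-Wilk tests plus Levene, each at alpha=0.05): ~0.95^6 ~ 0.74."""
    hits = 0
    n_rep = 300
    for _ in range(n_rep):
        values = rng.normal(0, 1, 5 * 30)
        groups = np.repeat(list("abcde"), 30)
        hits += choose_route(values, groups) == "parametric"
    assert 0.95**6 == pytest.approx(0.735, abs=0.001)
    assert 0.67 <= hits / n_rep <= 0.81


def test_constant_group_errors():
    with pytest.raises(ValueError, match="constant"):
        choose_route(np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0]), np.repeat(["a", "b"], 3))


def test_identical_groups_share_one_letter(rng):
    values = rng.normal(0, 1, 5 * 40)
    groups = np.repeat(list("abcde"), 40)
    comp = compare_groups(values, groups)
    assert set(comp.letters.values()) == {"a"}


@pytest.mark.parametrize("route", ["nonparametric", "parametric"])
def test_shifted_group_gets_distinct_letter(route, rng):
    """Means 0,0,0,0,5 with SD 1 and n=50: power ~1, distinct letter."""
    values = np.concatenate([rng.normal(0, 1, 50) for _ in range(4)] + [rng.normal(5, 1, 50)])
    groups = np.repeat(list("abcde"), 50)
    comp = compare_groups(values, groups, route=route)
    assert comp.omnibus_p < 1e-6
    letters = comp.letters
    assert all(set(letters["e"]) & set(letters[g]) == set() for g in "abcd")
    assert letters["a"] == letters["b"] == letters["c"] == letters["d"]


def test_dunn_two_groups_matches_kruskal():
    """For k=2, Dunn's z^2 equals the tie-corrected Kruskal-Wallis H."""
    rng = np.random.default_rng(4)
    values = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)])
    values = np.round(values, 1)  # induce ties to exercise the correction
    groups = np.repeat(["a", "b"], [20, 25])
    z = dunn_test(values, groups)["stat"].iloc[0]
    h, _ = stats.kruskal(values[:20], values[20:])
    assert z**2 == pytest.approx(h)


def test_tukey_route_matches_statsmodels(rng):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([rng.normal(m, 1, 30) for m in (0.0, 0.4, 1.0)])
    groups = np.repeat(list("abc"), 30)
    comp = compare_groups(values, groups, route="parametric")
    ref = pairwise_tukeyhsd(values, groups)
    np.testing.assert_allclose(
        comp.pairwise["p_adj"].to_numpy(), np.asarray(ref.pvalues), atol=1e-8
    )


def test_cld_consistency_with_pairwise_decisions(rng):
    values = np.concatenate([rng.normal(m, 1, 40) for m in (0, 0.2, 1.5, 1.6, 4.0)])
    groups = np.repeat(list("abcde"), 40)
    comp = compare_groups(values, groups)
    letters = comp.letters
    for row in comp.pairwise.itertuples():
        shared = set(letters[row.group_a]) & set(letters[row.group_b])
        if row.p_adj < 0.05:
            assert not shared, (row.group_a, row.group_b)
        else:
            assert shared, (row.group_a, row.group_b)


def test_cld_insertion_algorithm_minimal():
    letters = compact_letter_display(["g1", "g2", "g3"], {("g1", "g3")})
    assert set(letters["g1"]) & set(letters["g3"]) == set()
    assert set(letters["g2"]) & set(letters["g1"])
    assert set(letters["g2"]) & set(letters["g3"])


def test_adjusted_p_not_below_raw(default_table):
    groups = default_table["precip_class"].astype(str).to_numpy()
    comp = compare_groups(default_table["agb_gm2"].to_numpy(), groups, route="nonparametric")
    assert (comp.pairwise["p_adj"] + 1e-15 >= comp.pairwise["p_raw"]).all()


def test_nonparametric_invariant_to_monotone_transform(default_table):
    groups = default_table["precip_class"].astype(str).to_numpy()
    v = default_table["agb_gm2"].to_numpy()
    a = compare_groups(v, groups, route="nonparametric")
    b = compare_groups(np.log(v), groups, route="nonparametric")
    assert a.omnibus_stat == pytest.approx(b.omnibus_stat)
    np.testing.assert_allclose(a.pairwise["p_raw"], b.pairwise["p_raw"])


# ---------------------------------------------------------------- smooths

def test_smooth_linear_limit(rng):
    x = np.linspace(0, 10, 120)
    y = 2.0 + 0.5 * x
    fit = fit_smooth(pd.DataFrame({"x": x, "y": y}), "x", "y")
    assert fit.deviance_explained == pytest.approx(1.0, abs=1e-6)
    assert fit.edf == pytest.approx(1.0, abs=0.2)
    xs = np.linspace(0.5, 9.5, 30)
    np.testing.assert_allclose(fit.predict(xs), 2.0 + 0.5 * xs, atol=1e-4)


def test_smooth_monotone_on_positive_linear_effect(rng):
    x = rng.uniform(0, 10, 400)
    y = 1.0 + 0.8 * x + rng.normal(0, 0.5, 400)
    fit = fit_smooth(pd.DataFrame({"x": x, "y": y}), "x", "y")
    xs = np.linspace(x.min() + 0.2, x.max() - 0.2, 80)
    assert np.all(np.diff(fit.predict(xs)) > -1e-3)


def test_smooth_recovers_hump(rng):
    x = rng.uniform(0, 10, 500)
    y = np.exp(-0.5 * ((x - 5) / 1.5) ** 2) + rng.normal(0, 0.08, 500)
    fit = fit_smooth(pd.DataFrame({"x": x, "y": y}), "x", "y")
    xs = np.linspace(0.5, 9.5, 101)
    curve = fit.predict(xs)
    peak = xs[np.argmax(curve)]
    assert 4.0 < peak < 6.0
    # unimodal: rises then falls
    d = np.diff(curve)
    turn = np.argmax(curve)
    assert np.all(d[: max(turn - 3, 1)] > -1e-3) and np.all(d[min(turn + 3, len(d)) :] < 1e-3)


def test_smooth_errors(rng):
    with pytest.raises(ValueError, match="20 points"):
        fit_smooth(pd.DataFrame({"x": np.arange(5.0), "y": np.arange(5.0)}), "x", "y")
    df = pd.DataFrame({"x": np.ones(30), "y": rng.normal(size=30)})
    with pytest.raises(ValueError, match="constant predictor"):
        fit_smooth(df, "x", "y")
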