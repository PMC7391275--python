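"""Statistics oracles: hand-computed examples, enumeration, properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neonorm.errors import DegenerateDataError, InputError
from neonorm.stats import (
    BatteryConfig,
    bootstrap_ci_adj_r2,
    bootstrap_prediction_r2,
    fit_linear_model,
    holm_correct,
    mann_whitney,
    run_full_battery,
    sensitivity_rerun,
    spearman,
    vargha_delaney_a,
)

group_values = st.lists(
    st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 1)),
    min_size=2, max_size=12,
)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_limits():
    x = np.array([1.0, 2, 3, 5, 8])
    assert spearman(x, x**3).effect == pytest.approx(1.0)
    assert spearman(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])).effect == (
        pytest.approx(-1.0)
    )


def test_spearman_hand_computed():
    r = spearman(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
    assert r.effect == pytest.approx(0.8)


def test_spearman_constant_raises():
    with pytest.raises(DegenerateDataError):
        spearman(np.ones(5), np.arange(5.0))


def test_spearman_exact_permutation_small_n():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 5])
    res = spearman(x, y, method="exact")
    # brute-force reference: enumerate all 120 rank permutations
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = sum(
        abs(np.corrcoef(rx, p)[0, 1]) >= obs - 1e-12
        for p in itertools.permutations(ry)
    )
    assert res.p_value == pytest.approx(count / 120)


@given(
    xy=st.lists(
        st.tuples(st.floats(-10, 10, allow_nan=False),
                  st.floats(-10, 10, allow_nan=False)),
        min_size=4, max_size=20,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_spearman_equals_pearson_on_ranks(xy):
    from scipy.stats import rankdata
    x = np.array([round(a, 1) for a, _ in xy])
    y = np.array([round(b, 1) for _, b in xy])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    rho = spearman(x, y).effect
    pearson_on_ranks = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
    assert rho == pytest.approx(pearson_on_ranks, abs=1e-10)


# ---------------------------------------------------------------------------
# Mann–Whitney and Vargha–Delaney A


def test_u_statistic_complete_separation():
    res = mann_whitney(np.array([1.0, 2]), np.array([3.0, 4]))
    assert res.statistic == 0.0  # no x exceeds any y
    assert res.effect == 0.0


def test_a_identical_groups():
    g = np.array([1.0, 2, 3])
    assert mann_whitney(g, g).effect == pytest.approx(0.5)


def test_a_hand_computed_with_ties():
    assert vargha_delaney_a(np.array([2.0, 3]), np.array([1.0, 2])) == (
        pytest.approx(0.875)
    )
    assert vargha_delaney_a(np.array([1.0, 1, 2]), np.array([1.0, 2, 2])) == (
        pytest.approx(1 / 3)
    )


def test_a_dominance():
    assert vargha_delaney_a(np.array([10.0, 11]), np.array([1.0, 2])) == 1.0


@given(x=group_values, y=group_values)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_a_u_identity_and_complementarity(x, y):
    x, y = np.array(x), np.array(y)
    a = vargha_delaney_a(x, y)
    u = mann_whitney(x, y).statistic
    assert a == pytest.approx(u / (len(x) * len(y)), abs=1e-12)
    assert a + vargha_delaney_a(y, x) == pytest.approx(1.0, abs=1e-12)


def test_mann_whitney_p_matches_enumeration_small_groups():
    """Exact permutation null of U vs the tie-corrected normal p."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = np.round(rng.uniform(0, 5, 4), 1)
        y = np.round(rng.uniform(0, 5, 5), 1)
        res = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        n_x = len(x)
        stats = []
        for comb in itertools.combinations(range(len(pooled)), n_x):
            xs = pooled[list(comb)]
            ys = np.delete(pooled, list(comb))
            stats.append(vargha_delaney_a(xs, ys) * n_x * len(ys))
        stats = np.array(stats)
        mid = n_x * (len(pooled) - n_x) / 2
        exact = np.mean(np.abs(stats - mid) >= abs(res.statistic - mid) - 1e-9)
        assert res.p_value == pytest.approx(exact, abs=0.08)


# ---------------------------------------------------------------------------
# Holm


def test_holm_identity_for_single_test():
    adj, rej = holm_correct(np.array([0.03]))
    assert adj[0] == pytest.approx(0.03)
    assert rej[0]


def test_holm_hand_stepped_examples():
    adj, rej = holm_correct(np.array([0.01, 0.02, 0.04]), alpha=0.05)
    np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])
    assert rej.all()
    adj, rej = holm_correct(np.array([0.04, 0.04]), alpha=0.05)
    np.testing.assert_allclose(adj, [0.08, 0.08])
    assert not rej.any()


def test_holm_rejects_invalid_p():
    with pytest.raises(InputError):
        holm_correct(np.array([0.5, 1.2]))


@given(
    p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
    alpha=st.sampled_from([0.01, 0.05, 0.1]),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_holm_dominates_bonferroni(p, alpha):
    p = np.array(p)
    _, holm_rej = holm_correct(p, alpha)
    bonf_rej = p <= alpha / p.size
    assert np.all(bonf_rej <= holm_rej)  # Holm rejects a superset
    if p.size == 1:
        assert np.array_equal(holm_rej, bonf_rej | (p <= alpha))


# ---------------------------------------------------------------------------
# regression and bootstraps


def test_ols_perfect_fit():
    x = np.arange(10.0)
    res = fit_linear_model(2 * x, pd.DataFrame({"x": x}))
    assert res.r2 == pytest.approx(1.0)
    assert res.adj_r2 == pytest.approx(1.0)


def test_ols_hand_computed_three_points():
    res = fit_linear_model(
        np.array([0.0, 1.0, 4.0]), pd.DataFrame({"x": [0.0, 1.0, 2.0]})
    )
    assert res.params["x"] == pytest.approx(2.0)
    assert res.params["const"] == pytest.approx(-1 / 3)
    # SS_res = 6/9, SS_tot = 78/9 → R² = 72/78
    assert res.r2 == pytest.approx(72 / 78, abs=1e-10)


def test_ols_null_adj_r2_near_zero():
    rng = np.random.default_rng(8)
    y = rng.standard_normal(1000)
    X = pd.DataFrame(rng.standard_normal((1000, 3)), columns=list("abc"))
    res = fit_linear_model(y, X)
    assert abs(res.adj_r2) < 0.02
    assert res.adj_r2 <= res.r2


def test_ols_collinear_named():
    x = np.arange(12.0)
    X = pd.DataFrame({"x": x, "x2": 2 * x})
    with pytest.raises(InputError, match="x"):
        fit_linear_model(np.ones(12), X)


def test_bootstrap_ci_perfect_fit_degenerate():
    x = np.arange(10.0)
    lo, hi, draws = bootstrap_ci_adj_r2(3 * x + 1, pd.DataFrame({"x": x}),
                                        reps=50, seed=1)
    assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)


def test_bootstrap_ci_deterministic_and_ordered():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(40)
    y = x + rng.standard_normal(40)
    X = pd.DataFrame({"x": x})
    a = bootstrap_ci_adj_r2(y, X, reps=200, seed=9)
    b = bootstrap_ci_adj_r2(y, X, reps=200, seed=9)
    assert a[0] == b[0] and a[1] == b[1]
    np.testing.assert_array_equal(a[2], b[2])
    assert a[0] <= np.median(a[2]) <= a[1]


def test_bootstrap_ci_covers_zero_under_null():
    rng = np.random.default_rng(12)
    covered = 0
    for seed in range(20):
        g = np.random.default_rng(seed + 100)
        y = g.standard_normal(100)
        X = pd.DataFrame({"a": g.standard_normal(100),
                          "b": g.standard_normal(100)})
        lo, hi, _ = bootstrap_ci_adj_r2(y, X, reps=200, seed=seed)
        covered += lo <= 0.0 <= hi
    assert covered >= 18  # ≥90%


def test_prediction_r2_perfect_and_null():
    x = np.arange(30.0)
    assert bootstrap_prediction_r2(
        2 * x - 1, pd.DataFrame({"x": x}), resamples=30, seed=2
    ) == pytest.approx(1.0, abs=1e-8)
    g = np.random.default_rng(4)
    y = g.standard_normal(80)
    X = pd.DataFrame({"a": g.standard_normal(80)})
    null_val = bootstrap_prediction_r2(y, X, resamples=50, seed=2)
    assert null_val < 0.05
    assert null_val == bootstrap_prediction_r2(y, X, resamples=50, seed=2)


# ---------------------------------------------------------------------------
# sensitivity rerun


def test_sensitivity_noop_without_outliers():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(20)
    y = x + rng.standard_normal(20)
    full, trimmed, dropped = sensitivity_rerun(x, y)
    assert dropped == []
    assert full.effect == trimmed.effect


def test_sensitivity_standardization_sample_sd():
    """(0,0,10): Z of the outlier is 1.1547 under the n−1 convention."""
    x = np.array([0.0, 0.0, 10.0])
    z = (x - x.mean()) / x.std(ddof=1)
    assert z[2] == pytest.approx(1.1547, abs=1e-4)


def test_sensitivity_removes_influential_outlier():
    rng = np.random.default_rng(6)
    n = 30
    x = np.abs(rng.standard_normal(n)) * 0.5
    y = rng.standard_normal(n)  # no real association
    x[0], y[0] = 30.0, -30.0   # a single point fabricating a correlation
    full, trimmed, dropped = sensitivity_rerun(x, y)
    assert dropped == [0]
    assert abs(trimmed.effect) < abs(full.effect)


# ---------------------------------------------------------------------------
# battery plumbing


def _synthetic_table(seed=0, n_norm=40, n_atyp=30, effect=True):
    rng = np.random.default_rng(seed)
    n = n_norm + n_atyp
    group = ["normative"] * n_norm + ["atypical"] * n_atyp
    ga = np.concatenate([rng.uniform(37, 42, n_norm),
                         rng.uniform(25, 36.9, n_atyp)])
    load = np.zeros(n)
    if effect:
        load[n_norm:] = rng.gamma(2, 1.0, n_atyp) * (37 - ga[n_norm:]) / 8
    out = 100 - 5 * load + 6 * rng.standard_normal(n)
    idx_noise = rng.gamma(1.5, 0.15, n)
    table = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": group,
        "pma_scan": rng.uniform(37, 45, n),
        "ga_birth": ga,
        "sex": rng.integers(0, 2, n),
        "motion": rng.gamma(4, 0.25, n),
        "imd": rng.uniform(1, 60, n),
        "outcome_cognitive": out,
        "outcome_language": 100 - 5 * load + 6 * rng.standard_normal(n),
        "outcome_motor": 100 + 10 * rng.standard_normal(n),
        "fa_plus": idx_noise,
        "fa_minus": idx_noise * 0.3 + 0.8 * load,
        "md_plus": idx_noise * 0.3 + load,
        "md_minus": rng.gamma(1.5, 0.1, n),
    })
    return table


def test_battery_report_shape_and_determinism():
    table = _synthetic_table()
    cfg = BatteryConfig(bootstrap_reps=50, prediction_resamples=20, seed=1)
    rep1 = run_full_battery(table, cfg)
    rep2 = run_full_battery(table, cfg)
    # 4 group comparisons + 2×4 GA + 2×12 outcome correlations
    assert len(rep1.tests) == 4 + 8 + 24
    pd.testing.assert_frame_equal(rep1.tests, rep2.tests)


def test_battery_detects_lesion_linked_structure():
    table = _synthetic_table(effect=True)
    cfg = BatteryConfig(bootstrap_reps=50, prediction_resamples=20, seed=1)
    rep = run_full_battery(table, cfg)
    t = rep.tests
    md_group = t[(t["family"] == "group_difference") &
                 (t["test"].str.startswith("md_plus"))]
    assert md_group["reject"].item()
    assert md_group["effect"].item() > 0.7
    # surviving outcome correlations get a regression follow-up
    assert len(rep.models) >= 1
    for model in rep.models.values():
        assert model.adj_r2_ci is not None
        assert model.adj_r2_ci[0] <= model.adj_r2_ci[1]


def test_battery_handles_missing_outcome_with_warning():
    table = _synthetic_table().drop(columns=["outcome_motor"])
    rep = run_full_battery(
        table, BatteryConfig(bootstrap_reps=30, prediction_resamples=10)
    )
    assert len(rep.warnings) >= 1
    assert len(rep.tests) == 4 + 8 + 16
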