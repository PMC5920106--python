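import numpy as np
import pytest
from scipy import stats as sps

from alphap1 import stats as st
from alphap1.errors import ConfigError, DegenerateDataError


# --- cluster permutation --------------------------------------------------


def test_identical_conditions_give_zero_t_and_no_clusters(rng):
    a = rng.standard_normal((8, 40))
    res = st.cluster_permutation_paired(a, a.copy(), np.arange(40.0), n_perm=500,
                                        seed=0)
    np.testing.assert_array_equal(res.t_obs, 0.0)
    assert res.clusters == []


def test_exact_enumeration_p_values_are_dyadic_and_match_monte_carlo(rng):
    n = 8
    a = rng.standard_normal((n, 50)) + np.r_[np.zeros(20), 0.9 * np.ones(12),
                                             np.zeros(18)]
    b = rng.standard_normal((n, 50))
    times = np.arange(50.0)
    exact = st.cluster_permutation_paired(a, b, times, n_perm=4000,
                                          method="exact")
    assert exact.exact and exact.n_perm == 256
    for c in exact.clusters:
        assert (c.p * 256) == pytest.approx(round(c.p * 256), abs=1e-9)
    mc = st.cluster_permutation_paired(a, b, times, n_perm=4000, seed=3,
                                       method="montecarlo")
    assert not mc.exact
    for ce, cm in zip(exact.clusters, mc.clusters):
        tol = 2 * np.sqrt(max(ce.p * (1 - ce.p), 1 / 4000) / 4000)
        assert abs(ce.p - cm.p) <= tol
    # auto mode switches to enumeration when 2^n <= n_perm
    auto = st.cluster_permutation_paired(a, b, times, n_perm=4000)
    assert auto.exact


def test_clusters_are_maximal_same_sign_runs(rng):
    n = 30
    a = rng.standard_normal((n, 60)) * 0.1
    b = a.copy()
    a[:, 10:20] += 1.0   # positive cluster
    a[:, 40:45] -= 1.0   # negative cluster
    res = st.cluster_permutation_paired(a, b, np.arange(60.0), n_perm=500, seed=1)
    signs = {c.sign for c in res.clusters}
    assert signs == {1, -1}
    pos = [c for c in res.clusters if c.sign == 1]
    assert any(c.start_idx == 10 and c.size == 10 for c in pos)
    # cluster significance rule: size strictly above the null 95th percentile
    for c in res.clusters:
        assert c.significant == (c.size > res.null_q95)


def test_permutation_test_is_invariant_to_subject_order_and_seeded(rng):
    a = rng.standard_normal((10, 30)) + 0.5
    b = rng.standard_normal((10, 30))
    times = np.arange(30.0)
    r1 = st.cluster_permutation_paired(a, b, times, n_perm=800, seed=9,
                                       method="montecarlo")
    r2 = st.cluster_permutation_paired(a, b, times, n_perm=800, seed=9,
                                       method="montecarlo")
    assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]
    perm = rng.permutation(10)
    r3 = st.cluster_permutation_paired(a[perm], b[perm], times, n_perm=800,
                                       seed=9, method="exact")
    r4 = st.cluster_permutation_paired(a, b, times, n_perm=800, seed=9,
                                       method="exact")
    assert [c.p for c in r3.clusters] == [c.p for c in r4.clusters]
    np.testing.assert_allclose(r3.t_obs, r4.t_obs, atol=1e-12)


def test_cluster_schema_and_warning_paths(rng):
    a = rng.standard_normal((6, 20))
    with pytest.raises(ConfigError):
        st.cluster_permutation_paired(a, a[:, :10], np.arange(20.0))
    with pytest.warns(UserWarning, match="n_perm"):
        st.cluster_permutation_paired(a, a + 0.1, np.arange(20.0), n_perm=50,
                                      seed=0, method="montecarlo")


# --- paired t -------------------------------------------------------------


def test_paired_t_constant_shift_centres_the_ci(rng):
    # exactly shared noise: the difference is the constant shift and the CI
    # degenerates to a point at it
    a = rng.standard_normal(12)
    res = st.paired_t(a + 1.3, a)
    assert res.mean_diff == pytest.approx(1.3)
    assert (res.ci_low, res.ci_high) == (pytest.approx(1.3), pytest.approx(1.3))
    # independent noise: the CI is still centred on the mean difference
    b = a + 1.3 + 0.1 * rng.standard_normal(12)
    res = st.paired_t(b, a)
    assert (res.ci_low + res.ci_high) / 2 == pytest.approx(res.mean_diff,
                                                           abs=1e-9)


def test_paired_t_matches_textbook_formula_on_hand_example():
    a = np.array([2.0, 4.0, 9.0])
    b = np.array([1.0, 2.0, 3.0])
    d = a - b                     # (1, 2, 6)
    sd = d.std(ddof=1)            # sqrt(7)
    t_hand = d.mean() / (sd / np.sqrt(3))
    p_hand = 2 * sps.t.sf(abs(t_hand), df=2)
    res = st.paired_t(a, b)
    assert res.t == pytest.approx(t_hand, abs=1e-12)
    assert res.df == 2
    assert res.p == pytest.approx(p_hand, abs=1e-12)


def test_paired_t_p_values_are_uniform_under_the_null(rng):
    ps = []
    for _ in range(400):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        ps.append(st.paired_t(x, y).p)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_paired_t_degenerate_differences_raise():
    a = np.array([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateDataError):
        st.paired_t(a, a.copy())  # identically zero differences


# --- RM-ANOVA -------------------------------------------------------------


def test_anova_zero_effects_for_identical_conditions(rng):
    subj = rng.standard_normal(10)
    y = np.repeat(subj, 4).reshape(10, 2, 2)
    table = st.rm_anova_2x2(y).set_index("effect")
    for eff in ("A", "B", "A:B"):
        assert table.loc[eff, "F"] == pytest.approx(0.0, abs=1e-18)


def test_anova_agrees_with_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    y = rng.standard_normal((9, 2, 2)) + rng.standard_normal((9, 1, 1))
    ours = st.rm_anova_2x2(y).set_index("effect")
    rows = [
        {"subject": s, "A": f"a{i}", "B": f"b{j}", "y": y[s, i, j]}
        for s in range(9) for i in range(2) for j in range(2)
    ]
    theirs = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["A", "B"],
                         subject="subject", detailed=True)
    lookup = {"A": "A", "B": "B", "A * B": "A:B"}
    for _, row in theirs.iterrows():
        if row["Source"] in lookup:
            assert ours.loc[lookup[row["Source"]], "F"] == \
                pytest.approx(row["F"], rel=1e-9)
            assert ours.loc[lookup[row["Source"]], "p"] == \
                pytest.approx(row["p_unc"], rel=1e-9)


def test_anova_missing_cells_are_rejected(rng):
    y = rng.standard_normal((6, 2, 2))
    y[2, 1, 0] = np.nan
    with pytest.raises(Exception, match="missing"):
        st.rm_anova_2x2(y)


# --- bootstrap correlations ----------------------------------------------


def test_spearman_perfect_monotone_relationship():
    x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
    res = st.spearman_bootstrap(x, np.exp(x / 5.0), n_boot=2000, seed=0)
    assert res.rho == pytest.approx(1.0)
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)


def test_spearman_matches_hand_rank_computation():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])
    # d = (-1, 1, -1, 1); rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.6
    res = st.spearman_bootstrap(x, y, n_boot=500, seed=1)
    assert res.rho == pytest.approx(0.6)


def test_spearman_is_seeded_and_guards_constants(rng):
    x, y = rng.standard_normal((2, 12))
    r1 = st.spearman_bootstrap(x, y, n_boot=1000, seed=5)
    r2 = st.spearman_bootstrap(x, y, n_boot=1000, seed=5)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
    with pytest.raises(DegenerateDataError):
        st.spearman_bootstrap(np.ones(8), y[:8])
    with pytest.raises(ConfigError):
        st.spearman_bootstrap(x[:3], y[:3])


def test_correlation_difference_trivial_and_degenerate_cases(rng):
    x = rng.standard_normal(10)
    y = rng.standard_normal(10)
    same = st.correlation_difference(x, y, y.copy(), n_boot=1000, seed=2)
    assert same.delta_rho == pytest.approx(0.0)
    assert same.ci_low <= 0.0 <= same.ci_high
    perfect = st.correlation_difference(x, x.copy(), -x, n_boot=1000, seed=2)
    assert perfect.delta_rho == pytest.approx(2.0)
    assert (perfect.ci_low, perfect.ci_high) == (2.0, 2.0)


def test_correlation_difference_matches_naive_double_loop_bootstrap(rng):
    n, n_boot, seed = 8, 300, 77
    x, yl, yr = rng.standard_normal((3, n))
    res = st.correlation_difference(x, yl, yr, n_boot=n_boot, seed=seed)
    # naive oracle: same subject resampling stream, scipy's spearman per draw
    idx = np.random.default_rng(seed).integers(0, n, size=(n_boot, n))
    deltas = []
    for row in idx:
        if (np.ptp(x[row]) == 0 or np.ptp(yl[row]) == 0
                or np.ptp(yr[row]) == 0):
            continue
        deltas.append(sps.spearmanr(x[row], yl[row])[0]
                      - sps.spearmanr(x[row], yr[row])[0])
    deltas = np.array(deltas)
    np.testing.assert_allclose(np.sort(res.boot_deltas), np.sort(deltas),
                               atol=1e-12)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    assert res.ci_low == pytest.approx(lo, abs=1e-12)
    assert res.ci_high == pytest.approx(hi, abs=1e-12)


def test_correlation_difference_p_is_two_sided_fraction(rng):
    x = rng.standard_normal(12)
    yl = x + 0.3 * rng.standard_normal(12)
    yr = rng.standard_normal(12)
    res = st.correlation_difference(x, yl, yr, n_boot=2000, seed=4)
    frac = 2 * min((res.boot_deltas <= 0).mean(), (res.boot_deltas >= 0).mean())
    assert res.p == pytest.approx(min(frac, 1.0))
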