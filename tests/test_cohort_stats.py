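from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bmquant.cohort_stats import (
    benjamini_hochberg,
    jonckheere_terpstra,
    roc_analysis,
    run_validation,
    spearman_corr,
    wilcoxon_rank_sum,
)
from bmquant.synthetic_data import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles

def rank_average(x):
    """Average ranks via full sort (independent of scipy.rankdata)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = rank_average(x), rank_average(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, 2 * sps.t.sf(abs(t), df=n - 2)


def jt_oracle_statistic(groups):
    """Pairwise-count JT, written as explicit loops."""
    jt = 0.0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            for u in groups[gi]:
                for v in groups[gj]:
                    if u < v:
                        jt += 1.0
                    elif u == v:
                        jt += 0.5
    return jt


def jt_exact_enumeration(values, sizes, alternative="two_sided"):
    """Full enumeration over all distinct assignments of values to ordered groups."""
    values = list(values)
    n = len(values)
    idx_all = set(range(n))
    stats_all = []
    for g1 in combinations(range(n), sizes[0]):
        rest1 = idx_all - set(g1)
        for g2 in combinations(sorted(rest1), sizes[1]):
            g3 = sorted(rest1 - set(g2))
            groups = [
                [values[i] for i in g1],
                [values[i] for i in g2],
                [values[i] for i in g3],
            ]
            stats_all.append(jt_oracle_statistic(groups))
    stats_all = np.array(stats_all)
    obs = jt_oracle_statistic(
        [values[: sizes[0]], values[sizes[0] : sizes[0] + sizes[1]], values[sizes[0] + sizes[1] :]]
    )
    mu = stats_all.mean()
    if alternative == "increasing":
        return np.mean(stats_all >= obs - 1e-12)
    if alternative == "decreasing":
        return np.mean(stats_all <= obs + 1e-12)
    return np.mean(np.abs(stats_all - mu) >= abs(obs - mu) - 1e-12)


def auc_pairwise_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------------------

class TestSpearman:
    def test_comonotone(self):
        rho, p = spearman_corr([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        rho, _ = spearman_corr([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 5], dtype=float)
        rho, p = spearman_corr(x, y)
        orho, op = spearman_oracle(x, y)
        assert rho == pytest.approx(orho, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_with_ties_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, size=20).astype(float)
        y = rng.integers(0, 8, size=20).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            pytest.skip("degenerate draw")
        rho, p = spearman_corr(x, y)
        orho, op = spearman_oracle(x, y)
        assert rho == pytest.approx(orho, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-10)

    def test_constant_input_undefined(self):
        rho, p = spearman_corr([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)

    def test_matches_scipy(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        rho, p = spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, _ = spearman_corr(x, y)
        rho2, _ = spearman_corr(np.exp(2 * x), y)  # strictly monotone transform
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestWilcoxon:
    def test_most_extreme_small_exact(self):
        # a=(1,2), b=(10,20): 6 labelings, the two extremes are as-or-more extreme
        _, p = wilcoxon_rank_sum([1, 2], [10, 20])
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 60)
        b = rng.normal(2.5, 1, 60)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-3

    def test_asymptotic_matches_scipy_mannwhitney(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 10, 25).astype(float)
        b = rng.integers(2, 12, 30).astype(float)
        w, p = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        # U = W - n_a(n_a+1)/2
        assert w - 25 * 26 / 2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestJonckheereTerpstra:
    def test_strictly_increasing_attains_max(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], alternative="increasing")
        assert res.jt_statistic == 12.0  # = sum n_i n_j
        assert res.method == "exact_permutation"
        assert res.p_value < 0.05

    def test_reversal_is_zero(self):
        res = jonckheere_terpstra([[5, 6], [3, 4], [1, 2]], alternative="increasing")
        assert res.jt_statistic == 0.0
        assert res.p_value > 0.9

    @pytest.mark.parametrize("alternative", ["increasing", "decreasing", "two_sided"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_full_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        values = rng.permutation(np.arange(1, 10)).astype(float)  # all distinct
        groups = [values[:3], values[3:6], values[6:]]
        res = jonckheere_terpstra(groups, alternative=alternative)
        oracle_p = jt_exact_enumeration(values, (3, 3, 3), alternative)
        assert res.method == "exact_permutation"
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_statistic_matches_pairwise_oracle_with_ties(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0], [3.0, 3.0, 5.0]]
        res = jonckheere_terpstra(groups)
        assert res.jt_statistic == pytest.approx(jt_oracle_statistic(groups))

    def test_normal_approx_close_to_permutation_monte_carlo(self):
        # n = 15 takes the asymptotic path; compare against a 20k-draw
        # Monte Carlo permutation reference (within 0.02 absolute)
        rng = np.random.default_rng(12)
        values = rng.normal(size=15)
        sizes = (5, 5, 5)
        groups = [values[:5], values[5:10], values[10:]]
        res = jonckheere_terpstra(groups, alternative="two_sided")
        assert res.method == "normal_approx"
        obs = jt_oracle_statistic([list(g) for g in groups])
        draws = np.empty(20_000)
        for b in range(draws.size):
            perm = rng.permutation(values)
            draws[b] = jt_oracle_statistic(
                [list(perm[:5]), list(perm[5:10]), list(perm[10:])]
            )
        mu = draws.mean()
        mc_p = np.mean(np.abs(draws - mu) >= abs(obs - mu) - 1e-12)
        assert res.p_value == pytest.approx(mc_p, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1.0], []])

    def test_bad_alternative_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1], [2]], alternative="sideways")

    def test_jt_bounds_property(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            sizes = rng.integers(2, 6, size=3)
            groups = [rng.normal(size=s) for s in sizes]
            res = jonckheere_terpstra(groups)
            max_jt = sum(
                sizes[i] * sizes[j] for i in range(3) for j in range(i + 1, 3)
            )
            assert 0 <= res.jt_statistic <= max_jt
            assert 0 <= res.p_value <= 1


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=100)
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0
        assert res.cut_point == pytest.approx(10.0)
        assert res.accuracy == 1.0

    def test_null_large_balanced(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=2000)
        labels = np.r_[np.ones(1000), np.zeros(1000)].astype(int)
        res = roc_analysis(scores, labels, n_boot=50)
        assert res.auc == pytest.approx(0.5, abs=0.04)

    def test_six_point_tie_matches_pairwise_oracle(self):
        scores = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        labels = [0, 0, 1, 1, 0, 1]
        res = roc_analysis(scores, labels, n_boot=100)
        assert res.auc == pytest.approx(auc_pairwise_oracle(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_auc_u_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        scores = rng.integers(0, 6, size=n).astype(float)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            pytest.skip("single class")
        res = roc_analysis(scores, labels, n_boot=20)
        assert res.auc == pytest.approx(auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_cut_point_maximizes_sens_plus_spec_smallest_tie(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 1, 0, 1]
        res = roc_analysis(scores, labels, n_boot=20)
        # exhaustive check over observed thresholds
        best = max(
            (np.mean([s >= t for s, l in zip(scores, labels) if l == 1])
             + np.mean([s < t for s, l in zip(scores, labels) if l == 0]), -t)
            for t in scores
        )
        assert res.sensitivity + res.specificity == pytest.approx(best[0])
        assert res.cut_point == pytest.approx(-best[1])

    def test_ci_brackets_auc_and_is_seed_stable(self):
        rng = np.random.default_rng(10)
        scores = np.r_[rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)]
        labels = np.r_[np.zeros(40), np.ones(40)].astype(int)
        r1 = roc_analysis(scores, labels, n_boot=500, seed=7)
        r2 = roc_analysis(scores, labels, n_boot=500, seed=7)
        assert r1.ci_95 == r2.ci_95
        assert r1.ci_95[0] <= r1.auc <= r1.ci_95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=12)
        ours = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref)


class TestRunValidation:
    def test_comonotone_cohort_all_correlations_one(self):
        spec = CohortSpec(
            n=30,
            rank_corr=np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]),
            seed=1,
        )
        cohort = generate_cohort(spec)
        report = run_validation(cohort, n_boot=50, seed=0)
        corr = report["correlations"]
        assert np.allclose(corr["mtv_r_infiltration"], 1.0)
        assert np.allclose(corr["tlg_r_b2m"], 1.0)
        trend = report["trend"]
        assert (trend["p_value"] < 0.001).all()

    def test_missing_column_named_in_error(self):
        cohort = generate_cohort(CohortSpec(n=10, seed=0)).drop(
            columns=["beta2_microglobulin"]
        )
        with pytest.raises(ValueError, match="beta2_microglobulin"):
            run_validation(cohort, n_boot=10)

    def test_report_schema(self):
        cohort = generate_cohort(CohortSpec(n=35, seed=3, group_noise=0.1))
        report = run_validation(cohort, n_boot=50, seed=0)
        assert set(report) == {"correlations", "trend", "cytogenetics", "roc_mtv", "roc_tlg"}
        roc = report["roc_mtv"]
        for col in ("auc", "ci_low", "ci_high", "p_vs_half", "cut_point",
                    "sensitivity", "specificity", "accuracy"):
            assert col in roc.columns
        assert len(report["correlations"]) == 6  # six shipped approaches
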