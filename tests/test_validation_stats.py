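"""Unit and oracle tests for the validation statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ppgl_grading import (
    ConvergenceError,
    DegenerateTableError,
    DomainError,
    compare_groups,
    contingency_test,
    delong_compare,
    fit_cox,
    km_estimate,
    log_rank,
    pearson_mfs_corr,
    roc_auc,
    youden_cutoff,
)

from conftest import COX_FIXTURES, bootstrap_auc_diff_p, grid_search_cox


# ---------------------------------------------------------------------------
# contingency


class TestContingency:
    def test_identical_proportions_give_p_one(self):
        stat, p = contingency_test([[10, 10], [10, 10]], method="yates")
        assert stat == 0.0
        assert p == 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[51, 6], [10, 5]])
        _, p = contingency_test(table, method="fisher")
        # oracle: enumerate all tables with the observed margins and sum
        # the probabilities of those no more likely than the observed one
        r0, r1 = table.sum(axis=1)
        c0 = table[:, 0].sum()
        n = table.sum()
        obs = sps.hypergeom.pmf(table[0, 0], n, r0, c0)
        total = 0.0
        for a in range(max(0, c0 - r1), min(r0, c0) + 1):
            pa = sps.hypergeom.pmf(a, n, r0, c0)
            if pa <= obs * (1 + 1e-9):
                total += pa
        assert p == pytest.approx(total, rel=1e-9)

    def test_auto_switches_to_fisher_on_small_expected_count(self):
        table = [[51, 6], [10, 5]]  # min expected = 11*15/72 < 5
        _, p_auto = contingency_test(table, method="auto")
        _, p_fisher = contingency_test(table, method="fisher")
        assert p_auto == p_fisher

    def test_yates_never_exceeds_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2))
            y, py = contingency_test(t, method="yates")
            u, pu = contingency_test(t, method="pearson")
            assert y <= u + 1e-12
            assert 0 <= py <= 1 and 0 <= pu <= 1

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            contingency_test([[0, 0], [5, 7]])

    def test_rxc_uses_pearson(self):
        t = [[10, 2], [8, 4], [3, 9]]
        stat, p = contingency_test(t, method="auto")
        ref = sps.chi2_contingency(np.array(t), correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestCompareGroups:
    def test_identical_groups_symmetry(self):
        u, p = compare_groups([1, 2, 3], [1, 2, 3], method="mann_whitney")
        assert u == pytest.approx(3 * 3 / 2)
        assert p == 1.0

    def test_exact_mann_whitney_matches_permutation_oracle(self):
        a, b = [1, 2, 3], [4, 5, 6]
        _, p = compare_groups(a, b, method="mann_whitney")
        # oracle: enumerate all 20 assignments of ranks to group a
        pooled = sorted(a + b)
        u_obs = sum(x > y for x in a for y in b)
        n1 = len(a)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), n1):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(x > y for x in ga for y in gb)
            total += 1
            if min(u, n1 * 3 - u) <= min(u_obs, n1 * 3 - u_obs):
                count += 1
        assert p == pytest.approx(count / total)  # = 0.1

    def test_degenerate_all_identical(self):
        u, p = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0], method="mann_whitney")
        assert p == 1.0
        t, p = compare_groups([2.0, 2.0], [2.0, 2.0], method="t_test")
        assert (t, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            compare_groups([], [1.0])


# ---------------------------------------------------------------------------
# Cox


class TestCox:
    def test_three_subject_closed_form(self):
        res = fit_cox([1, 2, 3], [1, 1, 0], [1, 0, 1], ties="breslow")
        assert res.hr[0] == pytest.approx(2 ** -0.5, abs=1e-8)

    def test_symmetric_design_gives_null_coefficient(self):
        res = fit_cox([1, 1, 2, 2], [1, 1, 1, 1], [1, 0, 0, 1])
        assert res.coef[0] == pytest.approx(0.0, abs=1e-10)
        assert res.hr[0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("times, events, x", COX_FIXTURES)
    def test_matches_grid_search_of_partial_likelihood(self, times, events, x):
        res = fit_cox(times, events, x, ties="breslow")
        beta_grid = grid_search_cox(times, events, x)
        assert abs(res.coef[0] - beta_grid) < 1e-4

    def test_wald_ci_consistent_with_coef_and_se(self):
        res = fit_cox([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 0], [1, 0, 1, 0, 1, 1])
        assert res.ci_low[0] == pytest.approx(math.exp(res.coef[0] - 1.96 * res.se[0]))
        assert res.ci_high[0] == pytest.approx(math.exp(res.coef[0] + 1.96 * res.se[0]))
        assert res.ci_low[0] <= res.hr[0] <= res.ci_high[0]

    def test_efron_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 80
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = rng.exponential(10 / np.exp(0.7 * x1 - 0.3 * x2))
        c = rng.exponential(15, n)
        times = np.minimum(t, c)
        events = t <= c
        res = fit_cox(times, events, np.column_stack([x1, x2]),
                      names=("x1", "x2"), ties="efron")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": times, "E": events, "x1": x1, "x2": x2}),
            duration_col="T", event_col="E",
        )
        np.testing.assert_allclose(res.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(res.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_complete_separation_raises(self):
        # every event in the x=1 group with x=1 subjects always at risk first
        with pytest.raises(ConvergenceError):
            fit_cox([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0])

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(DomainError):
            fit_cox([1, 2, 3], [1, 1, 0], [1, 1, 1])

    def test_no_events_rejected(self):
        with pytest.raises(DomainError):
            fit_cox([1, 2], [0, 0], [0, 1])


# ---------------------------------------------------------------------------
# ROC / DeLong / Youden


class TestRoc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties(self):
        assert roc_auc([1, 1, 1, 1], [0, 0, 1, 1]).auc == 0.5

    def test_pairwise_counting_oracle(self):
        scores = [3, 1, 2, 4, 2]
        labels = [0, 0, 1, 1, 0]
        res = roc_auc(scores, labels)
        pos = [s for s, y in zip(scores, labels) if y == 1]
        neg = [s for s, y in zip(scores, labels) if y == 0]
        expect = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert res.auc == pytest.approx(expect)  # 4.5 / 6

    def test_auc_equals_mann_whitney_u_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = rng.normal(size=30) + y
            u, _ = compare_groups(s[y == 1], s[y == 0], method="mann_whitney")
            m, n = int(y.sum()), int((1 - y).sum())
            assert roc_auc(s, y).auc == pytest.approx(u / (m * n))

    def test_operating_points_monotone(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        res = roc_auc(s, y)
        assert np.all(np.diff(res.sensitivity) <= 1e-12)
        assert np.all(np.diff(res.specificity) >= -1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        s = [1.0, 2.0, 3.0, 4.0]
        y = [0, 1, 0, 1]
        a1, a2, diff, p = delong_compare(s, s, y)
        assert diff == 0.0
        assert p == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 15 + [1] * 10)
        s1 = rng.normal(size=25) + y
        s2 = 0.5 * s1 + rng.normal(size=25)
        a1, a2, d12, p12 = delong_compare(s1, s2, y)
        b2, b1, d21, p21 = delong_compare(s2, s1, y)
        assert d12 == pytest.approx(-d21)
        assert p12 == pytest.approx(p21)
        assert (a1, a2) == (b1, b2)

    def test_agrees_with_stratified_bootstrap(self):
        # a single n=40 cohort here; the 20-cohort sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(12)
        y = np.array([0] * 28 + [1] * 12)
        s1 = rng.normal(size=40) + 1.2 * y
        s2 = 0.6 * s1 + rng.normal(size=40, scale=0.8)
        _, _, diff, p = delong_compare(s1, s2, y)
        p_boot = bootstrap_auc_diff_p(s1, s2, y, n_boot=10_000, rng=rng)
        assert abs(p - p_boot) < 0.1


class TestYouden:
    def test_perfect_split(self):
        cutoff, j, sens, spec = youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert (cutoff, j, sens, spec) == (3.0, 1.0, 1.0, 1.0)

    def test_uninformative_score_ties_to_smallest(self):
        cutoff, j, _, _ = youden_cutoff([1, 1, 1, 1], [0, 0, 1, 1])
        assert cutoff == 1.0
        assert j == 0.0

    def test_matches_brute_force(self):
        scores = [0, 1, 2, 2, 3, 4]
        labels = [0, 0, 0, 1, 1, 1]
        cutoff, j, sens, spec = youden_cutoff(scores, labels)
        s, y = np.asarray(scores, float), np.asarray(labels)
        best_j, best_c = -2.0, None
        for c in sorted(set(scores)):
            tpr = (s[y == 1] >= c).mean()
            fpr = (s[y == 0] >= c).mean()
            if tpr - fpr > best_j + 1e-12:
                best_j, best_c = tpr - fpr, c
        assert j == pytest.approx(best_j)
        assert cutoff == best_c

    def test_j_equals_tpr_minus_fpr_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            y = rng.integers(0, 2, 25)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 6, 25).astype(float)
            _, j, sens, spec = youden_cutoff(s, y)
            assert j == pytest.approx(sens + spec - 1)
            js = [
                (s[y == 1] >= c).mean() - (s[y == 0] >= c).mean()
                for c in np.unique(s)
            ]
            assert j == pytest.approx(max(js))


# ---------------------------------------------------------------------------
# survival


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = km_estimate([3, 5, 8], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_curves_non_increasing_and_start_at_one(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(1, 30)
            t = rng.exponential(10, n)
            e = rng.integers(0, 2, n)
            curve = km_estimate(t, e)
            assert curve.survival[0] == 1.0
            assert np.all(np.diff(curve.survival) <= 1e-12)
            assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_scale_equivariance_and_order_invariance(self):
        t = np.array([2.0, 5.0, 5.0, 9.0, 12.0])
        e = np.array([1, 0, 1, 1, 0])
        base = km_estimate(t, e)
        scaled = km_estimate(t * 12.0, e)  # months -> years-of-months
        np.testing.assert_allclose(scaled.times, base.times * 12.0)
        np.testing.assert_allclose(scaled.survival, base.survival)
        perm = np.random.default_rng(1).permutation(t.size)
        shuffled = km_estimate(t[perm], e[perm])
        np.testing.assert_allclose(shuffled.survival, base.survival)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_p_one(self):
        g = ([1, 2, 3, 4], [1, 0, 1, 1])
        stat, p = log_rank([g, g])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_matches_hypergeometric_closed_form(self):
        # one event at t=1 in group 0; group 1 censored later.
        # O - E = 1 - 1/2, Var = 1/4, chi2 = 1.
        stat, p = log_rank([([1], [1]), ([2], [0])])
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(2 * sps.norm.sf(1.0))

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            log_rank([([1, 2], [1, 0]), ([], [])])

    def test_requires_an_event(self):
        with pytest.raises(DomainError):
            log_rank([([1], [0]), ([2], [0])])


class TestPearson:
    def test_perfect_inverse_linearity(self):
        r, _ = pearson_mfs_corr([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_perfect_linearity(self):
        r, p = pearson_mfs_corr([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson_mfs_corr([1, 1, 1], [3, 2, 1])
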