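"""Global and extreme-risk calibration tests: statistics, sets, p-values."""

import numpy as np
import pytest

from coxcal import (
    er_pvalue,
    er_statistic,
    er_test,
    extreme_sets,
    fit_cox,
    gb_test,
    grouped_sums,
    joint_tests,
    scale_h,
    simulate_cohort,
)
from coxcal.calibration import GroupedMartingales
from coxcal.cox import ResidualSet, extended_information
from coxcal.grouping import assign_groups, risk_scores
from coxcal.simulate import SimulationConfig


def _gm(H, sigma, reference=6, D=11):
    ids = np.array([g for g in range(1, D + 1) if g != reference])
    return GroupedMartingales(H=np.asarray(H, float), sigma=np.asarray(sigma, float),
                              group_ids=ids, reference_group=reference)


class TestGroupedSums:
    def test_zero_residuals_give_zero_sums(self, small_null_fit, small_null_cohort):
        grp = assign_groups(risk_scores(small_null_fit, small_null_cohort), 11, reference_group=11)
        r = ResidualSet(
            martingale=np.zeros(small_null_cohort.n), cox_snell=np.zeros(small_null_cohort.n)
        )
        np.testing.assert_array_equal(grouped_sums(r, grp), np.zeros(10))

    def test_omitted_group_is_minus_sum_of_retained(self, small_null_fit, small_null_cohort):
        from coxcal.cox import residuals

        grp = assign_groups(risk_scores(small_null_fit, small_null_cohort), 11, reference_group=11)
        r = residuals(small_null_fit, small_null_cohort)
        H = grouped_sums(r, grp)
        omitted = r.martingale[grp.labels == 11].sum()
        assert abs(omitted + H.sum()) < 1e-8


class TestScaleH:
    def test_correlation_input_unchanged(self):
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        gm = scale_h(_gm([1.2, -0.7], sigma, reference=2, D=3))
        np.testing.assert_allclose(gm.H_tilde, [1.2, -0.7])
        np.testing.assert_allclose(gm.sigma_tilde, sigma)

    def test_diagonal_scaling(self):
        gm = scale_h(_gm([2.0, 2.0], 4.0 * np.eye(2), reference=2, D=3))
        np.testing.assert_allclose(gm.H_tilde, [1.0, 1.0])
        np.testing.assert_allclose(gm.sigma_tilde, np.eye(2))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_h(_gm([1.0, 1.0], np.diag([1.0, 0.0]), reference=2, D=3))

    def test_scaled_components_have_unit_variance_under_null(self):
        # distributional check: H~ components over repeated null cohorts
        from coxcal.calibration import _GroupedMachinery

        cfg = SimulationConfig(n=1000, model="g01", p=2, target_event_rate=0.3).resolved()
        root = np.random.SeedSequence(3131)
        hts = []
        for child in root.spawn(600):
            data = simulate_cohort(cfg, rng=child)
            fit = fit_cox(data)
            gm = scale_h(_GroupedMachinery(fit, data, 5).martingales(reference=3))
            hts.append(gm.H_tilde)
        v = np.array(hts).var(axis=0)
        assert np.all(np.abs(v - 1.0) < 0.15)


class TestExtremeSets:
    def test_d11_enumeration(self):
        sets = extreme_sets(11)
        assert [list(s) for s in sets] == [
            [1, 11],
            [1, 2, 10, 11],
            [1, 2, 3, 9, 10, 11],
            [1, 2, 3, 4, 8, 9, 10, 11],
            [1, 2, 3, 4, 5, 7, 8, 9, 10, 11],
        ]

    def test_d5_enumeration(self):
        assert [list(s) for s in extreme_sets(5)] == [[1, 5], [1, 2, 4, 5]]

    def test_sets_nested_symmetric_and_exclude_median(self):
        for D in (5, 7, 9, 11, 13):
            sets = extreme_sets(D)
            med = (D + 1) // 2
            prev = set()
            for s in sets:
                s = set(map(int, s))
                assert med not in s
                assert prev <= s
                assert {D + 1 - g for g in s} == s  # symmetric about the median
                prev = s
            assert len(sets[-1]) == D - 1

    def test_even_D_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extreme_sets(10)


class TestERStatistic:
    def test_single_nonzero_component(self):
        h = 1.7
        H_tilde = np.zeros(10)
        H_tilde[0] = h
        gm = _gm(H_tilde, np.eye(10))
        gm = scale_h(gm)
        t_max, per_set = er_statistic(gm, extreme_sets(11))
        vals = [v for _, _, v in per_set]
        np.testing.assert_allclose(vals, [h**2 / nc for nc in (2, 4, 6, 8, 10)])
        assert t_max == pytest.approx(h**2 / 2)

    def test_zero_vector_gives_zero(self):
        gm = scale_h(_gm(np.zeros(10), np.eye(10)))
        t_max, _ = er_statistic(gm, extreme_sets(11))
        assert t_max == 0.0

    def test_invariant_to_symmetric_tail_swap(self):
        rng = np.random.default_rng(5)
        H = rng.standard_normal(10)
        gm = scale_h(_gm(H, np.eye(10)))
        t1, _ = er_statistic(gm, extreme_sets(11))
        gm2 = scale_h(_gm(H[::-1], np.eye(10)))
        t2, _ = er_statistic(gm2, extreme_sets(11))
        assert t1 == pytest.approx(t2)


class TestERPvalue:
    def test_zero_statistic_gives_p_one(self):
        assert er_pvalue(0.0, np.eye(10), n_replicates=200, seed=1) == 1.0

    def test_nonincreasing_in_t_max(self):
        sig = np.eye(10)
        ps = [er_pvalue(t, sig, n_replicates=500, seed=3) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_strictly_positive_and_bounded(self):
        p = er_pvalue(1e9, np.eye(10), n_replicates=500, seed=4)
        assert 0.0 < p <= 1.0 / 501 + 1e-12

    def test_invalid_sigma_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.9  # asymmetric
        with pytest.raises(ValueError):
            er_pvalue(1.0, bad, n_replicates=200, seed=0)
        with pytest.raises(ValueError):
            er_pvalue(1.0, np.array([[1.0, 2.0], [2.0, 1.0]]), n_replicates=200, seed=0)


class TestEndToEnd:
    def test_er_result_reproducible_bitwise(self, small_null_fit, small_null_cohort):
        a = er_test(small_null_fit, small_null_cohort, D=11, n_replicates=300, seed=12)
        b = er_test(small_null_fit, small_null_cohort, D=11, n_replicates=300, seed=12)
        assert a.t_max == b.t_max
        assert a.p_value == b.p_value
        assert a.per_set_stats == b.per_set_stats
        np.testing.assert_array_equal(a.gm.H, b.gm.H)

    def test_er_requires_odd_D(self, small_null_fit, small_null_cohort):
        with pytest.raises(ValueError, match="odd"):
            er_test(small_null_fit, small_null_cohort, D=10, n_replicates=200, seed=0)

    def test_er_omits_median_group_gb_omits_last(self, small_null_fit, small_null_cohort):
        er = er_test(small_null_fit, small_null_cohort, D=11, n_replicates=200, seed=0)
        gb = gb_test(small_null_fit, small_null_cohort, D=11)
        assert er.grouping.reference_group == 6
        assert gb.grouping.reference_group == 11
        assert list(er.gm.group_ids) == [1, 2, 3, 4, 5, 7, 8, 9, 10, 11]

    def test_joint_tests_match_standalone(self, small_null_fit, small_null_cohort):
        gb1, er1 = joint_tests(small_null_fit, small_null_cohort, D=11, n_replicates=300, seed=8)
        gb2 = gb_test(small_null_fit, small_null_cohort, D=11)
        er2 = er_test(small_null_fit, small_null_cohort, D=11, n_replicates=300, seed=8)
        assert gb1.statistic == pytest.approx(gb2.statistic, rel=1e-12)
        assert gb1.p_value == pytest.approx(gb2.p_value, rel=1e-12)
        assert er1.t_max == pytest.approx(er2.t_max, rel=1e-12)
        assert er1.p_value == er2.p_value

    def test_gb_simulation_pvalue_close_to_chisq(self, small_null_fit, small_null_cohort):
        asym = gb_test(small_null_fit, small_null_cohort, D=11)
        sim = gb_test(
            small_null_fit,
            small_null_cohort,
            D=11,
            p_value_method="simulation",
            n_replicates=4000,
            seed=5,
        )
        assert abs(asym.p_value - sim.p_value) < 0.05

    def test_gb_statistic_nonnegative_with_correct_df(self, small_null_fit, small_null_cohort):
        gb = gb_test(small_null_fit, small_null_cohort, D=11)
        assert gb.statistic >= 0
        assert gb.df == 10
        assert 0 <= gb.p_value <= 1

    def test_collapse_reduces_df(self):
        cfg = SimulationConfig(n=400, model="g01", p=5, target_event_rate=0.1, seed=55)
        data = simulate_cohort(cfg)  # ~40 events: the 5-events rule must fire
        fit = fit_cox(data)
        gb = gb_test(fit, data, D=11, collapse=True)
        assert gb.df < 10
        assert np.all(gb.grouping.expected_events >= 5)


@pytest.fixture(scope="module")
def oracle_case():
    cfg = SimulationConfig(n=80, model="g01", p=3, target_event_rate=0.4, seed=20240515)
    data = simulate_cohort(cfg)
    fit = fit_cox(data, ties="breslow")
    grp = assign_groups(risk_scores(fit, data), 5, reference_group=5)
    return data, fit, grp


class TestExternalSurvivalOracle:
    """Frozen cross-check against the R 'survival' package recipe.

    The fixture cohort (n=80, 3 SNPs, 40% event rate, seed 20240515) was
    fitted with coxph(ties="breslow"); the indicator-augmented model was
    then evaluated with the coefficients frozen via iter.max=0 and the
    covariance of the grouped martingale sums extracted by inverting the
    gamma submatrix of vcov(). The resulting beta, H and Sigma_hat are
    frozen below (R survival 3.8-3).
    """

    R_BETA = np.array([0.4404829043, 0.1856983243, 0.4640059158])
    R_H = np.array([0.0752802628, -2.9877894929, 4.1548212218, 2.7758665542])
    R_SIGMA = np.array(
        [
            [2.24449819920, -1.646250140677, -1.014111180824, -0.41739504548],
            [-1.64625014068, 3.604646295443, -0.877378759183, -1.45297839193],
            [-1.01411118082, -0.877378759183, 3.717813430799, -0.65555575931],
            [-0.41739504548, -1.452978391928, -0.655555759310, 4.98764184766],
        ]
    )

    def test_beta_matches_r(self, oracle_case):
        _, fit, _ = oracle_case
        np.testing.assert_allclose(fit.beta, self.R_BETA, atol=2e-7)

    def test_sigma_and_H_match_r_recipe(self, oracle_case):
        data, fit, grp = oracle_case
        ext = extended_information(fit, data, grp)
        np.testing.assert_allclose(ext.score_gamma, self.R_H, atol=1e-7)
        np.testing.assert_allclose(ext.sigma_hat, self.R_SIGMA, atol=1e-6)
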