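"""Cox model fitting, Breslow baseline, residuals and extended information."""

import numpy as np
import pandas as pd
import pytest

from coxcal import (
    SurvivalDataset,
    extended_information,
    fit_cox,
    residuals,
    simulate_cohort,
)
from coxcal.cox import ConvergenceError, SingularityError, extended_loglik
from coxcal.grouping import assign_groups, risk_scores
from coxcal.simulate import SimulationConfig


class TestFit:
    def test_no_covariate_variation_reduces_to_nelson_aalen(self, toy_two_subjects):
        # a constant covariate carries no partial-likelihood information:
        # beta pins at 0 and the Breslow baseline is the Nelson-Aalen
        # estimator: jumps 1/2 at t=1 and 1/1 at t=2
        fit = fit_cox(toy_two_subjects)
        assert fit.beta[0] == 0.0
        assert fit.dropped == ["z1"]
        np.testing.assert_allclose(fit.baseline_cumhaz([1.0, 2.0]), [0.5, 1.5])

    def test_beta_frozen_at_zero_gives_nelson_aalen(self, small_null_cohort):
        fit0 = fit_cox(small_null_cohort, max_iter=0)
        assert np.all(fit0.beta == 0.0)
        t = np.sort(small_null_cohort.time[small_null_cohort.event == 1])
        ut, dj = np.unique(t, return_counts=True)
        nj = np.array([(small_null_cohort.time >= u).sum() for u in ut])
        na = np.cumsum(dj / nj)
        np.testing.assert_allclose(fit0.baseline_cumhaz(ut), na, rtol=1e-12)

    def test_matches_lifelines_estimates(self, small_null_cohort):
        lifelines = pytest.importorskip("lifelines")
        cph = lifelines.CoxPHFitter().fit(
            small_null_cohort.to_frame(), duration_col="time", event_col="event"
        )
        fit = fit_cox(small_null_cohort)  # continuous times: no ties, so
        # Breslow and Efron coincide with lifelines' Efron default
        np.testing.assert_allclose(cph.params_.to_numpy(), fit.beta, atol=1e-6)
        np.testing.assert_allclose(
            cph.standard_errors_.to_numpy(), fit.standard_errors, atol=1e-6
        )

    def test_efron_matches_lifelines_on_tied_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        n = 120
        z = rng.standard_normal((n, 2))
        t = np.ceil(rng.exponential(scale=np.exp(-0.5 * z[:, 0]), size=n) * 4)  # heavy ties
        e = (rng.random(n) < 0.7).astype(int)
        e[:3] = 1
        data = SurvivalDataset(t, e, pd.DataFrame(z, columns=["z1", "z2"]))
        fit = fit_cox(data, ties="efron")
        cph = lifelines.CoxPHFitter().fit(data.to_frame(), "time", "event")
        np.testing.assert_allclose(cph.params_.to_numpy(), fit.beta, atol=1e-6)
        # Breslow handling must differ on tied data yet stay close
        fitb = fit_cox(data, ties="breslow")
        assert 1e-6 < np.abs(fitb.beta - fit.beta).max() < 0.2

    def test_parameter_recovery_large_sample(self):
        cfg = SimulationConfig(n=5000, model="g01", p=5, target_event_rate=0.2, seed=31)
        data = simulate_cohort(cfg)
        fit = fit_cox(data)
        z = (fit.beta - np.log(1.2)) / fit.standard_errors
        assert np.all(np.abs(z) < 3.0)

    def test_zero_events_rejected(self):
        with pytest.raises(Exception):
            SurvivalDataset(np.array([1.0, 2.0]), np.array([0, 0]), None)

    def test_collinear_covariates_raise(self, small_null_cohort):
        cov = small_null_cohort.covariates.copy()
        cov["dup"] = cov["G1"] * 2.0
        data = SurvivalDataset(small_null_cohort.time, small_null_cohort.event, cov)
        with pytest.raises((SingularityError, ConvergenceError)):
            fit_cox(data)

    def test_baseline_monotone_and_jumps_at_event_times(self, small_null_fit, small_null_cohort):
        assert np.all(small_null_fit.baseline_jumps > 0)
        ev_times = set(small_null_cohort.time[small_null_cohort.event == 1])
        assert set(small_null_fit.baseline_times) <= ev_times
        assert small_null_fit.baseline_cumhaz([0.0])[0] == 0.0


class TestResiduals:
    def test_toy_hand_values(self, toy_two_subjects):
        fit = fit_cox(toy_two_subjects)
        r = residuals(fit, toy_two_subjects)
        np.testing.assert_allclose(r.martingale, [0.5, -0.5])
        np.testing.assert_allclose(r.cox_snell, [0.5, 1.5])

    def test_subject_censored_at_time_zero_has_zero_residual(self):
        data = SurvivalDataset(
            np.array([0.0, 1.0, 2.0, 3.0]),
            np.array([0, 1, 1, 0]),
            pd.DataFrame({"z": [0.5, -0.5, 1.0, 0.0]}),
        )
        fit = fit_cox(data)
        r = residuals(fit, data)
        assert r.martingale[0] == 0.0
        assert r.cox_snell[0] == 0.0

    def test_martingale_identities(self, small_null_fit, small_null_cohort):
        r = residuals(small_null_fit, small_null_cohort)
        n = small_null_cohort.n
        assert abs(r.martingale.sum()) < 1e-8 * n
        assert abs(r.cox_snell.sum() - small_null_cohort.n_events) < 1e-8 * n
        assert np.all(r.martingale <= 1.0)
        assert np.all(r.cox_snell >= 0.0)
        np.testing.assert_allclose(
            r.martingale, np.asarray(small_null_cohort.event) - r.cox_snell
        )


class TestExtendedInformation:
    def test_score_gamma_equals_grouped_martingale_sums(self, small_null_fit, small_null_cohort):
        # score-test identity: the gamma score of the indicator-augmented
        # model at (beta_hat, 0) is the vector of grouped martingale sums
        from coxcal.calibration import grouped_sums

        grp = assign_groups(risk_scores(small_null_fit, small_null_cohort), 11, reference_group=11)
        ext = extended_information(small_null_fit, small_null_cohort, grp)
        H = grouped_sums(residuals(small_null_fit, small_null_cohort), grp)
        np.testing.assert_allclose(ext.score_gamma, H, atol=1e-8)

    def test_sigma_matches_finite_difference_hessian(self):
        cfg = SimulationConfig(n=50, model="g01", p=2, target_event_rate=0.5, seed=3)
        data = simulate_cohort(cfg)
        fit = fit_cox(data)
        grp = assign_groups(risk_scores(fit, data), 5, reference_group=3)
        ext = extended_information(fit, data, grp)
        p, m = 2, 4
        theta0 = np.concatenate([fit.beta, np.zeros(m)])

        def ll(th):
            return extended_loglik(fit, data, grp, th[:p], th[p:])

        h = 3e-4
        q = p + m
        hess = np.zeros((q, q))
        for i in range(q):
            for j in range(q):
                for si, sj, sgn in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
                    th = theta0.copy()
                    th[i] += si * h
                    th[j] += sj * h
                    hess[i, j] += sgn * ll(th)
        J = -hess / (4 * h * h)
        sigma_fd = J[p:, p:] - J[p:, :p] @ np.linalg.solve(J[:p, :p], J[:p, p:])
        rel = np.abs(sigma_fd - ext.sigma_hat).max() / np.abs(ext.sigma_hat).max()
        assert rel < 1e-5

    def test_sigma_symmetric_psd(self, small_null_fit, small_null_cohort):
        grp = assign_groups(risk_scores(small_null_fit, small_null_cohort), 11, reference_group=6)
        ext = extended_information(small_null_fit, small_null_cohort, grp)
        s = ext.sigma_hat
        np.testing.assert_allclose(s, s.T)
        assert np.linalg.eigvalsh(s).min() > -1e-8 * np.abs(s).max()

    def test_sigma_matches_empirical_covariance_of_H(self):
        # Monte Carlo oracle: over repeated null cohorts the analytic
        # Sigma_hat approximates the sampling covariance of H
        from coxcal.calibration import _GroupedMachinery

        cfg = SimulationConfig(n=1000, model="g01", p=2, target_event_rate=0.3).resolved()
        root = np.random.SeedSequence(424242)
        Hs, sigmas = [], []
        for child in root.spawn(800):
            data = simulate_cohort(cfg, rng=child)
            fit = fit_cox(data)
            gm = _GroupedMachinery(fit, data, 5).martingales(reference=5)
            Hs.append(gm.H)
            sigmas.append(gm.sigma)
        emp = np.cov(np.array(Hs).T)
        bar = np.mean(sigmas, axis=0)
        assert np.linalg.norm(emp - bar) / np.linalg.norm(bar) < 0.15

    def test_empty_group_rejected(self, small_null_fit, small_null_cohort):
        grp = assign_groups(risk_scores(small_null_fit, small_null_cohort), 5, reference_group=5)
        grp.labels[grp.labels == 2] = 3  # manufacture an empty group
        with pytest.raises(ValueError, match="empty"):
            extended_information(small_null_fit, small_null_cohort, grp)
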