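"""Logistic and Bayesian-logistic calibration: fits, posteriors, confidence."""

import numpy as np
import pytest
from scipy.special import expit

from idhcal.calibration import (
    BayesianLogisticCalibration,
    LogisticCalibration,
    confidence_score,
    logistic,
)
from idhcal.exceptions import UnfitCalibratorError


def simulate_xy(n, alpha, beta, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random(n)
    y = (rng.random(n) < expit(alpha + beta * x)).astype(float)
    return x, y


class TestLogisticFunction:
    def test_symmetry_point(self):
        assert logistic(0.5, alpha=-2.0, beta=4.0) == pytest.approx(0.5)

    def test_degenerate_slope_constant(self):
        vals = logistic(np.linspace(0, 1, 11), alpha=1.3, beta=0.0)
        assert np.allclose(vals, 1 / (1 + np.exp(-1.3)))

    def test_scalar_arithmetic(self):
        assert logistic(1.0, alpha=0.0, beta=4.0) == pytest.approx(1 / (1 + np.exp(-4)))

    def test_overflow_safe(self):
        assert logistic(1.0, alpha=0.0, beta=-5000.0) == 0.0
        assert logistic(1.0, alpha=0.0, beta=5000.0) == 1.0


class TestLogisticCalibration:
    def test_parameter_recovery_within_3se(self):
        x, y = simulate_xy(5000, alpha=-2.0, beta=4.0, seed=1)
        res = LogisticCalibration(y, x).fit()
        assert res.converged and not res.separated
        assert abs(res.alpha - (-2.0)) < 3 * res.bse[0]
        assert abs(res.beta - 4.0) < 3 * res.bse[1]

    def test_null_slope_detected(self):
        rng = np.random.default_rng(2)
        x = rng.random(4000)
        y = (rng.random(4000) < 0.6).astype(float)  # independent of x
        res = LogisticCalibration(y, x).fit()
        assert abs(res.beta) < 3 * res.bse[1]

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.linspace(0, 0.4, 20), np.linspace(0.6, 1, 20)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        res = LogisticCalibration(y, x).fit()
        assert res.separated
        assert np.isnan(res.alpha)
        with pytest.raises(UnfitCalibratorError):
            res.predict(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            LogisticCalibration(np.ones(10), np.linspace(0, 1, 10))

    def test_percent_scale_input_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            LogisticCalibration(np.array([0.0, 1.0]), np.array([10.0, 90.0]))

    def test_summary_mentions_estimates(self):
        x, y = simulate_xy(500, -1.0, 2.0, seed=3)
        s = LogisticCalibration(y, x).fit().summary()
        assert "alpha" in s and "beta" in s


@pytest.fixture(scope="module")
def data():
    return simulate_xy(5000, alpha=-2.0, beta=4.0, seed=4)


@pytest.fixture(scope="module")
def noninf_fit(data):
    x, y = data
    return BayesianLogisticCalibration(y, x, 1000.0).fit(seed=5)


class TestBayesianCalibration:

    def test_noninformative_posterior_matches_mle(self, data, noninf_fit):
        """N(0,1000) posterior means within 3 posterior SDs of the MLE at
        large n (prior contributes negligible information)."""
        x, y = data
        mle = LogisticCalibration(y, x).fit()
        mean, sd = noninf_fit.posterior_mean, noninf_fit.posterior_sd
        assert abs(mean[0] - mle.alpha) < 3 * sd[0]
        assert abs(mean[1] - mle.beta) < 3 * sd[1]

    def test_convergence_diagnostics_recorded(self, noninf_fit):
        assert max(noninf_fit.rhat.values()) < 1.01
        assert min(noninf_fit.ess.values()) > 100
        assert noninf_fit.draws.shape[0] >= 2

    def test_tiny_prior_variance_shrinks_to_zero(self, data):
        x, y = data
        res = BayesianLogisticCalibration(y, x, 1e-6).fit(seed=6)
        assert np.all(np.abs(res.posterior_mean) < 0.01)

    def test_informative_prior_shrinkage_ordering(self, data, noninf_fit):
        """Informative N(0,1) posterior means lie between 0 and the
        non-informative means, parameter-wise."""
        x, y = data
        inf = BayesianLogisticCalibration(y, x, 1.0).fit(seed=7)
        for i in range(2):
            lo, hi = sorted((0.0, noninf_fit.posterior_mean[i]))
            assert lo <= inf.posterior_mean[i] <= hi

    def test_posterior_sd_decreases_with_n(self):
        sds = []
        for n in (100, 1000, 10000):
            x, y = simulate_xy(n, alpha=-2.0, beta=4.0, seed=8)
            res = BayesianLogisticCalibration(y, x, 1000.0).fit(seed=9)
            sds.append(res.posterior_sd[1])
        assert sds[0] > sds[1] > sds[2]

    def test_seeded_draws_reproducible(self):
        x, y = simulate_xy(400, -2.0, 4.0, seed=10)
        r1 = BayesianLogisticCalibration(y, x, 1000.0).fit(seed=11)
        r2 = BayesianLogisticCalibration(y, x, 1000.0).fit(seed=11)
        assert np.array_equal(r1.draws, r2.draws)

    def test_predict_is_draw_average(self, noninf_fit):
        """Posterior-predictive mean equals a brute-force average of the
        logistic curve over the stored draws on a 101-point grid."""
        grid = np.linspace(0, 1, 101)
        expected = np.array([
            np.mean([expit(a + b * xi) for a, b in noninf_fit.flat_draws])
            for xi in grid
        ])
        assert np.allclose(noninf_fit.predict(grid), expected)

    def test_predict_bounded_by_draw_envelope(self, noninf_fit):
        grid = np.linspace(0, 1, 21)
        d = noninf_fit.flat_draws
        curves = expit(d[:, :1] + d[:, 1:] * grid)
        p = noninf_fit.predict(grid)
        assert np.all(p >= curves.min(axis=0) - 1e-12)
        assert np.all(p <= curves.max(axis=0) + 1e-12)

    def test_monotone_when_all_slopes_positive(self, noninf_fit):
        assert (noninf_fit.flat_draws[:, 1] > 0).all()
        p = noninf_fit.predict(np.linspace(0, 1, 101))
        assert np.all(np.diff(p) > 0)

    def test_matches_emcee_oracle(self):
        """Posterior means agree with an independent affine-invariant
        ensemble sampler on the same log posterior."""
        import emcee

        from idhcal.calibration import _log_posterior

        x, y = simulate_xy(400, alpha=-1.0, beta=2.0, seed=12)
        ours = BayesianLogisticCalibration(y, x, 1000.0).fit(seed=13)

        def lp(theta):
            return float(_log_posterior(theta, y, x, 1000.0)[0])

        rng = np.random.default_rng(14)
        sampler = emcee.EnsembleSampler(16, 2, lp)
        p0 = ours.mode + 0.1 * rng.standard_normal((16, 2))
        sampler.run_mcmc(p0, 2000, progress=False)
        ref = sampler.get_chain(discard=500, flat=True)
        assert np.allclose(ours.posterior_mean, ref.mean(axis=0),
                           atol=3 * ref.std(axis=0) / 10)

    def test_prior_variance_validation(self):
        x, y = simulate_xy(50, -1.0, 2.0)
        with pytest.raises(ValueError):
            BayesianLogisticCalibration(y, x, 0.0)


class TestConfidenceScore:
    def test_symmetry_point_half(self):
        x, y = simulate_xy(2000, 0.0, 3.0, seed=15)
        res = LogisticCalibration(y, x).fit()
        # evaluate at the fitted curve's own midpoint
        x_mid = -res.alpha / res.beta
        cs = confidence_score(x_mid, res, call="wildtype")
        assert cs.p_wildtype == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_posterior_equals_point_formula(self):
        x, y = simulate_xy(300, -2.0, 4.0, seed=16)
        res = BayesianLogisticCalibration(y, x, 1000.0).fit(seed=17)
        res.draws = np.full_like(res.draws, 0.0)
        res.draws[..., 0], res.draws[..., 1] = -1.0, 3.0
        grid = np.linspace(0, 1, 11)
        assert np.allclose(res.predict(grid), expit(-1.0 + 3.0 * grid))

    def test_predicted_class_probability_complement(self):
        x, y = simulate_xy(2000, -2.0, 4.0, seed=18)
        res = LogisticCalibration(y, x).fit()
        cs_wt = confidence_score(0.9, res, call="wildtype")
        cs_mut = confidence_score(0.9, res, call="mutant")
        assert cs_wt.p_wildtype == pytest.approx(cs_mut.p_wildtype)
        assert cs_mut.p_predicted_class == pytest.approx(1 - cs_wt.p_predicted_class)

    def test_unknown_call_rejected(self):
        x, y = simulate_xy(200, -2.0, 4.0, seed=19)
        res = LogisticCalibration(y, x).fit()
        with pytest.raises(ValueError):
            confidence_score(0.5, res, call="unknown")
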