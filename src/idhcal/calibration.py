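"""Confidence calibration of the wildtype voxel fraction.

The calibration model is a two-parameter logistic curve

    P(y = 1 | x) = 1 / (1 + exp(-(alpha + beta * x)))

mapping a subject's wildtype voxel fraction x in [0, 1] to the probability
that the subject is truly IDH-wildtype (y = 1, the positive class). Two
fitting routes are provided behind a statsmodels-style Model/Results
surface:

``LogisticCalibration``
    maximum-likelihood point fit (with exact detection of complete
    separation, which the MLE cannot survive);

``BayesianLogisticCalibration``
    posterior inference under independent zero-mean Gaussian priors on
    (alpha, beta) — variance 1 ("informative", regularising) or 1000
    ("non-informative", data-dominated) being the two canonical choices —
    sampled by adaptive random-walk Metropolis initialised at the posterior
    mode, with split-R-hat/ESS convergence gates.

The subject-level confidence score is the fitted curve evaluated at the
subject's x; for the Bayesian fits it is the posterior-predictive mean of
the curve over the stored draws — the Bayes estimate under squared-error
loss, the same loss the Brier score measures.

x must be a *fraction* in [0, 1], never a percentage: the slope is
scale-dependent and the N(0, 1) prior is only informative on a bounded
covariate scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit

from .exceptions import ConvergenceError, UnfitCalibratorError

__all__ = [
    "logistic",
    "LogisticCalibration",
    "LogisticCalibrationResults",
    "BayesianLogisticCalibration",
    "BayesianLogisticCalibrationResults",
    "ConfidenceScore",
    "confidence_score",
]

INFORMATIVE_PRIOR_VARIANCE = 1.0
NONINFORMATIVE_PRIOR_VARIANCE = 1000.0


def logistic(x, alpha: float, beta: float):
    """Two-parameter logistic curve, overflow-safe on any float input."""
    return expit(alpha + beta * np.asarray(x, dtype=float))


def _validate_xy(endog, exog):
    y = np.asarray(endog, dtype=float).ravel()
    x = np.asarray(exog, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError(f"endog and exog lengths differ: {y.size} vs {x.size}")
    if y.size < 2:
        raise ValueError("calibration requires at least 2 records")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("endog must be binary with wildtype coded 1")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("exog (wildtype fraction) must lie in [0, 1]")
    if y.min() == y.max():
        raise ValueError("single-class cohort: both classes are required to calibrate")
    return y, x


def _separation(y: np.ndarray, x: np.ndarray) -> bool:
    """Exact complete/quasi-separation check for a single covariate.

    With one covariate the MLE diverges iff some threshold on x classifies
    the data perfectly (allowing boundary ties), i.e. the class-conditional
    ranges of x do not overlap.
    """
    x1, x0 = x[y == 1], x[y == 0]
    return bool(x1.min() >= x0.max() or x1.max() <= x0.min())


# ---------------------------------------------------------------------------
# maximum likelihood


class LogisticCalibration:
    """Maximum-likelihood logistic calibration model.

    Parameters
    ----------
    endog : array-like of {0, 1}
        True labels, wildtype = 1.
    exog : array-like in [0, 1]
        Wildtype voxel fractions.
    """

    def __init__(self, endog, exog):
        self.endog, self.exog = _validate_xy(endog, exog)

    @classmethod
    def from_records(cls, frame, x_col: str = "x", label_col: str = "true_label"):
        """Build from a subjects DataFrame with fraction and label columns."""
        y = (frame[label_col] == "wildtype").to_numpy(dtype=float)
        return cls(y, frame[x_col].to_numpy(dtype=float))

    def fit(self, tol: float = 1e-8, maxiter: int = 200) -> "LogisticCalibrationResults":
        """Fit (alpha, beta) by Newton-type maximum likelihood.

        Complete separation is detected exactly beforehand; a separated fit
        carries ``separated=True`` with NaN estimates instead of divergent
        ones (callers fall back to the Bayesian route, whose priors
        regularise separation).
        """
        import statsmodels.api as sm

        separated = _separation(self.endog, self.exog)
        if separated:
            return LogisticCalibrationResults(
                model=self, alpha=np.nan, beta=np.nan, bse=(np.nan, np.nan),
                cov=np.full((2, 2), np.nan), llf=np.nan, converged=False, separated=True,
            )
        X = sm.add_constant(self.exog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sm emits RuntimeWarnings near-boundary
            res = sm.Logit(self.endog, X).fit(disp=0, tol=tol, maxiter=maxiter)
        return LogisticCalibrationResults(
            model=self,
            alpha=float(res.params[0]),
            beta=float(res.params[1]),
            bse=(float(res.bse[0]), float(res.bse[1])),
            cov=np.asarray(res.cov_params()),
            llf=float(res.llf),
            converged=bool(res.mle_retvals.get("converged", True)),
            separated=False,
        )


@dataclass
class LogisticCalibrationResults:
    """Point-fit results: estimates, observed-information SEs, diagnostics."""

    model: LogisticCalibration
    alpha: float
    beta: float
    bse: tuple[float, float]
    cov: np.ndarray
    llf: float
    converged: bool
    separated: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    def predict(self, x):
        """Calibrated P(wildtype | x) along the fitted curve."""
        if self.separated or not np.isfinite(self.alpha):
            raise UnfitCalibratorError(
                "logistic calibration is separated/unfit; use the Bayesian route"
            )
        return logistic(x, self.alpha, self.beta)

    def summary(self) -> str:
        lines = [
            "Logistic calibration (maximum likelihood)",
            f"  n = {self.model.endog.size}, wildtype = {int(self.model.endog.sum())}",
            f"  converged = {self.converged}, separated = {self.separated}",
            f"  {'param':<8}{'estimate':>12}{'std err':>12}",
            f"  {'alpha':<8}{self.alpha:>12.4f}{self.bse[0]:>12.4f}",
            f"  {'beta':<8}{self.beta:>12.4f}{self.bse[1]:>12.4f}",
            f"  log-likelihood = {self.llf:.3f}",
        ]
        return "\n".join(lines)

    def plot_curve(self, ax=None, n_points: int = 201):
        """Plot the fitted curve over the data (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 1, n_points)
        ax.plot(grid, self.predict(grid), label="LR fit")
        ax.scatter(self.model.exog, self.model.endog, s=8, alpha=0.4, c="k")
        ax.set_xlabel("wildtype voxel fraction x")
        ax.set_ylabel("P(wildtype)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Bayesian inference


def _log_posterior(theta: np.ndarray, y: np.ndarray, x: np.ndarray, prior_var: float):
    """Vectorised log posterior; ``theta`` has shape (..., 2)."""
    theta = np.atleast_2d(theta)
    logits = theta[..., :1] + theta[..., 1:] * x  # (..., n)
    ll = (y * logits - np.logaddexp(0.0, logits)).sum(axis=-1)
    lp = -(theta**2).sum(axis=-1) / (2.0 * prior_var)
    return ll + lp


def _neg_log_post_grad_hess(theta, y, x, prior_var):
    a, b = theta
    eta = a + b * x
    p = expit(eta)
    resid = p - y
    grad = np.array([resid.sum(), (resid * x).sum()]) + theta / prior_var
    w = p * (1 - p)
    hess = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    hess = hess + np.eye(2) / prior_var
    return grad, hess


class BayesianLogisticCalibration:
    """Bayesian logistic calibration under N(0, prior_variance) priors.

    The posterior p(alpha, beta | x, y) ∝ likelihood × N(alpha; 0, s²) ×
    N(beta; 0, s²) is sampled by adaptive random-walk Metropolis: chains
    start jittered around the posterior mode, the proposal is a scaled
    Laplace-approximation covariance, and each chain's step scale is
    adapted during warm-up toward ~35% acceptance (the optimum for a 2-D
    Gaussian target), then frozen.
    """

    def __init__(self, endog, exog, prior_variance: float = NONINFORMATIVE_PRIOR_VARIANCE):
        self.endog, self.exog = _validate_xy(endog, exog)
        if prior_variance <= 0:
            raise ValueError("prior_variance must be > 0")
        self.prior_variance = float(prior_variance)

    @classmethod
    def from_records(
        cls, frame, prior_variance: float = NONINFORMATIVE_PRIOR_VARIANCE,
        x_col: str = "x", label_col: str = "true_label",
    ):
        y = (frame[label_col] == "wildtype").to_numpy(dtype=float)
        return cls(y, frame[x_col].to_numpy(dtype=float), prior_variance)

    def posterior_mode(self) -> tuple[np.ndarray, np.ndarray]:
        """MAP estimate and Laplace covariance (inverse Hessian at the mode)."""
        y, x, pv = self.endog, self.exog, self.prior_variance

        def nlp(theta):
            return -float(_log_posterior(theta, y, x, pv)[0])

        def grad(theta):
            return _neg_log_post_grad_hess(theta, y, x, pv)[0]

        def hess(theta):
            return _neg_log_post_grad_hess(theta, y, x, pv)[1]

        res = optimize.minimize(nlp, np.zeros(2), jac=grad, hess=hess, method="trust-ncg")
        cov = np.linalg.inv(hess(res.x))
        return res.x, cov

    def fit(
        self,
        seed: int = 0,
        chains: int = 4,
        draws: int = 2000,
        warmup: int = 1000,
        rhat_threshold: float = 1.01,
        target_accept: float = 0.35,
    ) -> "BayesianLogisticCalibrationResults":
        """Sample the posterior and gate on convergence diagnostics.

        Raises :class:`ConvergenceError` (carrying the diagnostics) if the
        split-R-hat of either parameter reaches ``rhat_threshold``.
        """
        if chains < 2:
            raise ValueError("at least 2 chains are required for split-R-hat")
        rng = np.random.default_rng(seed)
        y, x, pv = self.endog, self.exog, self.prior_variance
        mode, cov = self.posterior_mode()
        chol = np.linalg.cholesky(cov)
        base_scale = 2.38 / np.sqrt(2.0)

        state = mode + 2.0 * rng.standard_normal((chains, 2)) @ chol.T  # overdispersed
        logp = _log_posterior(state, y, x, pv)
        log_scale = np.zeros(chains)
        out = np.empty((chains, draws, 2))
        accepted_post = np.zeros(chains)

        for t in range(warmup + draws):
            step = np.exp(log_scale)[:, None] * base_scale
            prop = state + step * (rng.standard_normal((chains, 2)) @ chol.T)
            logp_prop = _log_posterior(prop, y, x, pv)
            accept = np.log(rng.random(chains)) < (logp_prop - logp)
            state = np.where(accept[:, None], prop, state)
            logp = np.where(accept, logp_prop, logp)
            if t < warmup:
                log_scale += (t + 1) ** -0.6 * (accept.astype(float) - target_accept)
            else:
                out[:, t - warmup] = state
                accepted_post += accept

        diagnostics = _convergence_diagnostics(out)
        results = BayesianLogisticCalibrationResults(
            model=self,
            draws=out,
            prior_variance=pv,
            seed=seed,
            acceptance=accepted_post / draws,
            rhat=diagnostics["rhat"],
            ess=diagnostics["ess"],
            mode=mode,
        )
        if max(diagnostics["rhat"].values()) >= rhat_threshold:
            raise ConvergenceError(
                f"MCMC did not converge: split-R-hat {diagnostics['rhat']} "
                f"(threshold {rhat_threshold})",
                diagnostics=diagnostics,
            )
        return results


def _convergence_diagnostics(draws: np.ndarray) -> dict:
    """Rank-normalised split-R-hat and bulk ESS per parameter (via ArviZ)."""
    import arviz as az

    ds = az.convert_to_dataset({"alpha": draws[:, :, 0], "beta": draws[:, :, 1]})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    return {
        "rhat": {k: float(rhat[k].values) for k in ("alpha", "beta")},
        "ess": {k: float(ess[k].values) for k in ("alpha", "beta")},
    }


@dataclass
class BayesianLogisticCalibrationResults:
    """Posterior draws plus summaries, diagnostics and prediction."""

    model: BayesianLogisticCalibration
    draws: np.ndarray  # (chains, draws, 2)
    prior_variance: float
    seed: int
    acceptance: np.ndarray
    rhat: dict
    ess: dict
    mode: np.ndarray

    @property
    def flat_draws(self) -> np.ndarray:
        """All posterior draws pooled across chains, shape (n_draws, 2)."""
        return self.draws.reshape(-1, 2)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.flat_draws.mean(axis=0)

    @property
    def posterior_sd(self) -> np.ndarray:
        return self.flat_draws.std(axis=0, ddof=1)

    def posterior_interval(self, level: float = 0.95) -> np.ndarray:
        """Central credible interval per parameter, shape (2 params, 2)."""
        lo = (1 - level) / 2
        return np.quantile(self.flat_draws, [lo, 1 - lo], axis=0).T

    def predict(self, x):
        """Posterior-predictive mean confidence curve at x.

        Averages the logistic curve over all stored draws — the Bayes
        estimate of P(wildtype | x) under squared-error loss.
        """
        x = np.asarray(x, dtype=float)
        d = self.flat_draws
        curves = expit(d[:, :1] + d[:, 1:] * np.atleast_1d(x))
        mean = curves.mean(axis=0)
        return mean if x.ndim else float(mean[0])

    def predict_interval(self, x, level: float = 0.90) -> np.ndarray:
        """Central posterior band of the curve at x, shape (2, len(x))."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d = self.flat_draws
        curves = expit(d[:, :1] + d[:, 1:] * x)
        lo = (1 - level) / 2
        return np.quantile(curves, [lo, 1 - lo], axis=0)

    def predict_median(self, x):
        x = np.asarray(x, dtype=float)
        d = self.flat_draws
        med = np.median(expit(d[:, :1] + d[:, 1:] * np.atleast_1d(x)), axis=0)
        return med if x.ndim else float(med[0])

    def summary(self) -> str:
        mean, sd = self.posterior_mean, self.posterior_sd
        ci = self.posterior_interval(0.95)
        lines = [
            f"Bayesian logistic calibration, prior N(0, {self.prior_variance:g})",
            f"  n = {self.model.endog.size}, chains = {self.draws.shape[0]}, "
            f"draws/chain = {self.draws.shape[1]}, seed = {self.seed}",
            f"  {'param':<8}{'mean':>10}{'sd':>10}{'2.5%':>10}{'97.5%':>10}"
            f"{'R-hat':>8}{'ESS':>9}",
        ]
        for i, name in enumerate(("alpha", "beta")):
            lines.append(
                f"  {name:<8}{mean[i]:>10.4f}{sd[i]:>10.4f}{ci[i, 0]:>10.4f}"
                f"{ci[i, 1]:>10.4f}{self.rhat[name]:>8.4f}{self.ess[name]:>9.0f}"
            )
        lines.append(f"  mean acceptance = {self.acceptance.mean():.2f}")
        return "\n".join(lines)

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {
            "method": "BLR",
            "prior_variance": self.prior_variance,
            "seed": self.seed,
            "posterior_mean": self.posterior_mean.tolist(),
            "posterior_sd": self.posterior_sd.tolist(),
            "rhat": self.rhat,
            "ess": self.ess,
        }
        if include_draws:
            d["draws"] = self.flat_draws.tolist()
        return d

    def plot_curve(self, ax=None, n_points: int = 201, level: float = 0.90):
        """Posterior-mean curve with a central posterior band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 1, n_points)
        band = self.predict_interval(grid, level)
        ax.fill_between(grid, band[0], band[1], alpha=0.3,
                        label=f"{int(level * 100)}% posterior band")
        ax.plot(grid, self.predict(grid), label=f"BLR N(0, {self.prior_variance:g})")
        ax.scatter(self.model.exog, self.model.endog, s=8, alpha=0.4, c="k")
        ax.set_xlabel("wildtype voxel fraction x")
        ax.set_ylabel("P(wildtype)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# confidence scores


@dataclass(frozen=True)
class ConfidenceScore:
    """Calibrated probabilities attached to one subject-level call."""

    p_wildtype: float
    p_predicted_class: float


def confidence_score(x: float, fit, call: str) -> ConfidenceScore:
    """Confidence on a subject's call from a fitted calibrator.

    ``fit`` is either results object; ``call`` is "mutant" or "wildtype".
    ``p_predicted_class`` is the probability of the class actually called —
    the clinician-facing number — while ``p_wildtype`` is the positive-class
    probability the Brier score evaluates.
    """
    if call not in ("mutant", "wildtype"):
        raise ValueError(f"unknown call {call!r}")
    p_wt = float(np.asarray(fit.predict(np.asarray([x], dtype=float)))[0])
    return ConfidenceScore(
        p_wildtype=p_wt,
        p_predicted_class=p_wt if call == "wildtype" else 1.0 - p_wt,
    )
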