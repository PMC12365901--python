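"""Two-stage held-out confidence protocol.

Calibration curves (maximum-likelihood LR and Bayesian LR under the
informative N(0,1) and non-informative N(0,1000) priors) are fitted on one
held-out cohort (the "fit" or TG-1 analogue) and evaluated on a second,
disjoint cohort (the "eval" or TG-2 analogue), so no evaluation datum ever
influences a fit. Confidence on the evaluation cohort is scored with the
Brier score for all four scoring routes: the raw wildtype fraction taken as
a probability, LR, and the two BLR variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    INFORMATIVE_PRIOR_VARIANCE,
    NONINFORMATIVE_PRIOR_VARIANCE,
    BayesianLogisticCalibration,
    BayesianLogisticCalibrationResults,
    LogisticCalibration,
    LogisticCalibrationResults,
)
from .exceptions import LeakageError
from .metrics import ClassificationMetrics, brier, classification_metrics, reliability_bins

logger = logging.getLogger(__name__)

__all__ = ["TwoStageReport", "two_stage_protocol", "score_cohort"]

METHODS = ("raw_x", "lr", "blr_informative", "blr_noninformative")


@dataclass
class TwoStageReport:
    """Everything the two-stage protocol produces."""

    lr: LogisticCalibrationResults
    blr_informative: BayesianLogisticCalibrationResults
    blr_noninformative: BayesianLogisticCalibrationResults
    metrics_fit: ClassificationMetrics
    metrics_eval: ClassificationMetrics
    brier_fit: dict[str, float]
    brier_eval: dict[str, float]
    scored_eval: pd.DataFrame
    lr_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "calibrators": {
                "lr": {
                    "alpha": self.lr.alpha, "beta": self.lr.beta,
                    "separated": self.lr.separated, "fallback_to_blr": self.lr_fallback,
                },
                "blr_informative": self.blr_informative.to_dict(),
                "blr_noninformative": self.blr_noninformative.to_dict(),
            },
            "metrics": {
                "fit_cohort": self.metrics_fit.to_dict(),
                "eval_cohort": self.metrics_eval.to_dict(),
            },
            "brier": {"fit_cohort": self.brier_fit, "eval_cohort": self.brier_eval},
        }


def _check_disjoint(cohort_fit: pd.DataFrame, cohort_eval: pd.DataFrame) -> None:
    overlap = sorted(set(cohort_fit["subject_id"]) & set(cohort_eval["subject_id"]))
    if overlap:
        shown = overlap[:20]
        raise LeakageError(
            f"fit and eval cohorts share {len(overlap)} subject id(s): {shown}"
            + (" ..." if len(overlap) > 20 else "")
        )


def score_cohort(frame: pd.DataFrame, lr, blr_inf, blr_non, lr_fallback: bool) -> pd.DataFrame:
    """Append the four probability columns and per-call confidences."""
    out = frame.copy()
    x = out["x"].to_numpy(dtype=float)
    out["p_wildtype_raw"] = x
    out["p_wildtype_blr_inf"] = blr_inf.predict(x)
    out["p_wildtype_blr_noninf"] = blr_non.predict(x)
    out["p_wildtype_lr"] = (
        out["p_wildtype_blr_noninf"] if lr_fallback else lr.predict(x)
    )
    is_wt = (out["predicted_label"] == "wildtype").to_numpy()
    for method in ("lr", "blr_inf", "blr_noninf"):
        p = out[f"p_wildtype_{method}"].to_numpy(dtype=float)
        out[f"confidence_{method}"] = np.where(is_wt, p, 1.0 - p)
    return out


def two_stage_protocol(
    cohort_fit: pd.DataFrame,
    cohort_eval: pd.DataFrame,
    seed: int = 0,
    chains: int = 4,
    draws: int = 2000,
    warmup: int = 1000,
    informative_variance: float = INFORMATIVE_PRIOR_VARIANCE,
    noninformative_variance: float = NONINFORMATIVE_PRIOR_VARIANCE,
) -> TwoStageReport:
    """Fit calibrations on ``cohort_fit``, score ``cohort_eval``.

    Both frames need subject_id, x, predicted_label, true_label. Cohorts
    must be disjoint by subject id (overlap raises :class:`LeakageError`
    listing the offenders). If the LR fit is separated, LR-route scores
    fall back to the non-informative BLR (whose priors regularise
    separation) with a logged warning.
    """
    _check_disjoint(cohort_fit, cohort_eval)
    y_fit = (cohort_fit["true_label"] == "wildtype").to_numpy(dtype=float)
    x_fit = cohort_fit["x"].to_numpy(dtype=float)

    lr = LogisticCalibration(y_fit, x_fit).fit()
    blr_inf = BayesianLogisticCalibration(y_fit, x_fit, informative_variance).fit(
        seed=seed, chains=chains, draws=draws, warmup=warmup
    )
    blr_non = BayesianLogisticCalibration(y_fit, x_fit, noninformative_variance).fit(
        seed=seed + 1, chains=chains, draws=draws, warmup=warmup
    )
    lr_fallback = lr.separated
    if lr_fallback:
        logger.warning(
            "LR fit is separated; LR-route scores fall back to BLR(non-informative)"
        )

    scored_eval = score_cohort(cohort_eval, lr, blr_inf, blr_non, lr_fallback)
    scored_fit = score_cohort(cohort_fit, lr, blr_inf, blr_non, lr_fallback)

    def _briers(frame: pd.DataFrame) -> dict[str, float]:
        y = (frame["true_label"] == "wildtype").to_numpy(dtype=float)
        return {
            "raw_x": brier(frame["p_wildtype_raw"], y),
            "lr": brier(frame["p_wildtype_lr"], y),
            "blr_informative": brier(frame["p_wildtype_blr_inf"], y),
            "blr_noninformative": brier(frame["p_wildtype_blr_noninf"], y),
        }

    return TwoStageReport(
        lr=lr,
        blr_informative=blr_inf,
        blr_noninformative=blr_non,
        metrics_fit=classification_metrics(cohort_fit),
        metrics_eval=classification_metrics(cohort_eval),
        brier_fit=_briers(scored_fit),
        brier_eval=_briers(scored_eval),
        scored_eval=scored_eval,
        lr_fallback=lr_fallback,
    )


def reliability_table(scored: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Reliability-diagram data for each scoring route on a scored cohort."""
    y = (scored["true_label"] == "wildtype").to_numpy(dtype=float)
    frames = []
    for method, col in (
        ("raw_x", "p_wildtype_raw"),
        ("lr", "p_wildtype_lr"),
        ("blr_informative", "p_wildtype_blr_inf"),
        ("blr_noninformative", "p_wildtype_blr_noninf"),
    ):
        t = reliability_bins(scored[col].to_numpy(dtype=float), y, n_bins)
        t.insert(0, "method", method)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
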