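"""Published multi-site cohort summaries used for pooling consistency checks.

These tables transcribe the per-site subject counts and subject-level
classification metrics reported for a 2,481-subject multi-institutional
glioma cohort (eight institutions; 577 IDH-mutant, 1904 IDH-wildtype).
The evaluation cohort was split into two held-out groups: test group 1
(NYU, UWM, EGD, UPenn; 1236 subjects) used to fit the confidence
calibration, and test group 2 (UTSW-2, UTSW-3; 164 subjects) used to
evaluate it.

Only percent-scale per-site metrics and integer counts were published; the
integer confusion-matrix cells below are reconstructed from them (they are
the unique integer cells consistent with the printed per-site recall and
mutant-class accuracy at one-decimal rounding) and reproduce the printed
per-site metrics, so pooling them by cell summation recovers the printed
overall columns exactly.
"""

from __future__ import annotations

import pandas as pd

from .metrics import ConfusionCells

__all__ = [
    "site_class_counts",
    "tg1_site_metrics",
    "tg2_site_metrics",
    "tg1_site_confusions",
    "tg2_site_confusions",
]

#: Per-site IDH class counts of the full cohort (mutant, wildtype).
SITE_CLASS_COUNTS = {
    "TCIA": (92, 112),
    "Ivy-GAP": (2, 21),
    "UCSF": (103, 392),
    "EGD": (150, 306),
    "UPenn": (11, 387),
    "UTSW-1": (106, 254),
    "UTSW-2": (22, 37),
    "UTSW-3": (28, 77),
    "NYU": (47, 130),
    "UWM": (16, 188),
}

# Per-site published metrics (percent; AUC on [0, 1]). The class counts
# here follow the evaluation table's own headers, which for UPenn differ
# by one wildtype subject from the cohort breakdown table (388 vs 387).
_TG1 = {
    #        n    n_mut n_wt  acc   acc_mut acc_wt prec  rec   f1    auc
    "NYU":   (177, 47, 130, 96.0, 93.6, 96.9, 97.7, 96.9, 97.3, 0.97),
    "UWM":   (204, 16, 188, 93.6, 81.2, 94.7, 98.3, 94.7, 96.5, 0.96),
    "EGD":   (456, 150, 306, 96.3, 93.3, 97.7, 96.8, 97.7, 97.2, 0.98),
    "UPenn": (399, 11, 388, 98.0, 81.8, 98.5, 99.5, 98.5, 99.0, 0.98),
}
_TG2 = {
    "UTSW-2": (59, 22, 37, 93.2, 95.5, 91.9, 97.1, 91.9, 94.4, 0.98),
    "UTSW-3": (105, 28, 77, 96.2, 96.4, 96.1, 98.6, 96.1, 97.3, 0.97),
}

#: Published overall (pooled) cells of the two evaluation groups, for
#: reference in consistency checks: percent scale, AUC on [0, 1].
TG1_OVERALL = {
    "accuracy": 96.4, "accuracy_mutant_class": 92.0, "accuracy_wildtype_class": 97.3,
    "precision": 98.2, "recall": 97.3, "f1": 97.8, "auc": 0.98,
}
TG2_OVERALL = {
    "accuracy": 95.1, "accuracy_mutant_class": 96.0, "accuracy_wildtype_class": 94.7,
    "precision": 98.2, "recall": 94.7, "f1": 96.4, "auc": 0.98,
}

# Reconstructed integer confusion cells (wildtype positive):
# tp = round(recall * n_wt), tn = round(acc_mut * n_mut); unique integers
# consistent with the printed one-decimal percentages.
_TG1_CELLS = {
    "NYU": ConfusionCells(tp=126, fp=3, tn=44, fn=4),
    "UWM": ConfusionCells(tp=178, fp=3, tn=13, fn=10),
    "EGD": ConfusionCells(tp=299, fp=10, tn=140, fn=7),
    "UPenn": ConfusionCells(tp=382, fp=2, tn=9, fn=6),
}
_TG2_CELLS = {
    "UTSW-2": ConfusionCells(tp=34, fp=1, tn=21, fn=3),
    "UTSW-3": ConfusionCells(tp=74, fp=1, tn=27, fn=3),
}

_COLUMNS = [
    "site", "n", "n_mutant", "n_wildtype", "accuracy", "accuracy_mutant_class",
    "accuracy_wildtype_class", "precision", "recall", "f1", "auc",
]


def _frame(table: dict) -> pd.DataFrame:
    rows = [[site, *vals] for site, vals in table.items()]
    return pd.DataFrame(rows, columns=_COLUMNS)


def site_class_counts() -> pd.DataFrame:
    """Per-site (mutant, wildtype) subject counts of the full cohort."""
    return pd.DataFrame(
        [(s, m, w) for s, (m, w) in SITE_CLASS_COUNTS.items()],
        columns=["site", "n_mutant", "n_wildtype"],
    )


def tg1_site_metrics() -> pd.DataFrame:
    """Published per-site metrics of the calibration test group (n=1236)."""
    return _frame(_TG1)


def tg2_site_metrics() -> pd.DataFrame:
    """Published per-site metrics of the evaluation test group (n=164)."""
    return _frame(_TG2)


def tg1_site_confusions() -> dict[str, ConfusionCells]:
    """Reconstructed per-site confusion cells of test group 1."""
    return dict(_TG1_CELLS)


def tg2_site_confusions() -> dict[str, ConfusionCells]:
    """Reconstructed per-site confusion cells of test group 2."""
    return dict(_TG2_CELLS)
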