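"""Subject-level IDH calls from per-fold segmentations.

The subject pipeline is: per-voxel plurality vote across the fold models'
label maps -> whole-tumor per-class counts -> wildtype voxel fraction
x = n_wildtype / (n_mutant + n_wildtype) -> majority-vote call (wildtype iff
the wildtype voxels hold the strict majority; an exact tie goes to wildtype,
the prevalent positive class, and is flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyTumorError, ShapeMismatchError
from .voxels import (
    BACKGROUND,
    MUTANT,
    WILDTYPE,
    ClassCounts,
    VoxelLabelMap,
    whole_tumor_counts,
)

__all__ = [
    "SubjectRecord",
    "ensemble_folds",
    "wildtype_fraction",
    "majority_vote",
    "call_subject",
    "records_from_counts",
    "records_to_frame",
]

MUTANT_LABEL = "mutant"
WILDTYPE_LABEL = "wildtype"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's post-ensemble counts, fraction, call and (optional) truth."""

    subject_id: str
    counts: ClassCounts
    x: float  # wildtype voxel fraction, in [0, 1]
    predicted_label: str
    tie_flag: bool
    true_label: str | None = None


def ensemble_folds(maps: Sequence[VoxelLabelMap]) -> tuple[VoxelLabelMap, int]:
    """Per-voxel plurality vote over {0, 1, 2} across fold label maps.

    Ties are broken by the fixed priority wildtype(2) > mutant(1) >
    background(0) — prefer calling tumor over background and the prevalent
    class over the rare one. Returns the ensembled map and the number of
    voxels whose vote was tied (the ensemble-tie tally).
    """
    if len(maps) == 0:
        raise ValueError("ensemble_folds requires at least one fold map")
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        detail = ", ".join(f"fold {m.fold_id}: {m.shape}" for m in maps)
        raise ShapeMismatchError(
            f"subject {maps[0].subject_id}: fold label maps disagree on shape ({detail})"
        )
    stack = np.stack([m.labels for m in maps])
    votes = np.stack(
        [(stack == lab).sum(axis=0) for lab in (BACKGROUND, MUTANT, WILDTYPE)]
    )  # (3, *shape)
    top = votes.max(axis=0)
    # highest label among those achieving the max vote count wins
    winner = np.where(
        votes[WILDTYPE] == top,
        WILDTYPE,
        np.where(votes[MUTANT] == top, MUTANT, BACKGROUND),
    ).astype(np.int16)
    n_ties = int(((votes == top).sum(axis=0) > 1).sum())
    out = VoxelLabelMap(
        subject_id=maps[0].subject_id, fold_id=-1, labels=winner, affine=maps[0].affine
    )
    return out, n_ties


def wildtype_fraction(counts: ClassCounts) -> float:
    """Wildtype voxel fraction x = n_wildtype / (n_mutant + n_wildtype)."""
    if counts.total == 0:
        raise EmptyTumorError("cannot compute wildtype fraction of an empty tumor")
    return counts.n_wildtype / counts.total


def majority_vote(counts: ClassCounts) -> tuple[str, bool]:
    """Subject-level call by majority of tumor voxel classes.

    Wildtype iff n_wildtype > n_mutant, mutant iff the reverse; an exact
    tie is called wildtype (the positive, prevalent class) with
    ``tie_flag=True`` so reports can surface it. Equivalent to thresholding
    the wildtype fraction at 0.5.
    """
    if counts.total == 0:
        raise EmptyTumorError("cannot vote on an empty tumor")
    if counts.n_wildtype > counts.n_mutant:
        return WILDTYPE_LABEL, False
    if counts.n_mutant > counts.n_wildtype:
        return MUTANT_LABEL, False
    return WILDTYPE_LABEL, True


def call_subject(
    maps: Sequence[VoxelLabelMap], true_label: str | None = None
) -> tuple[SubjectRecord, int]:
    """Full subject pipeline: ensemble folds, count, fraction, vote.

    Returns the record and the ensemble-tie tally.
    """
    ensembled, n_ties = ensemble_folds(maps)
    counts = whole_tumor_counts(ensembled)
    x = wildtype_fraction(counts)
    label, tie = majority_vote(counts)
    rec = SubjectRecord(
        subject_id=maps[0].subject_id,
        counts=counts,
        x=x,
        predicted_label=label,
        tie_flag=tie,
        true_label=true_label,
    )
    return rec, n_ties


def records_from_counts(
    df: pd.DataFrame, truth: pd.DataFrame | None = None
) -> list[SubjectRecord]:
    """Build subject records from a post-ensemble counts table.

    ``df`` needs columns subject_id, n_mutant, n_wildtype; rows sharing a
    subject_id (per-fold counts) are pooled by summation — the count-level
    analogue of vote ensembling when per-voxel alignment is unavailable.
    ``truth`` (subject_id, true_label) attaches ground truth when given.
    Subjects with zero tumor voxels raise :class:`EmptyTumorError`.
    """
    pooled = df.groupby("subject_id", sort=True)[["n_mutant", "n_wildtype"]].sum()
    labels = None
    if truth is not None:
        labels = truth.set_index("subject_id")["true_label"]
    records = []
    for sid, row in pooled.iterrows():
        counts = ClassCounts(int(row["n_mutant"]), int(row["n_wildtype"]))
        if counts.total == 0:
            raise EmptyTumorError(f"subject {sid}: zero tumor voxels in counts table")
        label, tie = majority_vote(counts)
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                counts=counts,
                x=wildtype_fraction(counts),
                predicted_label=label,
                tie_flag=tie,
                true_label=None if labels is None else str(labels.get(sid)),
            )
        )
    return records


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (the subjects.csv layout)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "n_mutant": r.counts.n_mutant,
                "n_wildtype": r.counts.n_wildtype,
                "x": r.x,
                "predicted_label": r.predicted_label,
                "tie_flag": r.tie_flag,
                "true_label": r.true_label,
            }
            for r in records
        ]
    )
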