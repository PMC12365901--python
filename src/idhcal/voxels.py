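"""Label-volume I/O and per-class voxel counting.

The label convention is fixed across the package: 0 = background, 1 =
IDH-mutant tumor voxel, 2 = IDH-wildtype tumor voxel. Whole-tumor masks with
any other value are rejected at load time. Affine/orientation metadata is
carried opaquely and never interpreted — every downstream computation is
voxel-count based, so coordinate conventions are irrelevant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import EmptyTumorError, LabelFormatError

__all__ = [
    "BACKGROUND",
    "MUTANT",
    "WILDTYPE",
    "VoxelLabelMap",
    "ClassCounts",
    "load_label_map",
    "save_label_map",
    "whole_tumor_counts",
    "counts_table",
    "read_counts_csv",
]

BACKGROUND, MUTANT, WILDTYPE = 0, 1, 2
_VALID = frozenset({BACKGROUND, MUTANT, WILDTYPE})


@dataclass
class VoxelLabelMap:
    """One subject/fold 3-D integer label volume with opaque grid metadata."""

    subject_id: str
    fold_id: int
    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = np.setdiff1d(np.unique(self.labels), sorted(_VALID))
        if bad.size:
            raise LabelFormatError(
                f"label map {self.subject_id}/fold{self.fold_id} contains values outside "
                f"{{0, 1, 2}}: {bad.tolist()}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass(frozen=True)
class ClassCounts:
    """Per-class tumor voxel counts of one (usually fold-ensembled) volume."""

    n_mutant: int
    n_wildtype: int

    def __post_init__(self):
        if self.n_mutant < 0 or self.n_wildtype < 0:
            raise ValueError("voxel counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_mutant + self.n_wildtype


def load_label_map(path, subject_id: str | None = None, fold_id: int = 0) -> VoxelLabelMap:
    """Load and validate a NIfTI label volume.

    The on-disk data must be integer-valued after exact cast and contain
    only values in {0, 1, 2}; anything else raises
    :class:`LabelFormatError` naming the offending values.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    rounded = np.rint(data)
    if not np.array_equal(data, rounded):
        offending = np.unique(data[data != rounded])[:10]
        raise LabelFormatError(
            f"{path.name}: non-integer voxel values present, e.g. {offending.tolist()}"
        )
    labels = rounded.astype(np.int16)
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return VoxelLabelMap(subject_id=sid, fold_id=fold_id, labels=labels, affine=img.affine)


def save_label_map(vmap: VoxelLabelMap, path) -> None:
    """Write a label map as integer NIfTI-1."""
    img = nib.Nifti1Image(vmap.labels.astype(np.int16), vmap.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def whole_tumor_counts(vmap: VoxelLabelMap) -> ClassCounts:
    """Reduce a validated label map to per-class tumor voxel counts.

    Background voxels are ignored. An all-background volume raises
    :class:`EmptyTumorError`; callers exclude such subjects with a logged
    reason rather than propagating a zero-voxel record downstream.
    """
    n_mut = int(np.count_nonzero(vmap.labels == MUTANT))
    n_wt = int(np.count_nonzero(vmap.labels == WILDTYPE))
    if n_mut + n_wt == 0:
        raise EmptyTumorError(
            f"subject {vmap.subject_id} fold {vmap.fold_id}: no tumor voxels (labels 1/2)"
        )
    return ClassCounts(n_mutant=n_mut, n_wildtype=n_wt)


def counts_table(counts: dict[str, dict[int, ClassCounts]]) -> pd.DataFrame:
    """Tabulate per-subject, per-fold counts as a tidy DataFrame."""
    rows = [
        {"subject_id": sid, "fold_id": fold, "n_mutant": c.n_mutant, "n_wildtype": c.n_wildtype}
        for sid, folds in counts.items()
        for fold, c in sorted(folds.items())
    ]
    return pd.DataFrame(rows, columns=["subject_id", "fold_id", "n_mutant", "n_wildtype"])


def read_counts_csv(path) -> pd.DataFrame:
    """Read a counts CSV (subject_id, [fold_id,] n_mutant, n_wildtype)."""
    df = pd.read_csv(path)
    required = {"subject_id", "n_mutant", "n_wildtype"}
    missing = required - set(df.columns)
    if missing:
        raise LabelFormatError(f"counts file {path} missing columns: {sorted(missing)}")
    if (df[["n_mutant", "n_wildtype"]] < 0).any().any():
        raise LabelFormatError(f"counts file {path} contains negative counts")
    return df
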