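"""Synthetic glioma cohort generator.

Emulates the statistical shape of voxel-wise two-class tumor segmentations
produced by a cross-validated segmentation network, without any imaging or
network: each subject carries a latent wildtype voxel fraction drawn from a
class-conditional Beta distribution (mutant-truth subjects concentrated near
0, wildtype-truth near 1, a bimodal mixture overall), a tumor size drawn from
a log-normal, and per-fold label maps in which every tumor voxel's class is
flipped independently with a configurable rate.

Subjects are sampled on counter-based substreams keyed by
``(seed, cohort_key, subject_index)``, so enlarging a cohort never perturbs
the draws of earlier subjects and identical configs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigurationError
from .voxels import VoxelLabelMap, MUTANT, WILDTYPE

__all__ = [
    "CohortSimConfig",
    "SubjectTruth",
    "simulate_truth",
    "simulate_cohort",
    "simulate_counts",
    "write_cohort",
]

#: Class prevalence of the multi-institutional cohort the generator mirrors
#: (1904 wildtype of 2481 subjects).
DEFAULT_WILDTYPE_PREVALENCE = 1904 / 2481


@dataclass(frozen=True)
class CohortSimConfig:
    """All knobs of the synthetic cohort generator.

    Parameters
    ----------
    n_subjects
        Cohort size.
    wildtype_prevalence
        P(true label = wildtype). Default mirrors the 1904/2481 class mix of
        the multi-site cohort this generator emulates.
    frac_dist_mutant, frac_dist_wildtype
        Beta(a, b) parameters of the latent wildtype voxel fraction for
        mutant-truth and wildtype-truth subjects. Defaults put the mutant
        mass near 0 and the wildtype mass near 1, yielding the bimodal
        mixture the calibration model assumes (~97% latent accuracy at a
        0.5 threshold).
    tumor_size_log_mean, tumor_size_log_sd
        Parameters of the log-normal tumor voxel count (mean/sd of log
        count). Defaults give a median of ~8 100 voxels, i.e. ~8 cm**3 at
        1 mm**3 resolution, with a long right tail.
    n_folds
        Number of cross-validation fold models whose outputs are emulated.
    fold_flip_rate
        Probability that a tumor voxel's class flips (1 <-> 2),
        independently per voxel and per fold.
    volume_shape
        Grid of emitted label maps (volumes mode only).
    seed
        Base seed; combined with ``cohort_key`` and the subject index to
        form per-subject substreams.
    cohort_key
        Distinguishes cohorts drawn from the same base seed (e.g. the
        calibration and evaluation cohorts of the two-stage protocol).
    """

    n_subjects: int
    wildtype_prevalence: float = DEFAULT_WILDTYPE_PREVALENCE
    frac_dist_mutant: tuple[float, float] = (0.9, 4.5)
    frac_dist_wildtype: tuple[float, float] = (5.5, 1.1)
    tumor_size_log_mean: float = 9.0
    tumor_size_log_sd: float = 1.0
    n_folds: int = 5
    fold_flip_rate: float = 0.05
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    seed: int = 0
    cohort_key: int = 0
    subject_prefix: str = "S"

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name in ("wildtype_prevalence", "fold_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("frac_dist_mutant", "frac_dist_wildtype"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigurationError(f"{name}={(a, b)}: Beta parameters must be > 0")
        if self.tumor_size_log_sd <= 0:
            raise ConfigurationError("tumor_size_log_sd must be > 0")
        if self.n_folds < 1:
            raise ConfigurationError("n_folds must be >= 1")
        if len(self.volume_shape) != 3 or any(s < 1 for s in self.volume_shape):
            raise ConfigurationError(f"volume_shape {self.volume_shape} is not a 3-D grid")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frac_dist_mutant"] = list(d["frac_dist_mutant"])
        d["frac_dist_wildtype"] = list(d["frac_dist_wildtype"])
        d["volume_shape"] = list(d["volume_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSimConfig":
        d = dict(d)
        for key in ("frac_dist_mutant", "frac_dist_wildtype", "volume_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth of one simulated subject."""

    subject_id: str
    true_label: str  # "mutant" | "wildtype"
    latent_wildtype_fraction: float
    tumor_voxels: int

    def __post_init__(self):
        if not 0.0 <= self.latent_wildtype_fraction <= 1.0:
            raise ConfigurationError("latent_wildtype_fraction outside [0, 1]")
        if self.tumor_voxels < 1:
            raise ConfigurationError("tumor_voxels must be >= 1")


def _subject_rng(config: CohortSimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, config.cohort_key, index])


def _draw_truth(config: CohortSimConfig, index: int, rng: np.random.Generator) -> SubjectTruth:
    is_wt = rng.random() < config.wildtype_prevalence
    a, b = config.frac_dist_wildtype if is_wt else config.frac_dist_mutant
    frac = float(rng.beta(a, b))
    size = int(np.rint(np.exp(rng.normal(config.tumor_size_log_mean, config.tumor_size_log_sd))))
    size = max(size, 1)
    return SubjectTruth(
        subject_id=f"{config.subject_prefix}{index:05d}",
        true_label="wildtype" if is_wt else "mutant",
        latent_wildtype_fraction=frac,
        tumor_voxels=size,
    )


def simulate_truth(config: CohortSimConfig) -> list[SubjectTruth]:
    """Draw the latent per-subject truths (labels, fractions, sizes)."""
    return [_draw_truth(config, i, _subject_rng(config, i)) for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# volumes path


def _blob_indices(shape: tuple[int, int, int], n_voxels: int) -> tuple[np.ndarray, ...]:
    """Flat indices of a centred ellipsoidal blob of exactly ``n_voxels`` voxels.

    Voxels are ranked by normalised squared distance from the volume centre
    (axes scaled to the grid aspect), and the nearest ``n_voxels`` are taken;
    the stable argsort makes the blob deterministic. Geometry is irrelevant
    downstream — only counts matter — it exists to exercise the NIfTI path.
    """
    capacity = int(np.prod(shape))
    if n_voxels > capacity:
        raise ConfigurationError(
            f"tumor of {n_voxels} voxels does not fit in volume of {capacity} voxels "
            f"(shape {shape})"
        )
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    d2 = sum(((g - (s - 1) / 2.0) / s) ** 2 for g, s in zip(grids, shape))
    order = np.argsort(d2.ravel(), kind="stable")[:n_voxels]
    return np.unravel_index(order, shape)


def _base_labels(truth: SubjectTruth, rng: np.random.Generator) -> np.ndarray:
    """Per-voxel base classes of the blob: round(x*N) wildtype, rest mutant."""
    n = truth.tumor_voxels
    n_wt = int(np.rint(truth.latent_wildtype_fraction * n))
    labels = np.full(n, MUTANT, dtype=np.int16)
    labels[rng.permutation(n)[:n_wt]] = WILDTYPE
    return labels


def _fold_labels(base: np.ndarray, flip_rate: float, rng: np.random.Generator) -> np.ndarray:
    flip = rng.random(base.shape) < flip_rate
    out = base.copy()
    out[flip] = (MUTANT + WILDTYPE) - out[flip]  # 1 <-> 2
    return out


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[SubjectTruth], dict[str, list[VoxelLabelMap]]]:
    """Generate the cohort as per-subject, per-fold 3-D label maps.

    Returns the truth list and a mapping subject_id -> one
    :class:`VoxelLabelMap` per fold. Background is 0 outside the tumor blob.
    """
    subjects: list[SubjectTruth] = []
    maps: dict[str, list[VoxelLabelMap]] = {}
    for i in range(config.n_subjects):
        rng = _subject_rng(config, i)
        truth = _draw_truth(config, i, rng)
        subjects.append(truth)
        idx = _blob_indices(config.volume_shape, truth.tumor_voxels)
        base = _base_labels(truth, rng)
        fold_maps = []
        for fold in range(config.n_folds):
            vol = np.zeros(config.volume_shape, dtype=np.int16)
            vol[idx] = _fold_labels(base, config.fold_flip_rate, rng)
            fold_maps.append(
                VoxelLabelMap(subject_id=truth.subject_id, fold_id=fold, labels=vol)
            )
        maps[truth.subject_id] = fold_maps
    return subjects, maps


# ---------------------------------------------------------------------------
# counts path (voxel geometry marginalised out)


def ensemble_flip_probability(flip_rate: float, n_folds: int) -> tuple[float, float]:
    """Probability that fold-ensembling flips a tumor voxel's base class.

    A voxel of base class c appears as the other class in k ~ Binom(n_folds,
    flip_rate) folds. The per-voxel plurality vote with tie priority
    wildtype > mutant flips mutant -> wildtype when k >= n_folds/2 (ties go
    to wildtype) and wildtype -> mutant only when k > n_folds/2 strictly.

    Returns ``(p_mut_to_wt, p_wt_to_mut)``.
    """
    k = stats.binom(n_folds, flip_rate)
    half = n_folds / 2.0
    p_mut_to_wt = float(k.sf(np.ceil(half) - 1)) if n_folds % 2 == 0 else float(k.sf(half))
    # even: P(k >= n/2); odd: P(k > n/2) = P(k >= (n+1)/2) = sf(n/2)
    p_wt_to_mut = float(k.sf(np.floor(half)))  # P(k > n/2) strictly, both parities
    return p_mut_to_wt, p_wt_to_mut


def simulate_counts(config: CohortSimConfig) -> tuple[list[SubjectTruth], pd.DataFrame]:
    """Generate the cohort directly as post-ensemble per-class voxel counts.

    Statistically equivalent to running :func:`simulate_cohort` and the
    per-voxel fold-ensembling downstream, with the voxel geometry
    marginalised out: each base-mutant voxel independently ends up wildtype
    after ensembling with probability ``p_mut_to_wt`` and vice versa, so the
    ensembled counts are sums of two binomials.

    Returns the truth list and a DataFrame with one row per subject:
    ``subject_id, true_label, latent_fraction, tumor_voxels, n_mutant,
    n_wildtype``.
    """
    p_m2w, p_w2m = ensemble_flip_probability(config.fold_flip_rate, config.n_folds)
    rows = []
    subjects = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config, i)
        truth = _draw_truth(config, i, rng)
        subjects.append(truth)
        n = truth.tumor_voxels
        n_wt_base = int(np.rint(truth.latent_wildtype_fraction * n))
        n_mut_base = n - n_wt_base
        n_wt = int(rng.binomial(n_wt_base, 1.0 - p_w2m) + rng.binomial(n_mut_base, p_m2w))
        rows.append(
            {
                "subject_id": truth.subject_id,
                "true_label": truth.true_label,
                "latent_fraction": truth.latent_wildtype_fraction,
                "tumor_voxels": n,
                "n_mutant": n - n_wt,
                "n_wildtype": n_wt,
            }
        )
    return subjects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk cohort


def write_cohort(config: CohortSimConfig, outdir, volumes: bool = True) -> dict:
    """Write a simulated cohort to ``outdir``.

    Emits ``truth.csv`` (subject_id, true_label, latent_fraction,
    tumor_voxels), ``config.yaml``, and — in volumes mode — one NIfTI per
    subject and fold (``<subject>_fold<k>.nii.gz``); in counts mode a single
    ``counts.csv`` of post-ensemble counts instead. Returns a manifest dict.
    """
    from pathlib import Path

    from .voxels import save_label_map

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    if volumes:
        subjects, maps = simulate_cohort(config)
        for sid, fold_maps in maps.items():
            for m in fold_maps:
                path = outdir / f"{sid}_fold{m.fold_id}.nii.gz"
                save_label_map(m, path)
                files.append(path.name)
    else:
        subjects, counts = simulate_counts(config)
        counts.to_csv(outdir / "counts.csv", index=False)
        files.append("counts.csv")

    truth = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "true_label": [s.true_label for s in subjects],
            "latent_fraction": [s.latent_wildtype_fraction for s in subjects],
            "tumor_voxels": [s.tumor_voxels for s in subjects],
        }
    )
    truth.to_csv(outdir / "truth.csv", index=False)
    files.append("truth.csv")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    files.append("config.yaml")
    return {"n_subjects": config.n_subjects, "files": sorted(files), "seed": config.seed}
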