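"""Synthetic cohort generator: determinism, degeneracies, distributional shape."""

import numpy as np
import pytest
from scipy import stats

from idhcal.exceptions import ConfigurationError
from idhcal.simulate import (
    CohortSimConfig,
    ensemble_flip_probability,
    simulate_cohort,
    simulate_counts,
    simulate_truth,
)
from idhcal.voxels import WILDTYPE

SMALL = dict(tumor_size_log_mean=4.5, tumor_size_log_sd=0.4, volume_shape=(12, 12, 12))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0},
            {"n_subjects": 10, "wildtype_prevalence": 1.2},
            {"n_subjects": 10, "fold_flip_rate": -0.1},
            {"n_subjects": 10, "frac_dist_mutant": (0.0, 2.0)},
            {"n_subjects": 10, "tumor_size_log_sd": 0.0},
            {"n_subjects": 10, "n_folds": 0},
            {"n_subjects": 10, "volume_shape": (4, 4)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortSimConfig(**kwargs)

    def test_oversized_tumor_names_both_sizes(self):
        cfg = CohortSimConfig(n_subjects=1, volume_shape=(4, 4, 4),
                              tumor_size_log_mean=8.0, tumor_size_log_sd=0.01, seed=3)
        with pytest.raises(ConfigurationError, match="64"):
            simulate_cohort(cfg)


class TestDeterminism:
    def test_same_seed_bit_identical_maps(self):
        cfg = CohortSimConfig(n_subjects=4, seed=7, **SMALL)
        _, maps1 = simulate_cohort(cfg)
        _, maps2 = simulate_cohort(cfg)
        for sid in maps1:
            for m1, m2 in zip(maps1[sid], maps2[sid]):
                assert np.array_equal(m1.labels, m2.labels)

    def test_extending_cohort_preserves_earlier_subjects(self):
        """Counter-based substreams: subject i's draws do not depend on n."""
        short = simulate_truth(CohortSimConfig(n_subjects=5, seed=3))
        long = simulate_truth(CohortSimConfig(n_subjects=20, seed=3))
        assert short == long[:5]

    def test_counts_mode_reproducible(self):
        cfg = CohortSimConfig(n_subjects=30, seed=11)
        _, c1 = simulate_counts(cfg)
        _, c2 = simulate_counts(cfg)
        assert c1.equals(c2)


class TestDegenerateSettings:
    def test_noise_free_wildtype_subjects_all_label2(self):
        """Degenerate Beta at 1 + zero flip rate: every wildtype-truth voxel
        carries label 2 in every fold."""
        cfg = CohortSimConfig(
            n_subjects=6, seed=2, fold_flip_rate=0.0,
            wildtype_prevalence=1.0, frac_dist_wildtype=(1e6, 1e-3), **SMALL,
        )
        subjects, maps = simulate_cohort(cfg)
        for s in subjects:
            assert s.true_label == "wildtype"
            for m in maps[s.subject_id]:
                tumor = m.labels[m.labels != 0]
                assert tumor.size == s.tumor_voxels
                assert (tumor == WILDTYPE).all()

    def test_zero_flip_rate_folds_identical(self):
        cfg = CohortSimConfig(n_subjects=4, seed=5, fold_flip_rate=0.0, **SMALL)
        _, maps = simulate_cohort(cfg)
        for fold_maps in maps.values():
            for m in fold_maps[1:]:
                assert np.array_equal(m.labels, fold_maps[0].labels)


class TestDistributionalShape:
    def test_mutant_fraction_mean_matches_beta(self):
        """Empirical mean wildtype fraction among mutant-truth subjects is
        within 3 MC standard errors of the Beta(2, 20) mean 2/22."""
        cfg = CohortSimConfig(n_subjects=5000, seed=9, frac_dist_mutant=(2.0, 20.0))
        subjects = simulate_truth(cfg)
        fracs = np.array([s.latent_wildtype_fraction for s in subjects
                          if s.true_label == "mutant"])
        mean = 2.0 / 22.0
        sd = np.sqrt(stats.beta(2, 20).var() / fracs.size)
        assert abs(fracs.mean() - mean) < 3 * sd

    def test_prevalence_within_binomial_ci(self):
        cfg = CohortSimConfig(n_subjects=3000, seed=4)
        subjects = simulate_truth(cfg)
        p_hat = np.mean([s.true_label == "wildtype" for s in subjects])
        p = cfg.wildtype_prevalence
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / cfg.n_subjects)

    def test_default_fractions_bimodal(self):
        """Class-conditional means are separated by more than the sum of the
        class-conditional standard deviations (the bimodality the
        calibration assumes)."""
        subjects = simulate_truth(CohortSimConfig(n_subjects=3000, seed=6))
        f = np.array([s.latent_wildtype_fraction for s in subjects])
        wt = np.array([s.true_label == "wildtype" for s in subjects])
        gap = f[wt].mean() - f[~wt].mean()
        assert gap > f[wt].std() + f[~wt].std()

    def test_tumor_sizes_positive_and_lognormal_scale(self):
        subjects = simulate_truth(CohortSimConfig(n_subjects=2000, seed=8))
        sizes = np.array([s.tumor_voxels for s in subjects])
        assert (sizes >= 1).all()
        # median of log-normal(9, 1) is e^9 ~ 8100; loose MC band
        assert 6000 < np.median(sizes) < 11000


class TestCountsPathEquivalence:
    def test_ensemble_flip_probability_matches_enumeration(self):
        """Closed-form ensembled flip probabilities equal brute-force
        enumeration over fold flip patterns."""
        for n_folds in (1, 2, 3, 4, 5, 6):
            for p in (0.0, 0.05, 0.3):
                m2w, w2m = ensemble_flip_probability(p, n_folds)
                # enumerate k = number of flipped folds
                pk = stats.binom(n_folds, p)
                m2w_ref = sum(pk.pmf(k) for k in range(n_folds + 1)
                              if k > n_folds - k or k == n_folds - k)
                w2m_ref = sum(pk.pmf(k) for k in range(n_folds + 1)
                              if k > n_folds - k)
                assert m2w == pytest.approx(m2w_ref, abs=1e-12)
                assert w2m == pytest.approx(w2m_ref, abs=1e-12)

    def test_counts_and_voxel_paths_agree_in_distribution(self):
        """Mean ensembled wildtype fraction agrees between the marginalised
        counts path and the full voxel path on matched truths."""
        from idhcal.calls import ensemble_folds
        from idhcal.voxels import whole_tumor_counts

        cfg = CohortSimConfig(n_subjects=40, seed=13, fold_flip_rate=0.15, **SMALL)
        subjects, maps = simulate_cohort(cfg)
        _, counts = simulate_counts(cfg)
        x_vox = []
        for s in subjects:
            ens, _ = ensemble_folds(maps[s.subject_id])
            c = whole_tumor_counts(ens)
            x_vox.append(c.n_wildtype / c.total)
        x_cnt = (counts["n_wildtype"] / counts["tumor_voxels"]).to_numpy()
        # same truths, independent noise realisations; compare cohort means
        assert np.mean(x_vox) == pytest.approx(np.mean(x_cnt), abs=0.03)
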