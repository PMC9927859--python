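"""Generative-model correctness: expectations, determinism, behavior model."""

import numpy as np
import pytest

from narrisc.isc import mean_isc_map, pairwise_between_isc, pairwise_within_isc
from narrisc.synthetic import (SimulationConfig, draw_skills, expected_isc,
                               generate_behavior, generate_cohort)
from narrisc.dataio import DataError
from narrisc.preprocess import (NuisanceDesign, canonical_hrf, regress_out,
                                silence_regressor)


def small_config(**kw):
    defaults = dict(n_subjects=6, shape=(3, 3, 1), n_timepoints=200,
                    conditions=("lipread", "listen"),
                    shared_fraction_within=0.5, shared_fraction_between=0.25,
                    seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        c1, b1, s1, t1 = generate_cohort(small_config())
        c2, b2, s2, t2 = generate_cohort(small_config())
        for key in c1.images:
            np.testing.assert_array_equal(c1.images[key].data,
                                          c2.images[key].data)
        assert b1.frame.equals(b2.frame)
        np.testing.assert_array_equal(t1.skills, t2.skills)

    def test_different_seed_differs(self):
        c1, *_ = generate_cohort(small_config(seed=0))
        c2, *_ = generate_cohort(small_config(seed=1))
        key = next(iter(c1.images))
        assert not np.array_equal(c1.images[key].data, c2.images[key].data)


class TestExpectations:
    def test_zero_shared_fraction_zero_expected_isc(self):
        cfg = small_config(shared_fraction_within=0.0,
                           shared_fraction_between=0.0)
        truth = expected_isc(cfg, np.full(6, 50.0))
        np.testing.assert_allclose(truth.expected_within, 0.0)
        np.testing.assert_allclose(truth.expected_between, 0.0)

    def test_full_shared_fraction_unit_isc(self):
        cfg = small_config(shared_fraction_within=1.0,
                           shared_fraction_between=0.0)
        truth = expected_isc(cfg, np.full(6, 50.0))
        np.testing.assert_allclose(truth.expected_within, 1.0)

    def test_zero_skill_subject_kills_its_pairs(self):
        region = np.ones((3, 3, 1), dtype=bool)
        cfg = small_config(skill_region=region, skill_bounds=(0.0, 100.0))
        skills = np.array([0.0, 50.0, 50.0, 50.0, 50.0, 50.0])
        b = 0.25
        # pairwise between expectation for pairs including subject 1 is 0
        k = skills / 100.0
        pair_exp = [b * k[i] * k[j] for i in range(6) for j in range(i + 1, 6)]
        truth = expected_isc(cfg, skills)
        np.testing.assert_allclose(truth.expected_between,
                                   np.mean(pair_exp), atol=1e-12)
        assert pair_exp[:5] == [0.0] * 5

    def test_between_fraction_exceeding_within_rejected(self):
        with pytest.raises(DataError, match="exceed"):
            small_config(shared_fraction_within=0.2,
                         shared_fraction_between=0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError, match="mask"):
            small_config(mask=np.zeros((3, 3, 1), dtype=bool))


class TestEmpiricalRecovery:
    def test_within_isc_recovers_shared_fraction(self):
        """E[r] = f under the generative model: at f=0.5, n=20, T=300 the
        pair-averaged map recovers f within 0.05."""
        cfg = small_config(n_subjects=20, n_timepoints=300,
                           conditions=("listen",),
                           shared_fraction_within=0.5,
                           shared_fraction_between=0.0, seed=3)
        cohort, *_ = generate_cohort(cfg)
        m = mean_isc_map(pairwise_within_isc(cohort, "listen"))
        assert abs(np.nanmean(m.data) - 0.5) < 0.05

    def test_between_isc_recovers_between_fraction(self):
        cfg = small_config(n_subjects=10, n_timepoints=1000, seed=4)
        cohort, *_ = generate_cohort(cfg)
        m = mean_isc_map(pairwise_between_isc(cohort, "lipread", "listen"))
        assert abs(np.nanmean(m.data) - 0.25) < 0.03

    def test_large_T_supnorm_convergence_to_expected(self):
        """Empirical pair means converge voxelwise to the analytic ground
        truth (sup-norm < 0.05 at T=2000, n=10)."""
        cfg = small_config(n_subjects=10, n_timepoints=2000, seed=5)
        cohort, _, _, truth = generate_cohort(cfg)
        within = mean_isc_map(pairwise_within_isc(cohort, "listen"))
        between = mean_isc_map(pairwise_between_isc(cohort, "lipread", "listen"))
        mask = cohort.mask.data
        assert np.max(np.abs(within.data[mask] - truth.expected_within)) < 0.05
        assert np.max(np.abs(between.data[mask] - truth.expected_between)) < 0.05

    def test_silence_transient_inflates_isc_and_regression_restores(self):
        """A common silence-driven transient inflates pairwise ISC; regressing
        the HRF-convolved silence vector restores the configured level."""
        silences = [(20.0, 30.0), (80.0, 95.0), (150.0, 165.0),
                    (220.0, 240.0), (280.0, 300.0)]
        cfg = small_config(n_subjects=8, n_timepoints=200, tr_s=1.7,
                           conditions=("listen",),
                           shared_fraction_within=0.2,
                           shared_fraction_between=0.0,
                           silences=silences, silence_effect_amplitude=1.5,
                           seed=6)
        cohort, _, stim, _ = generate_cohort(cfg)
        raw = np.nanmean(mean_isc_map(pairwise_within_isc(cohort, "listen")).data)
        kernel = canonical_hrf(cfg.tr_s)
        reg = silence_regressor(stim, cfg.n_timepoints, cfg.tr_s, kernel)
        design = NuisanceDesign.from_silence(reg)
        for key, img in cohort.images.items():
            cohort.images[key] = regress_out(img, design)
        clean = np.nanmean(mean_isc_map(pairwise_within_isc(cohort, "listen")).data)
        assert raw > 0.3          # transient clearly inflates ISC above f=0.2
        assert abs(clean - 0.2) < 0.06

    def test_hrf_smoothed_mode_keeps_expectation(self):
        cfg = small_config(n_subjects=10, n_timepoints=800,
                           conditions=("listen",), noise_mode="hrf",
                           shared_fraction_within=0.4,
                           shared_fraction_between=0.0, seed=7)
        cohort, *_ = generate_cohort(cfg)
        m = mean_isc_map(pairwise_within_isc(cohort, "listen"))
        assert abs(np.nanmean(m.data) - 0.4) < 0.08


class TestBehaviorModel:
    def test_noise_free_unit_slope_identity(self):
        cfg = small_config(rating_slope=1.0, rating_noise_sd=0.0,
                           rating_order_offsets=(0.0, 0.0, 0.0))
        skills = np.array([6.0, 20.0, 45.0, 60.0, 85.0, 100.0])
        table = generate_behavior(cfg, skills, np.random.default_rng(0))
        np.testing.assert_allclose(table.frame["mean_rating"], skills / 100.0)

    def test_zero_slope_gives_null_correlation_distribution(self):
        """With slope 0 the score-rating correlation is null: |r| < 0.5 in at
        least 95% of Monte-Carlo draws at n=29, and centered near zero."""
        cfg = small_config(n_subjects=29, rating_slope=0.0)
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(200):
            skills = draw_skills(cfg, rng)
            table = generate_behavior(cfg, skills, rng)
            rs.append(np.corrcoef(table.frame["lip_score_pct"],
                                  table.frame["mean_rating"])[0, 1])
        rs = np.array(rs)
        assert np.mean(np.abs(rs) < 0.5) >= 0.95
        assert abs(rs.mean()) < 0.05

    def test_order_offsets_raise_later_groups(self):
        """Positive offsets for later order groups reproduce the pattern of
        better subjective comprehension when lipreading comes last."""
        cfg = small_config(n_subjects=120, rating_slope=0.0,
                           rating_noise_sd=0.0,
                           rating_order_offsets=(0.0, 0.03, 0.06))
        skills = np.full(120, 50.0)
        table = generate_behavior(cfg, skills, np.random.default_rng(2))
        means = table.frame.groupby("order_group")["mean_rating"].mean()
        assert means[1] < means[2] < means[3]

    def test_round_robin_group_assignment(self):
        cfg = small_config()
        table = generate_behavior(cfg, np.full(6, 50.0),
                                  np.random.default_rng(3))
        assert table.frame["order_group"].tolist() == [1, 2, 3, 1, 2, 3]

    def test_skill_summary_matches_target_moments(self):
        cfg = small_config(n_subjects=4000)
        skills = draw_skills(cfg, np.random.default_rng(4))
        assert skills.min() >= 6.0 and skills.max() <= 100.0
        assert skills.mean() == pytest.approx(50.7, abs=1.5)
        assert skills.std() == pytest.approx(26.0, abs=1.5)
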