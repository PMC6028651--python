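import warnings

import numpy as np
import pytest
from scipy.stats import ks_2samp

from petrad.features import texture_features
from petrad.selection import roc_auc
from petrad.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_records,
    generate_tumor,
    sample_exponential_times,
)
from petrad.volume_io import extract_voi


class TestGenerateTumor:
    def test_degenerate_config_constant_ellipsoid(self):
        cfg = CohortConfig(noise_sd=0.0, texture_amplitude=0.0)
        vol, mask = generate_tumor(cfg, 0, np.random.default_rng(0))
        inside = vol.values[mask.values]
        assert np.allclose(inside, cfg.tumor_suv_mean[0])
        outside = vol.values[~mask.values]
        assert np.allclose(outside, cfg.background_suv)

    def test_fixed_seed_bit_identical(self):
        cfg = CohortConfig(seed=5)
        a_vol, a_mask = generate_tumor(cfg, 1, np.random.default_rng(42))
        b_vol, b_mask = generate_tumor(cfg, 1, np.random.default_rng(42))
        np.testing.assert_array_equal(a_vol.values, b_vol.values)
        np.testing.assert_array_equal(a_mask.values, b_mask.values)

    def test_tumor_larger_than_grid_rejected(self):
        cfg = CohortConfig(grid_size=8, tumor_radius_range=(40.0, 60.0))
        with pytest.raises(ValueError, match="grid"):
            generate_tumor(cfg, 0, np.random.default_rng(0))

    def test_planted_texture_effect_separates_classes(self):
        """Tumors of the two classes differ in correlation length; a GLCM
        texture feature should separate them with AUC > 0.7."""
        cfg = CohortConfig()
        rng = np.random.default_rng(99)
        scores, labels = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for label in (0, 1):
                for _ in range(20):
                    vol, mask = generate_tumor(cfg, label, rng)
                    feats = texture_features(extract_voi(vol, mask))
                    scores.append(feats["correlation"])
                    labels.append(label)
        assert roc_auc(scores, labels) > 0.7


class TestGenerateRecords:
    def test_default_cohort_has_7_of_30_progressions(self):
        records = generate_records(CohortConfig(seed=3))
        labels = [r.label for r in records]
        assert len(records) == 30
        assert sum(labels) == 7

    def test_progression_implies_lc_event(self):
        for rec in generate_records(CohortConfig(seed=8)):
            if rec.label == 1:
                assert rec.lc_event == 1

    def test_determinism(self):
        a = generate_records(CohortConfig(seed=21))
        b = generate_records(CohortConfig(seed=21))
        assert a == b

    def test_clinical_fields_within_ranges(self):
        for rec in generate_records(CohortConfig(seed=4)):
            assert rec.location in (0, 1, 2, 3)
            assert rec.t_stage in (2, 3, 4)
            assert rec.chemo_cycles in (1, 2, 3, 4)
            assert 44 <= rec.age <= 75
            assert rec.gender in (0, 1)
            assert rec.bed_gy in (67.2, 71.175, 73.925)


class TestEventTimes:
    def test_null_config_classes_indistinguishable(self):
        rng = np.random.default_rng(17)
        labels = np.repeat([0, 1], 500)
        times, events = sample_exponential_times(rng, labels, 24.0, 1.0, 0.0)
        assert events.all()
        stat = ks_2samp(times[labels == 0], times[labels == 1])
        assert stat.pvalue > 0.01

    def test_hazard_ratio_scales_median(self):
        rng = np.random.default_rng(23)
        labels = np.repeat([0, 1], 2000)
        times, _ = sample_exponential_times(rng, labels, 24.0, 8.0, 0.0)
        ratio = np.median(times[labels == 0]) / np.median(times[labels == 1])
        assert ratio == pytest.approx(8.0, rel=0.15)

    def test_censor_rate(self):
        rng = np.random.default_rng(31)
        labels = np.zeros(4000, dtype=int)
        _, events = sample_exponential_times(rng, labels, 24.0, 1.0, 0.3)
        assert 1.0 - events.mean() == pytest.approx(0.3, abs=0.03)


class TestGenerateCohort:
    def test_structure_and_determinism(self):
        cfg = CohortConfig(n_patients=6, n_progression=2, seed=13)
        rec_a, img_a = generate_cohort(cfg)
        rec_b, img_b = generate_cohort(cfg)
        assert [r.label for r in rec_a] == [r.label for r in rec_b]
        assert sum(r.label for r in rec_a) == 2
        for pa, pb in zip(img_a, img_b):
            for tp in ("pre", "mid"):
                np.testing.assert_array_equal(pa[tp][0].values, pb[tp][0].values)

    def test_mid_volume_responds_to_treatment(self):
        """Controls respond strongly: mid-treatment uptake excess shrinks by
        the response factor."""
        cfg = CohortConfig(n_patients=8, n_progression=2, noise_sd=0.0, seed=2)
        records, images = generate_cohort(cfg)
        for rec, pair in zip(records, images):
            mask = pair["pre"][1].values
            pre_excess = pair["pre"][0].values[mask].mean() - cfg.background_suv
            mid_excess = pair["mid"][0].values[mask].mean() - cfg.background_suv
            f = cfg.mid_crt_response_factor[rec.label]
            assert mid_excess == pytest.approx(f * pre_excess, rel=1e-9)

    def test_masks_shared_between_timepoints(self):
        _, images = generate_cohort(CohortConfig(n_patients=4, n_progression=1, seed=1))
        for pair in images:
            np.testing.assert_array_equal(
                pair["pre"][1].values, pair["mid"][1].values
            )


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_progression=30)
    with pytest.raises(ValueError):
        CohortConfig(hazard_ratio=0.0)
    with pytest.raises(ValueError):
        CohortConfig(censor_rate=1.5)
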