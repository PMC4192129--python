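"""Volumetry arithmetic, histogram peaks, sampling and t-tests."""

import numpy as np
import pytest

from gbpct.segment import SegmentationResult
from gbpct.stats import (
    compute_ratios,
    compute_volumes,
    histogram_and_peaks,
    printed_table_arithmetic,
    round_half_up,
    sample_and_test,
    shrinkage_percent,
    smoothed_peak_count,
    voxel_volume_mm3,
)

# printed volumetric table of the two segmented kidneys (mm^3)
PRINTED_IR = {"total": 27.96, "inner_medulla": 2.62,
              "cortex_outer_medulla": 24.90, "blood_vessels": 0.44}
PRINTED_CONTRA = {"total": 61.14, "inner_medulla": 2.76,
                  "cortex_outer_medulla": 56.96, "blood_vessels": 2.42}


class TestVolumeArithmetic:
    def test_voxel_volume_of_7p5_micron_voxel(self):
        v = voxel_volume_mm3(0.0075)
        assert v == pytest.approx(4.21875e-7)
        assert round_half_up(v * 1e7, 2) == 4.22

    def test_hand_computed_volume(self):
        seg = SegmentationResult(
            labels=np.full((10, 10, 10), 4, dtype=np.uint8), voxel_size=0.01
        )
        assert compute_volumes(seg)["im"] == pytest.approx(1e-3)

    def test_empty_compartment_reports_nothing(self):
        seg = SegmentationResult(labels=np.zeros((4, 4, 4), dtype=np.uint8))
        vols = compute_volumes(seg)
        assert vols["total"] == 0.0

    @pytest.mark.parametrize(
        "isch,contra,expected",
        [(27.96, 61.14, 0.46), (2.62, 2.76, 0.95), (0.44, 2.42, 0.18), (5.0, 5.0, 1.0)],
    )
    def test_reported_ratio_rounding(self, isch, contra, expected):
        ratios = compute_ratios({"x": isch}, {"x": contra})
        assert ratios["x"] == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compute_ratios({"x": 1.0}, {"x": 0.0})

    def test_shrinkage_exceeds_half(self):
        ratio = PRINTED_IR["total"] / PRINTED_CONTRA["total"]
        assert round_half_up(shrinkage_percent(ratio), 1) == 54.3
        assert shrinkage_percent(ratio) > 50.0

    def test_printed_table_inconsistent_row_flagged(self):
        # 24.90 / 56.96 = 0.44, but the printed table says 0.49
        out = printed_table_arithmetic(
            PRINTED_IR, PRINTED_CONTRA,
            printed_ratios={"total": 0.46, "inner_medulla": 0.95,
                            "cortex_outer_medulla": 0.49, "blood_vessels": 0.18},
        )
        assert out["ratios"]["cortex_outer_medulla"] == 0.44
        assert out["inconsistent_rows"] == ["cortex_outer_medulla"]
        assert out["shrinkage_percent"] == 54.3


class TestHistogramPeaks:
    def test_single_valued_volume_has_one_peak(self):
        vol = np.full((12, 12, 12), 3.0)
        seg = SegmentationResult(labels=np.full(vol.shape, 9, dtype=np.uint8))
        report = histogram_and_peaks(vol, seg, n_bins=32)
        assert report.peak_count == 1

    def test_empty_segmentation_rejected(self):
        seg = SegmentationResult(labels=np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            histogram_and_peaks(np.zeros((4, 4, 4)), seg)

    def test_too_few_bins_rejected(self):
        seg = SegmentationResult(labels=np.full((4, 4, 4), 9, dtype=np.uint8))
        with pytest.raises(ValueError, match="n_bins"):
            histogram_and_peaks(np.zeros((4, 4, 4)), seg, n_bins=8)

    def test_peak_counter_on_synthetic_mixtures(self):
        rng = np.random.default_rng(0)
        three = np.concatenate([
            rng.normal(0.0, 0.1, 40000),
            rng.normal(1.0, 0.1, 10000),
            rng.normal(2.0, 0.1, 5000),
        ])
        counts, _ = np.histogram(three, bins=256)
        assert smoothed_peak_count(counts)[0] == 3
        merged = rng.normal(0.0, 0.1, 50000)
        counts, _ = np.histogram(merged, bins=256)
        assert smoothed_peak_count(counts)[0] == 1


class TestSampleAndTest:
    @pytest.fixture
    def two_class_volume(self):
        rng = np.random.default_rng(42)
        vol = np.empty((20, 20, 20))
        labels = np.zeros(vol.shape, dtype=np.uint8)
        labels[:10] = 4
        labels[10:] = 3
        vol[labels == 4] = rng.normal(0.0, 0.1, (labels == 4).sum())
        vol[labels == 3] = rng.normal(1.0, 0.1, (labels == 3).sum())
        return vol, SegmentationResult(labels=labels)

    def test_identical_samples_give_null_result(self):
        vol = np.zeros((10, 10, 10))
        labels = np.zeros(vol.shape, dtype=np.uint8)
        labels[:5] = 4
        labels[5:] = 3
        seg = SegmentationResult(labels=labels)
        tests = sample_and_test(vol, seg, compartments=["isom", "im"], n=100, seed=0)
        assert tests[0].t_paired == 0.0 and tests[0].p_paired == 1.0

    def test_separated_gaussians_are_significant(self, two_class_volume):
        vol, seg = two_class_volume
        tests = sample_and_test(vol, seg, compartments=["isom", "im"], n=3000, seed=1)
        assert tests[0].p_paired < 0.01
        assert tests[0].p_welch < 0.01
        assert tests[0].significant

    def test_sampling_is_deterministic(self, two_class_volume):
        vol, seg = two_class_volume
        a = sample_and_test(vol, seg, compartments=["isom", "im"], n=500, seed=7)
        b = sample_and_test(vol, seg, compartments=["isom", "im"], n=500, seed=7)
        assert a[0].t_paired == b[0].t_paired and a[0].p_paired == b[0].p_paired

    def test_tiny_compartment_rejected(self):
        vol = np.zeros((4, 4, 4))
        labels = np.zeros(vol.shape, dtype=np.uint8)
        labels[0, 0, 0] = 4
        labels[1:] = 3
        seg = SegmentationResult(labels=labels)
        with pytest.raises(ValueError, match="fewer than 2"):
            sample_and_test(vol, seg, compartments=["isom", "im"], n=10, seed=0)

    def test_paired_null_rejection_rate_is_calibrated(self):
        """Monte-Carlo type-I error of the index-matched paired test at alpha=0.05."""
        from gbpct.stats import paired_null_rejection_rate

        rate = paired_null_rejection_rate(repeats=1000, n=2000, alpha=0.05, seed=2024)
        assert 0.03 <= rate <= 0.07
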