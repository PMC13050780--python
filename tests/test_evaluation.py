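"""IoU matching, the four lesion-level metrics, and the stratified analyses."""

import math

import numpy as np
import pytest

from cmbscreen.errors import ValidationError
from cmbscreen.evaluation import (
    BurdenThresholds,
    SizeBins,
    aria_severity,
    assign_region,
    estimate_diameter,
    iou,
    lesion_metrics,
    match_detections,
    metrics_from_match,
    patient_burden_class,
    patient_level_metrics,
    regional_metrics,
    size_stratified_metrics,
)
from cmbscreen.imaging_io import Box, Volume


def box(cx, cy, w=10.0, h=10.0, k=0, conf=1.0):
    return Box(k, cx, cy, w, h, confidence=conf)


class TestIou:
    def test_identical_boxes(self):
        assert iou(box(10, 10), box(10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(box(10, 10), box(40, 40)) == 0.0

    def test_offset_overlap_arithmetic(self):
        # 10x10 boxes offset by (5,5): intersection 25, union 175
        assert iou(box(10, 10), box(15, 15)) == pytest.approx(25 / 175)

    def test_symmetric(self, rng):
        for _ in range(20):
            a = box(*rng.uniform(5, 40, 2), *rng.uniform(3, 15, 2))
            b = box(*rng.uniform(5, 40, 2), *rng.uniform(3, 15, 2))
            assert iou(a, b) == pytest.approx(iou(b, a))

    def test_different_slices_never_overlap(self):
        assert iou(box(10, 10, k=0), box(10, 10, k=1)) == 0.0

    def test_degenerate_box_unconstructible(self):
        with pytest.raises(ValidationError):
            Box(0, 10, 10, 0.0, 5.0)


class TestMatching:
    def test_perfect_detector_no_errors(self, rng):
        gts = [box(15, 15), box(40, 40), box(20, 50, k=1)]
        m = match_detections(list(gts), gts, 0.5)
        assert (m.tp, len(m.fp), len(m.fn)) == (3, 0, 0)
        assert all(v == 1.0 for _, _, v in m.tp_pairs)

    def test_prediction_claims_highest_iou_ground_truth(self):
        gt_a = box(10, 10, 10, 10)
        gt_b = box(14, 10, 10, 10)
        pred = box(11, 10, 10, 10)  # IoU 0.82 with a, 0.54 with b
        m = match_detections([pred], [gt_a, gt_b], 0.5)
        assert m.tp == 1
        assert m.tp_pairs[0][1] is gt_a
        assert m.fn == [gt_b]

    def test_threshold_is_strict(self):
        # IoU exactly 0.5: shift a 10x10 box by 10/3 in one axis
        pred = box(10 + 10 / 3.0, 10)
        gt = box(10, 10)
        assert iou(pred, gt) == pytest.approx(0.5)
        m = match_detections([pred], [gt], 0.5)
        assert m.tp == 0 and len(m.fp) == 1 and len(m.fn) == 1

    def test_conservation_on_fuzzed_instances(self, rng):
        for _ in range(200):
            preds = [
                box(*rng.uniform(0, 64, 2), *rng.uniform(3, 15, 2),
                    k=int(rng.integers(2)), conf=float(rng.random()))
                for _ in range(rng.integers(0, 8))
            ]
            gts = [
                box(*rng.uniform(0, 64, 2), *rng.uniform(3, 15, 2),
                    k=int(rng.integers(2)))
                for _ in range(rng.integers(0, 8))
            ]
            m = match_detections(preds, gts, 0.5)
            assert m.tp + len(m.fn) == len(gts)
            assert m.tp + len(m.fp) == len(preds)
            assert all(v > 0.5 for _, _, v in m.tp_pairs)
            matched_gts = [id(g) for _, g, _ in m.tp_pairs]
            assert len(set(matched_gts)) == len(matched_gts)

    def test_greedy_never_beats_bruteforce_optimum(self, rng):
        from .oracles import optimal_matching_tp

        for _ in range(100):
            preds = [
                box(*rng.uniform(5, 59, 2), *rng.uniform(5, 18, 2),
                    conf=float(rng.random()))
                for _ in range(rng.integers(1, 6))
            ]
            gts = [
                box(*rng.uniform(5, 59, 2), *rng.uniform(5, 18, 2))
                for _ in range(rng.integers(1, 6))
            ]
            mat = np.array([[iou(p, g) for g in gts] for p in preds])
            assert match_detections(preds, gts, 0.5).tp <= optimal_matching_tp(mat, 0.5)


class TestLesionMetrics:
    def test_published_count_arithmetic_first_row(self):
        m = lesion_metrics(1484, 622, 654, 153)
        assert round(m.sensitivity, 3) == 0.694
        assert round(m.precision, 3) == 0.705
        assert round(m.f1, 3) == 0.699
        assert round(m.fp_avg, 2) == 4.07

    def test_published_count_arithmetic_multichannel_row(self):
        m = lesion_metrics(1491, 693, 647, 153)
        assert round(m.f1, 3) == 0.690
        assert round(m.fp_avg, 2) == 4.53

    def test_degenerate_counts_reported_absent_not_zero(self):
        m = lesion_metrics(0, 0, 0, 5)
        assert m.sensitivity is None and m.precision is None and m.f1 is None
        assert m.fp_avg == 0.0

    def test_f1_between_precision_and_sensitivity(self, rng):
        for _ in range(100):
            tp, fp, fn = (int(x) for x in rng.integers(0, 50, 3))
            m = lesion_metrics(tp, fp, fn, 10)
            if m.sensitivity is not None and m.precision is not None and m.f1 is not None:
                lo, hi = sorted((m.sensitivity, m.precision))
                assert lo - 1e-12 <= m.f1 <= hi + 1e-12

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValidationError):
            lesion_metrics(1, 1, 1, 0)


class TestDiameterAndSizeBins:
    def test_mean_side_estimator(self):
        d = estimate_diameter(box(0, 0, w=10, h=12), (0.429, 0.429))
        assert d == pytest.approx((4.29 + 5.148) / 2)

    def test_square_box_diameter_is_side_times_spacing(self):
        assert estimate_diameter(box(0, 0, 8, 8), (0.5, 0.5)) == pytest.approx(4.0)

    def test_anisotropic_spacing_per_axis(self):
        d = estimate_diameter(box(0, 0, w=10, h=10), (0.4, 0.6))
        assert d == pytest.approx((10 * 0.6 + 10 * 0.4) / 2)

    def test_default_bin_of_typical_lesion(self):
        bins = SizeBins()
        assert bins.label(bins.bin_of(4.7)) == "[4,5)"
        assert bins.bin_of(2.5) == 1  # half-open edges: [2.5, 3)
        assert bins.label(bins.bin_of(8.0)) == ">=6"

    def test_bin_conservation(self, rng):
        gts = [box(*rng.uniform(10, 50, 2), *rng.uniform(4, 24, 2)) for _ in range(20)]
        preds = [box(*rng.uniform(10, 50, 2), *rng.uniform(4, 24, 2), conf=0.9)
                 for _ in range(15)]
        m = match_detections(preds, gts, 0.5)
        table = size_stratified_metrics(m, SizeBins(), (0.429, 0.429), 1)
        assert table.tp.sum() == m.tp
        assert table.fn.sum() == len(m.fn)
        assert table.fp.sum() == len(m.fp)

    def test_single_occupied_bin_leaves_others_absent(self):
        gts = [box(20, 20, 10, 10)]  # 4.29 mm -> [4,5)
        m = match_detections([], gts, 0.5)
        table = size_stratified_metrics(m, SizeBins(), (0.429, 0.429))
        occupied = table[table.fn > 0]
        assert list(occupied.bin) == ["[4,5)"]
        empty = table[table.fn == 0]
        assert empty.sensitivity.isna().all()

    def test_bad_edges_rejected(self):
        with pytest.raises(ValidationError):
            SizeBins((0.0, 3.0, 2.0, math.inf))
        with pytest.raises(ValidationError):
            SizeBins((0.0, 3.0, 6.0))


class TestRegions:
    @pytest.fixture()
    def half_plane_regions(self):
        labels = np.zeros((64, 64, 2), dtype=np.int16)
        labels[:, :32, :] = 1  # lobar left
        labels[:, 32:, :] = 2  # deep right
        return Volume(labels, (0.429, 0.429, 6.5))

    def test_lesions_credited_to_their_half(self, half_plane_regions):
        gts = [box(10, 30), box(50, 30)]
        preds = [box(10, 30, conf=0.9), box(50, 30, conf=0.8)]
        m = match_detections(preds, gts, 0.5)
        table = regional_metrics(m, half_plane_regions)
        by = table.set_index("region")
        assert by.loc["lobar", "tp"] == 1 and by.loc["deep", "tp"] == 1
        assert by.loc["infratentorial", ["tp", "fp", "fn"]].sum() == 0

    def test_background_centre_is_excluded(self, half_plane_regions):
        half_plane_regions.data[:, :, :] = 0
        assert assign_region(box(10, 10), half_plane_regions) == "excluded"

    def test_single_region_collapses_to_global(self, half_plane_regions):
        half_plane_regions.data[:, :, :] = 2
        gts = [box(10, 30), box(50, 30)]
        m = match_detections([box(10, 30, conf=1.0)], gts, 0.5)
        table = regional_metrics(m, half_plane_regions).set_index("region")
        assert table.loc["deep", "tp"] == m.tp
        assert table.loc["deep", "fn"] == len(m.fn)

    def test_regional_counts_never_exceed_global(self, half_plane_regions, rng):
        gts = [box(*rng.uniform(5, 58, 2)) for _ in range(10)]
        preds = [box(*rng.uniform(5, 58, 2), conf=float(rng.random())) for _ in range(10)]
        m = match_detections(preds, gts, 0.5)
        table = regional_metrics(m, half_plane_regions)
        assert table.tp.sum() + table.fn.sum() <= m.tp + len(m.fn)
        assert table.fp.sum() <= len(m.fp)


class TestPatientLevel:
    def test_burden_boundaries(self):
        assert patient_burden_class(3) == "low"
        assert patient_burden_class(4) == "elevated"
        assert patient_burden_class(0) == "low"

    def test_perfect_counts_give_unit_metrics(self):
        counts = {f"s{i}": c for i, c in enumerate([0, 2, 3, 4, 9])}
        out = patient_level_metrics(counts, counts)
        assert (out["sensitivity"], out["specificity"], out["ppv"], out["npv"]) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_hand_built_two_by_two(self):
        true = {}
        pred = {}
        i = 0
        for truth, guess, n in (
            (5, 5, 9),  # TP
            (5, 1, 1),  # FN
            (1, 5, 1),  # FP
            (1, 1, 9),  # TN
        ):
            for _ in range(n):
                true[f"s{i}"] = truth
                pred[f"s{i}"] = guess
                i += 1
        out = patient_level_metrics(pred, true)
        assert out["sensitivity"] == pytest.approx(0.9)
        assert out["specificity"] == pytest.approx(0.9)
        assert out["ppv"] == pytest.approx(0.9)
        assert out["npv"] == pytest.approx(0.9)

    def test_all_predicted_elevated_degenerates(self):
        true = {"a": 1, "b": 2}
        pred = {"a": 9, "b": 9}
        out = patient_level_metrics(pred, true)
        assert out["specificity"] == 0.0
        assert out["npv"] is None

    def test_subject_set_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            patient_level_metrics({"a": 1}, {"b": 1})


class TestAriaSeverity:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "none"), (1, "mild"), (5, "mild"), (6, "moderate"),
         (10, "moderate"), (11, "severe"), (40, "severe")],
    )
    def test_bins(self, count, expected):
        assert aria_severity(count) == expected

    def test_thresholds_must_be_contiguous(self):
        with pytest.raises(ValidationError):
            BurdenThresholds(aria_mild=(1, 4))
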