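"""Detection evaluation: IoU matching, lesion/patient/region/size metrics.

A predicted box counts as a true positive when its intersection-over-union
with a ground-truth box *exceeds* the matching threshold (default 0.5, the
"exceeding" read strictly).  Matching is greedy in descending confidence:
each prediction claims the unmatched ground-truth box with the highest
qualifying IoU.  Greedy assignment is the community default for detection
scoring; it never exceeds the maximum-cardinality matching and coincides
with it on realistic instances (this is oracle-checked in the test suite).

Lesion-level metrics are
``sensitivity = TP / (TP + FN)``, ``precision = TP / (TP + FP)``,
``F1 = 2 * P * R / (P + R)``, and ``FPavg = FP / n_subjects``.
Ratios with empty denominators are reported as *absent* (``None``), never
as zero, so that aggregation stays honest.

Patient-level analysis dichotomizes subjects by microbleed burden — low
(1–3) versus elevated (>= 4) — and reports the standard 2x2 ratios.  The
hemosiderin-ARIA severity bins follow the clinical cutoffs: none (0),
mild (1–5), moderate (6–10), severe (> 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError
from .imaging_io import Box, Volume

__all__ = [
    "MatchResult",
    "MetricsReport",
    "SizeBins",
    "BurdenThresholds",
    "iou",
    "match_detections",
    "lesion_metrics",
    "metrics_from_match",
    "estimate_diameter",
    "size_stratified_metrics",
    "assign_region",
    "regional_metrics",
    "patient_burden_class",
    "patient_level_metrics",
    "aria_severity",
    "DEFAULT_REGION_LABELS",
]

DEFAULT_REGION_LABELS: Mapping[int, str] = {1: "lobar", 2: "deep", 3: "infratentorial"}


# ---------------------------------------------------------------------------
# Geometry


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when on different slices."""
    if a.area <= 0 or b.area <= 0:
        raise ValidationError("zero-area box in IoU computation")
    if a.slice_index != b.slice_index:
        return 0.0
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# Matching


@dataclass
class MatchResult:
    """Outcome of matching predictions against ground truth."""

    tp_pairs: list[tuple[Box, Box, float]]  # (prediction, ground truth, IoU)
    fp: list[Box]
    fn: list[Box]
    iou_thresh: float

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_pred(self) -> int:
        return self.tp + len(self.fp)

    @property
    def n_gt(self) -> int:
        return self.tp + len(self.fn)

    def merged(self, other: "MatchResult") -> "MatchResult":
        if other.iou_thresh != self.iou_thresh:
            raise ValidationError("cannot merge matches at different IoU thresholds")
        return MatchResult(
            tp_pairs=self.tp_pairs + other.tp_pairs,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            iou_thresh=self.iou_thresh,
        )


def match_detections(
    preds: Sequence[Box], gts: Sequence[Box], iou_thresh: float = 0.5
) -> MatchResult:
    """Greedy confidence-ordered matching.

    Predictions are visited in descending confidence (ties broken by
    slice index, then cy, then cx); each claims the still-unmatched ground
    truth box with the highest IoU strictly greater than ``iou_thresh``.
    Unclaimed predictions become false positives, unclaimed ground truth
    false negatives.
    """
    order = sorted(
        range(len(preds)),
        key=lambda i: (-preds[i].confidence, preds[i].slice_index, preds[i].cy, preds[i].cx),
    )
    unmatched = set(range(len(gts)))
    tp_pairs: list[tuple[Box, Box, float]] = []
    fp: list[Box] = []
    for i in order:
        p = preds[i]
        best_j, best_iou = -1, iou_thresh
        for j in sorted(unmatched):
            v = iou(p, gts[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            unmatched.discard(best_j)
            tp_pairs.append((p, gts[best_j], best_iou))
        else:
            fp.append(p)
    fn = [gts[j] for j in sorted(unmatched)]
    return MatchResult(tp_pairs=tp_pairs, fp=fp, fn=fn, iou_thresh=iou_thresh)


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricsReport:
    """Counts plus the four lesion-level metrics; undefined ratios are None."""

    tp: int
    fp: int
    fn: int
    n_subjects: int
    sensitivity: float | None
    precision: float | None
    f1: float | None
    fp_avg: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "n_subjects": self.n_subjects,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "fp_avg": self.fp_avg,
        }


def lesion_metrics(tp: int, fp: int, fn: int, n_subjects: int) -> MetricsReport:
    """Sensitivity, precision, F1 and FPavg from raw counts."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be non-negative")
    if n_subjects < 1:
        raise ValidationError(f"n_subjects must be >= 1, got {n_subjects}")
    sens = tp / (tp + fn) if tp + fn > 0 else None
    prec = tp / (tp + fp) if tp + fp > 0 else None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    elif sens == prec == 0.0:
        f1 = 0.0
    else:
        f1 = None
    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        n_subjects=n_subjects,
        sensitivity=sens,
        precision=prec,
        f1=f1,
        fp_avg=fp / n_subjects,
    )


def metrics_from_match(match: MatchResult, n_subjects: int) -> MetricsReport:
    return lesion_metrics(match.tp, len(match.fp), len(match.fn), n_subjects)


# ---------------------------------------------------------------------------
# Size stratification


@dataclass(frozen=True)
class SizeBins:
    """Half-open diameter bins [lo, hi) in mm covering (0, inf)."""

    edges_mm: tuple[float, ...] = (0.0, 2.5, 3.0, 4.0, 5.0, 6.0, math.inf)

    def __post_init__(self):
        e = self.edges_mm
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValidationError(f"bin edges must be strictly increasing, got {e}")
        if e[0] > 0 or e[-1] != math.inf:
            raise ValidationError("bins must cover (0, inf)")
        object.__setattr__(self, "edges_mm", tuple(float(x) for x in e))

    @property
    def n_bins(self) -> int:
        return len(self.edges_mm) - 1

    def bin_of(self, d_mm: float) -> int:
        idx = int(np.searchsorted(self.edges_mm, d_mm, side="right")) - 1
        return min(max(idx, 0), self.n_bins - 1)

    def label(self, idx: int) -> str:
        lo, hi = self.edges_mm[idx], self.edges_mm[idx + 1]
        return f">={lo:g}" if math.isinf(hi) else f"[{lo:g},{hi:g})"


def estimate_diameter(box: Box, pixel_spacing_mm: tuple[float, float]) -> float:
    """Estimated lesion diameter: mean of the two box side lengths in mm."""
    row_mm, col_mm = pixel_spacing_mm
    if row_mm <= 0 or col_mm <= 0:
        raise ValidationError("pixel spacing must be positive")
    return (box.w * col_mm + box.h * row_mm) / 2.0


def size_stratified_metrics(
    match: MatchResult,
    bins: SizeBins,
    pixel_spacing_mm: tuple[float, float],
    n_subjects: int = 1,
) -> pd.DataFrame:
    """Per-size-bin detection outcome table.

    True positives and false negatives are binned by the *ground-truth* box
    diameter, false positives by the predicted box diameter.  Per-bin
    sensitivity and precision use the same absent-on-0/0 convention as the
    global metrics.
    """
    tp = np.zeros(bins.n_bins, int)
    fn = np.zeros(bins.n_bins, int)
    fp = np.zeros(bins.n_bins, int)
    for _, gt, _ in match.tp_pairs:
        tp[bins.bin_of(estimate_diameter(gt, pixel_spacing_mm))] += 1
    for gt in match.fn:
        fn[bins.bin_of(estimate_diameter(gt, pixel_spacing_mm))] += 1
    for p in match.fp:
        fp[bins.bin_of(estimate_diameter(p, pixel_spacing_mm))] += 1
    rows = []
    for i in range(bins.n_bins):
        m = lesion_metrics(int(tp[i]), int(fp[i]), int(fn[i]), n_subjects)
        rows.append(
            {
                "bin": bins.label(i),
                "lo_mm": bins.edges_mm[i],
                "hi_mm": bins.edges_mm[i + 1],
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "sensitivity": m.sensitivity,
                "precision": m.precision,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regional analysis


def assign_region(
    box: Box,
    region_masks: Volume,
    label_names: Mapping[int, str] = DEFAULT_REGION_LABELS,
) -> str:
    """Anatomical region of a box: label of the voxel at its centre.

    The centre is rounded to the nearest voxel; background (label 0) and
    labels outside the mapping return ``"excluded"``, mirroring the rule
    that lesions outside atlas coverage are dropped from regional analysis.
    """
    nr, nc = region_masks.slice_dims
    r = int(round(box.cy))
    c = int(round(box.cx))
    if not (0 <= r < nr and 0 <= c < nc) or box.slice_index >= region_masks.n_slices:
        raise GridMismatchError(
            f"box centre ({r},{c},z{box.slice_index}) outside region grid "
            f"{region_masks.data.shape}"
        )
    label = int(region_masks.get_slice(box.slice_index)[r, c])
    return label_names.get(label, "excluded") if label != 0 else "excluded"


def regional_metrics(
    match: MatchResult,
    region_masks: Volume,
    label_names: Mapping[int, str] = DEFAULT_REGION_LABELS,
    n_subjects: int = 1,
) -> pd.DataFrame:
    """Per-region detection metrics over anatomically classifiable lesions.

    Ground-truth lesions are assigned by the ground-truth box centre, false
    positives by the predicted box centre; ``excluded`` lesions are dropped
    (their count is reported separately in the table's attrs).
    """
    regions = sorted(set(label_names.values()))
    tp = {r: 0 for r in regions}
    fn = {r: 0 for r in regions}
    fp = {r: 0 for r in regions}
    excluded = 0
    for p, gt, _ in match.tp_pairs:
        r = assign_region(gt, region_masks, label_names)
        if r == "excluded":
            excluded += 1
        else:
            tp[r] += 1
    for gt in match.fn:
        r = assign_region(gt, region_masks, label_names)
        if r == "excluded":
            excluded += 1
        else:
            fn[r] += 1
    for p in match.fp:
        r = assign_region(p, region_masks, label_names)
        if r == "excluded":
            excluded += 1
        else:
            fp[r] += 1
    rows = []
    for r in regions:
        m = lesion_metrics(tp[r], fp[r], fn[r], n_subjects)
        rows.append(
            {
                "region": r,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "sensitivity": m.sensitivity,
                "precision": m.precision,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    return df


# ---------------------------------------------------------------------------
# Patient-level burden


@dataclass(frozen=True)
class BurdenThresholds:
    """Burden dichotomy and hemosiderin-ARIA severity bins (lesion counts)."""

    elevated_min: int = 4
    aria_mild: tuple[int, int] = (1, 5)
    aria_moderate: tuple[int, int] = (6, 10)
    aria_severe_min: int = 11

    def __post_init__(self):
        if self.aria_mild[0] != 1 or self.aria_mild[1] + 1 != self.aria_moderate[0]:
            raise ValidationError("ARIA bins must be contiguous from 1")
        if self.aria_moderate[1] + 1 != self.aria_severe_min:
            raise ValidationError("ARIA bins must be contiguous and non-overlapping")
        if self.elevated_min < 1:
            raise ValidationError("elevated_min must be >= 1")


def patient_burden_class(count: int, th: BurdenThresholds = BurdenThresholds()) -> str:
    """Dichotomize a lesion count: ``elevated`` iff count >= elevated_min."""
    if count < 0:
        raise ValidationError("count must be >= 0")
    return "elevated" if count >= th.elevated_min else "low"


def patient_level_metrics(
    pred_counts: Mapping[str, int],
    true_counts: Mapping[str, int],
    th: BurdenThresholds = BurdenThresholds(),
) -> dict:
    """Patient-level 2x2 screening metrics at the burden threshold.

    Subjects are dichotomized by their true and predicted burden class;
    sensitivity, specificity, PPV and NPV follow; ratios with empty
    denominators are absent (None).  Both mappings must cover the same
    subject set.
    """
    if set(pred_counts) != set(true_counts):
        raise ValidationError(
            "predicted and true counts must cover the same subjects; "
            f"difference: {set(pred_counts) ^ set(true_counts)}"
        )
    tp = fp = fn = tn = 0
    for s in true_counts:
        truth = patient_burden_class(true_counts[s], th) == "elevated"
        pred = patient_burden_class(pred_counts[s], th) == "elevated"
        if truth and pred:
            tp += 1
        elif truth and not pred:
            fn += 1
        elif not truth and pred:
            fp += 1
        else:
            tn += 1

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def aria_severity(lobar_count: int, th: BurdenThresholds = BurdenThresholds()) -> str:
    """Hemosiderin-ARIA severity bin from a lobar microbleed count."""
    if lobar_count < 0:
        raise ValidationError("count must be >= 0")
    if lobar_count == 0:
        return "none"
    if lobar_count <= th.aria_mild[1]:
        return "mild"
    if lobar_count <= th.aria_moderate[1]:
        return "moderate"
    return "severe"
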