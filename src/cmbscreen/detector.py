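"""Candidate detection: a classical channel-1 detector plus postprocessing.

The detection stage is a pluggable seam: a learned single-stage detector can
be registered as a backend, and a built-in classical detector derived from
the MIG channel-1 operators provides a desk-scale default.  The classical
backend boxes each 8-connected component of the channel-1 support (tight
bounds, optionally dilated about the centre by ``box_scale``) and scores it
either by the component's peak channel-1 value ("depth", the normalized
interior distance — deeper, rounder candidates score higher) or by its
min-max-rescaled mean |Z| ("zmean").

Postprocessing is applied uniformly regardless of backend: confidence
filtering (inclusive at the threshold, default 0.2) followed by greedy
per-slice non-maximum suppression at IoU 0.5.

``box_scale`` defaults to 1.0 — the tight candidate bounds.  A dilation
factor of 2.0 (used as a box-regression hyperparameter when training neural
detectors on this task) is available through the config, but for a
connected-component detector any dilation ``s`` caps the achievable IoU
against a tight ground-truth box near ``1/s^2``, so the tight default is
the only one under which the classical backend can satisfy the IoU-0.5
true-positive criterion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError, DegenerateSliceError, ValidationError
from .evaluation import iou
from .imaging_io import Box, Volume
from .mig import MigConfig, MultiChannelSlice, make_multichannel, zscore_slice

__all__ = [
    "DetectorConfig",
    "DetectionResult",
    "detect_slice",
    "filter_by_confidence",
    "nms",
    "run_detector",
    "register_detector_backend",
    "detector_backend_names",
]

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectorConfig:
    conf_thresh: float = 0.2
    nms_iou: float = 0.5
    box_scale: float = 1.0
    score_mode: str = "depth"

    def __post_init__(self):
        if not 0.0 <= self.conf_thresh <= 1.0:
            raise ValidationError(f"conf_thresh must lie in [0,1], got {self.conf_thresh}")
        if not 0.0 < self.nms_iou <= 1.0:
            raise ValidationError(f"nms_iou must lie in (0,1], got {self.nms_iou}")
        if self.box_scale <= 0:
            raise ValidationError(f"box_scale must be positive, got {self.box_scale}")
        if self.score_mode not in ("depth", "zmean"):
            raise ValidationError(f"score_mode must be 'depth' or 'zmean'")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:8]


@dataclass
class DetectionResult:
    """All surviving detections of one subject, sorted by confidence."""

    subject_id: str
    boxes: list[Box]
    provenance: str = ""

    def __post_init__(self):
        self.boxes = sorted(
            self.boxes, key=lambda b: (-b.confidence, b.slice_index, b.cy, b.cx)
        )

    def __len__(self) -> int:
        return len(self.boxes)

    def to_records(self) -> list[dict]:
        return [
            {
                "slice": b.slice_index,
                "cx": b.cx,
                "cy": b.cy,
                "w": b.w,
                "h": b.h,
                "conf": b.confidence,
            }
            for b in self.boxes
        ]

    @classmethod
    def from_records(
        cls, subject_id: str, records: Iterable[dict], provenance: str = ""
    ) -> "DetectionResult":
        boxes = [
            Box(
                slice_index=int(r["slice"]),
                cx=float(r["cx"]),
                cy=float(r["cy"]),
                w=float(r["w"]),
                h=float(r["h"]),
                confidence=float(r["conf"]),
            )
            for r in records
        ]
        return cls(subject_id=subject_id, boxes=boxes, provenance=provenance)


# ---------------------------------------------------------------------------
# Classical channel-1 detector


def _channel1_boxes(
    mc: MultiChannelSlice,
    z: np.ndarray | None,
    cfg: DetectorConfig,
    slice_index: int,
) -> list[Box]:
    """Raw (pre-filter, pre-NMS) boxes from the channel-1 support."""
    support = mc.ch1 > 0
    labeled, n = ndi.label(support, structure=_CONN8)
    if n == 0:
        return []
    if cfg.score_mode == "depth":
        scores = ndi.maximum(mc.ch1, labeled, index=np.arange(1, n + 1))
    else:
        if z is None:
            raise ConfigurationError("score_mode 'zmean' requires the z-scored slice")
        means = ndi.mean(np.abs(z), labeled, index=np.arange(1, n + 1))
        lo, hi = means.min(), means.max()
        scores = np.ones_like(means) if hi == lo else (means - lo) / (hi - lo)
    boxes: list[Box] = []
    frame = mc.shape
    for idx, obj in enumerate(ndi.find_objects(labeled)):
        rs, cs = obj
        b = Box(
            slice_index=slice_index,
            cx=(cs.start + cs.stop - 1) / 2.0,
            cy=(rs.start + rs.stop - 1) / 2.0,
            w=float(cs.stop - cs.start),
            h=float(rs.stop - rs.start),
            confidence=float(np.clip(scores[idx], 0.0, 1.0)),
        )
        boxes.append(b.scaled(cfg.box_scale).clipped_to_frame(frame))
    return boxes


def detect_slice(
    mc: MultiChannelSlice,
    cfg: DetectorConfig | None = None,
    slice_index: int = 0,
    z: np.ndarray | None = None,
) -> list[Box]:
    """Classical detection on one multi-channel slice.

    One box per 8-connected component of the channel-1 support, scored per
    ``cfg.score_mode``, then confidence filtering and NMS.  An empty list is
    a valid outcome.
    """
    cfg = cfg or DetectorConfig()
    boxes = _channel1_boxes(mc, z, cfg, slice_index)
    return nms(filter_by_confidence(boxes, cfg.conf_thresh), cfg.nms_iou)


# ---------------------------------------------------------------------------
# Postprocessing


def filter_by_confidence(boxes: Sequence[Box], conf_thresh: float) -> list[Box]:
    """Keep boxes with confidence >= threshold (inclusive); order preserved."""
    return [b for b in boxes if b.confidence >= conf_thresh]


def nms(boxes: Sequence[Box], nms_iou: float) -> list[Box]:
    """Greedy per-slice non-maximum suppression.

    Repeatedly keep the highest-confidence remaining box and discard boxes
    with IoU strictly greater than ``nms_iou`` against it.  Ties in
    confidence are broken by (slice_index, cy, cx) so the result is
    deterministic.  Surviving boxes form an independent set: no pair has
    IoU above the threshold.
    """
    order = sorted(boxes, key=lambda b: (-b.confidence, b.slice_index, b.cy, b.cx))
    kept: list[Box] = []
    for b in order:
        if all(iou(b, k) <= nms_iou for k in kept):
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# Backend registry and volume-level driver

# An external backend receives the per-slice 3-channel image and the slice
# index and returns raw pixel-space boxes with confidences; all geometry
# postprocessing stays here so evaluation is backend-agnostic.
DetectorBackend = Callable[[MultiChannelSlice, int], list[Box]]

_CHANNEL1 = "channel1"
_DETECTOR_BACKENDS: dict[str, DetectorBackend | None] = {_CHANNEL1: None}


def register_detector_backend(name: str, fn: DetectorBackend) -> None:
    _DETECTOR_BACKENDS[name] = fn


def detector_backend_names() -> list[str]:
    return sorted(_DETECTOR_BACKENDS)


def run_detector(
    vol: Volume,
    mask: Volume,
    backend: str | DetectorBackend = _CHANNEL1,
    cfg: DetectorConfig | None = None,
    mig_cfg: MigConfig | None = None,
) -> DetectionResult:
    """Slice-wise detection over a preprocessed volume.

    Each slice is expanded to its multi-channel representation and handed to
    the backend (a registered name or a callable); confidence filtering and
    NMS are applied uniformly to every backend's output.  Slices that cannot
    be standardized contribute no classical candidates (the backend still
    runs, on zero channels).
    """
    backend_fn: DetectorBackend | None = None
    if callable(backend):
        backend_fn = backend
        backend = getattr(backend, "__name__", "custom")
    elif backend not in _DETECTOR_BACKENDS:
        raise ConfigurationError(
            f"unknown detector backend {backend!r}; registered: {detector_backend_names()}"
        )
    else:
        backend_fn = _DETECTOR_BACKENDS[backend]
    cfg = cfg or DetectorConfig()
    mig_cfg = mig_cfg or MigConfig()
    spacing = vol.in_plane_spacing
    all_boxes: list[Box] = []
    for k, sl in vol.iter_slices():
        msl = mask.get_slice(k)
        z: np.ndarray | None = None
        try:
            z = zscore_slice(sl, msl)
            mc = make_multichannel(sl, msl, mig_cfg, spacing)
        except (DegenerateSliceError, ValidationError):
            zeros = np.zeros(sl.shape)
            mc = MultiChannelSlice(zeros, zeros.copy(), zeros.copy(), tuple(spacing))
        if backend_fn is None:  # built-in channel-1 detector
            raw = _channel1_boxes(mc, z, cfg, k)
        else:
            raw = backend_fn(mc, k)
        all_boxes.extend(nms(filter_by_confidence(raw, cfg.conf_thresh), cfg.nms_iou))
    return DetectionResult(
        subject_id=vol.id,
        boxes=all_boxes,
        provenance=f"{backend}:{cfg.digest()}",
    )
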