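"""End-to-end orchestration: simulate -> preprocess -> MIG -> detect -> evaluate.

This module glues the stages together behind a single configuration mapping
(the YAML schema used by the command-line interface) and produces the report
tables: global lesion-level metrics, per-size-bin and per-region tables,
per-patient burden classification, and a plain-text summary.  Detections are
made on the preprocessed grid and mapped back to the annotation grid before
scoring, so evaluation is independent of the super-resolution factor.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detector import DetectionResult, DetectorConfig, run_detector
from .errors import ConfigurationError, ValidationError
from .evaluation import (
    BurdenThresholds,
    MatchResult,
    MetricsReport,
    SizeBins,
    match_detections,
    metrics_from_match,
    patient_burden_class,
    patient_level_metrics,
    regional_metrics,
    size_stratified_metrics,
)
from .imaging_io import rescale_boxes
from .mig import MigConfig
from .phantom import PhantomSpec, PhantomSubject, generate_cohort, make_oracle_backend
from .preprocess import PreprocessConfig, preprocess_volume

__all__ = [
    "parse_config",
    "detect_subject",
    "evaluate_cohort",
    "run_all",
    "config_digest",
]

_SECTIONS = {"seed", "phantom", "preprocess", "mig", "detector", "evaluation"}


def _build(cls, section: Mapping[str, Any], name: str, coerce: dict | None = None):
    coerce = coerce or {}
    kwargs = {}
    valid = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
    for key, value in section.items():
        if key not in valid:
            raise ConfigurationError(f"{name}: unknown field {key!r}")
        if key in coerce:
            value = coerce[key](value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValidationError) as exc:
        raise ConfigurationError(f"{name}: {exc}") from exc


def parse_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Validate a configuration mapping and build the typed stage configs.

    Returns a dict with keys ``seed``, ``n_subjects``, ``phantom`` (a
    :class:`PhantomSpec` template), ``preprocess``, ``mig``, ``detector``
    (config), ``backend`` (name), ``evaluation`` (iou_thresh, bins,
    burden thresholds).  Unknown sections or fields raise
    :class:`ConfigurationError` naming the offending field.
    """
    unknown = set(config) - _SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown configuration sections: {sorted(unknown)}")
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigurationError(f"seed: must be a non-negative integer, got {seed!r}")

    ph = dict(config.get("phantom", {}))
    n_subjects = ph.pop("n_subjects", 1)
    if not isinstance(n_subjects, int) or n_subjects < 1:
        raise ConfigurationError(f"phantom.n_subjects: must be a positive integer")
    tupled = {
        "dims": tuple,
        "spacing": tuple,
        "diameter_range_mm": tuple,
    }
    spec = _build(PhantomSpec, {**ph, "seed": seed}, "phantom", tupled)

    pre = _build(
        PreprocessConfig,
        config.get("preprocess", {}),
        "preprocess",
        {"target_spacing": tuple},
    )
    mig = _build(MigConfig, config.get("mig", {}), "mig")

    det_section = dict(config.get("detector", {}))
    backend = det_section.pop("backend", "channel1")
    det = _build(DetectorConfig, det_section, "detector")

    ev = dict(config.get("evaluation", {}))
    iou_thresh = ev.pop("iou_thresh", 0.5)
    edges = ev.pop("size_bin_edges", None)
    elevated_min = ev.pop("elevated_min", 4)
    if ev:
        raise ConfigurationError(f"evaluation: unknown fields {sorted(ev)}")
    if edges:
        edges = [float(e) for e in edges]
        if edges[-1] != float("inf"):
            edges.append(float("inf"))
        bins = SizeBins(tuple(edges))
    else:
        bins = SizeBins()
    return {
        "seed": seed,
        "n_subjects": n_subjects,
        "phantom": spec,
        "preprocess": pre,
        "mig": mig,
        "detector": det,
        "backend": backend,
        "iou_thresh": float(iou_thresh),
        "bins": bins,
        "burden": BurdenThresholds(elevated_min=elevated_min),
    }


def config_digest(config: Mapping[str, Any]) -> str:
    """Stable digest of a configuration mapping (order-insensitive)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Detection on one subject


def detect_subject(
    subject: PhantomSubject,
    pre_cfg: PreprocessConfig,
    mig_cfg: MigConfig,
    det_cfg: DetectorConfig,
    backend: str | Callable = "channel1",
) -> DetectionResult:
    """Preprocess, detect, and map boxes back to the annotation grid."""
    processed, mask = preprocess_volume(subject.volume, pre_cfg, subject.brain_mask)
    if processed.n_slices != subject.volume.n_slices:
        raise ValidationError(
            "slice count changed during preprocessing; detections cannot be "
            "mapped back to the annotation grid"
        )
    if backend == "oracle":
        backend = make_oracle_backend(
            # oracle boxes live on the original grid; rescale to processed
            _rescaled_annotations(subject, processed),
            seed=int(subject.volume.data.shape[0]),
        )
        backend.__name__ = "oracle"  # type: ignore[attr-defined]
    result = run_detector(processed, mask, backend, det_cfg, mig_cfg)
    back = rescale_boxes(
        result.boxes, processed.in_plane_spacing, subject.volume.in_plane_spacing
    )
    return DetectionResult(
        subject_id=subject.volume.id, boxes=back, provenance=result.provenance
    )


def _rescaled_annotations(subject: PhantomSubject, processed):
    from dataclasses import replace as dreplace

    boxes = rescale_boxes(
        subject.annotations.boxes,
        subject.volume.in_plane_spacing,
        processed.in_plane_spacing,
    )
    return dreplace(
        subject.annotations, boxes=boxes, image_dims=processed.slice_dims
    )


# ---------------------------------------------------------------------------
# Cohort evaluation


def evaluate_cohort(
    subjects: Sequence[PhantomSubject],
    detections: Sequence[DetectionResult],
    iou_thresh: float = 0.5,
    bins: SizeBins | None = None,
    burden: BurdenThresholds | None = None,
) -> dict[str, Any]:
    """Score a cohort: global, per-size, per-region, and per-patient tables."""
    if len(subjects) != len(detections):
        raise ValidationError("subjects and detections must align 1:1")
    bins = bins or SizeBins()
    burden = burden or BurdenThresholds()
    n = len(subjects)

    merged: MatchResult | None = None
    patient_rows = []
    pred_counts: dict[str, int] = {}
    true_counts: dict[str, int] = {}
    region_frames = []
    for subj, det in zip(subjects, detections):
        match = match_detections(det.boxes, subj.annotations.boxes, iou_thresh)
        merged = match if merged is None else merged.merged(match)
        sid = subj.volume.id
        true_counts[sid] = len(subj.annotations)
        pred_counts[sid] = len(det.boxes)
        patient_rows.append(
            {
                "subject": sid,
                "true_count": true_counts[sid],
                "pred_count": pred_counts[sid],
                "true_class": patient_burden_class(true_counts[sid], burden),
                "pred_class": patient_burden_class(pred_counts[sid], burden),
            }
        )
        region_frames.append(regional_metrics(match, subj.region_masks))

    spacing = subjects[0].volume.in_plane_spacing
    assert merged is not None
    global_metrics = metrics_from_match(merged, n)
    size_table = size_stratified_metrics(merged, bins, spacing, n)

    regions = (
        pd.concat(region_frames)
        .groupby("region", as_index=False)[["tp", "fp", "fn"]]
        .sum()
    )
    regions["sensitivity"] = regions.apply(
        lambda r: r.tp / (r.tp + r.fn) if r.tp + r.fn > 0 else None, axis=1
    )
    regions["precision"] = regions.apply(
        lambda r: r.tp / (r.tp + r.fp) if r.tp + r.fp > 0 else None, axis=1
    )

    patients = pd.DataFrame(patient_rows)
    patient_metrics = patient_level_metrics(pred_counts, true_counts, burden)
    return {
        "match": merged,
        "global": global_metrics,
        "size": size_table,
        "regions": regions,
        "patients": patients,
        "patient_metrics": patient_metrics,
    }


# ---------------------------------------------------------------------------
# Full run


def _summary_text(report: dict[str, Any]) -> str:
    g: MetricsReport = report["global"]

    def fmt(v):
        return "absent" if v is None else f"{v:.3f}"

    lines = [
        "Lesion-level detection summary",
        "TP\tFP\tFN\tSensitivity\tPrecision\tF1-score\tFPavg",
        f"{g.tp}\t{g.fp}\t{g.fn}\t{fmt(g.sensitivity)}\t{fmt(g.precision)}"
        f"\t{fmt(g.f1)}\t{g.fp_avg:.2f}",
        "",
        "Patient-level burden screening",
    ]
    pm = report["patient_metrics"]
    lines.append(
        "sens={} spec={} ppv={} npv={} (tp={} fp={} fn={} tn={})".format(
            fmt(pm["sensitivity"]),
            fmt(pm["specificity"]),
            fmt(pm["ppv"]),
            fmt(pm["npv"]),
            pm["tp"],
            pm["fp"],
            pm["fn"],
            pm["tn"],
        )
    )
    return "\n".join(lines) + "\n"


def run_all(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline from a configuration mapping.

    Writes the metric tables (JSON + CSV), a plain-text summary, and a run
    manifest into ``out_dir``; returns the paths.  Two runs with the same
    configuration produce byte-identical metric tables.
    """
    parsed = parse_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    subjects = generate_cohort(parsed["n_subjects"], parsed["phantom"], parsed["seed"])
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    detections = [
        detect_subject(
            s, parsed["preprocess"], parsed["mig"], parsed["detector"], parsed["backend"]
        )
        for s in subjects
    ]
    timings["detect"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = evaluate_cohort(
        subjects, detections, parsed["iou_thresh"], parsed["bins"], parsed["burden"]
    )
    timings["evaluate"] = time.perf_counter() - t0

    paths: dict[str, Path] = {}
    g: MetricsReport = report["global"]
    paths["global_json"] = out_dir / "global_metrics.json"
    paths["global_json"].write_text(
        json.dumps(
            {"lesion_level": g.as_dict(), "patient_level": report["patient_metrics"]},
            indent=2,
        )
        + "\n"
    )
    for name, df in (("size_bins", report["size"]), ("regions", report["regions"]),
                     ("patients", report["patients"])):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    paths["summary"] = out_dir / "summary.txt"
    paths["summary"].write_text(_summary_text(report))

    manifest = {
        "tool": "cmbscreen",
        "version": __version__,
        "config_digest": config_digest(config),
        "seed": parsed["seed"],
        "n_subjects": parsed["n_subjects"],
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
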