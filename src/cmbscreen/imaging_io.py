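"""Volumes, boxes, and annotation I/O.

The carriers defined here are shared by every stage of the pipeline:

* :class:`Volume` — a 3D intensity grid with its voxel spacing in mm and the
  identity of the through-plane (slice) axis.  2D multi-slice GRE acquisitions
  have strongly anisotropic spacing (sub-millimetre in plane, several mm
  between slices), so the slice axis is inferred as the axis with the largest
  spacing unless stated explicitly.
* :class:`Box` — one per-slice, axis-aligned lesion bounding box.  Coordinates
  are 0-based and pixel-centred: pixel ``i`` spans the continuous interval
  ``[i - 0.5, i + 0.5]``, and a ``w``-wide box centred at ``cx`` spans
  ``[cx - w/2, cx + w/2]``.  ``cx`` runs along image columns (x), ``cy``
  along rows (y).
* :class:`AnnotationSet` — the ground-truth container for one subject.

Annotations can be converted between binary segmentation masks, pixel-space
boxes, and normalized YOLO text records (one ``.txt`` per slice, class id 0
for microbleeds).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

from .errors import DimensionalityError, ParseError, ValidationError

__all__ = [
    "Volume",
    "Box",
    "AnnotationSet",
    "read_volume",
    "write_volume",
    "boxes_from_mask",
    "to_yolo",
    "from_yolo",
    "write_yolo_dir",
    "read_yolo_dir",
    "rescale_boxes",
]

# 8-connectivity structuring element for 2D component labeling
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and slice-axis identity.

    ``spacing[i]`` is the voxel pitch along data axis ``i``; ``slice_axis``
    names the through-plane axis.  The canonical in-memory layout produced by
    the phantom generator is ``(rows, cols, slices)`` with ``slice_axis=2``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    id: str = ""

    def __post_init__(self):
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume requires a 3D array, got shape {self.data.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive mm values, got {self.spacing}")
        if not 0 <= self.slice_axis <= 2:
            raise ValidationError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")
        if self.data.shape[self.slice_axis] < 1:
            raise ValidationError("volume must contain at least one slice")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def slice_dims(self) -> tuple[int, int]:
        """(n_rows, n_cols) of one slice, in-plane axes kept in axis order."""
        shape = list(self.data.shape)
        shape.pop(self.slice_axis)
        return tuple(shape)  # type: ignore[return-value]

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        """(row_mm, col_mm) spacing of one slice."""
        sp = list(self.spacing)
        sp.pop(self.slice_axis)
        return tuple(sp)  # type: ignore[return-value]

    @property
    def slice_spacing(self) -> float:
        return self.spacing[self.slice_axis]

    def get_slice(self, index: int) -> np.ndarray:
        """Return the 2D slice at ``index`` (a view when possible)."""
        return np.moveaxis(self.data, self.slice_axis, 0)[index]

    def iter_slices(self):
        moved = np.moveaxis(self.data, self.slice_axis, 0)
        for k in range(moved.shape[0]):
            yield k, moved[k]

    def with_data(self, data: np.ndarray, spacing: Sequence[float] | None = None) -> "Volume":
        return replace(
            self,
            data=data,
            spacing=tuple(spacing) if spacing is not None else self.spacing,
        )

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )


@dataclass
class Box:
    """One per-slice axis-aligned bounding box in pixel coordinates.

    ``cx``/``w`` run along columns, ``cy``/``h`` along rows; both sides must
    be positive and the confidence lies in [0, 1].
    """

    slice_index: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float = 1.0
    label: str = "CMB"

    def __post_init__(self):
        if self.slice_index < 0:
            raise ValidationError(f"slice_index must be >= 0, got {self.slice_index}")
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"box sides must be positive, got w={self.w}, h={self.h}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence must lie in [0,1], got {self.confidence}")

    # continuous extents under the pixel-centre convention
    @property
    def x1(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def scaled(self, factor: float) -> "Box":
        """Symmetric enlargement (or shrinkage) about the box centre."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return replace(self, w=self.w * factor, h=self.h * factor)

    def clipped_to_frame(self, image_dims: tuple[int, int]) -> "Box":
        """Intersect with the image frame ``[-0.5, n-0.5]`` per axis."""
        n_rows, n_cols = image_dims
        x1 = max(self.x1, -0.5)
        x2 = min(self.x2, n_cols - 0.5)
        y1 = max(self.y1, -0.5)
        y2 = min(self.y2, n_rows - 0.5)
        if x2 <= x1 or y2 <= y1:
            raise ValidationError("box does not intersect the image frame")
        return replace(self, cx=(x1 + x2) / 2, cy=(y1 + y2) / 2, w=x2 - x1, h=y2 - y1)

    def center_inside(self, image_dims: tuple[int, int]) -> bool:
        n_rows, n_cols = image_dims
        return -0.5 <= self.cx <= n_cols - 0.5 and -0.5 <= self.cy <= n_rows - 0.5


@dataclass
class AnnotationSet:
    """All ground-truth boxes of one subject plus the slice geometry."""

    subject_id: str
    boxes: list[Box]
    image_dims: tuple[int, int]
    n_slices: int | None = None

    def __post_init__(self):
        nr, nc = self.image_dims
        if nr <= 0 or nc <= 0:
            raise ValidationError(f"image_dims must be positive, got {self.image_dims}")
        for b in self.boxes:
            if self.n_slices is not None and b.slice_index >= self.n_slices:
                raise ValidationError(
                    f"box slice_index {b.slice_index} >= n_slices {self.n_slices}"
                )
            if not b.center_inside(self.image_dims):
                raise ValidationError(
                    f"box centre ({b.cx:.1f}, {b.cy:.1f}) outside {self.image_dims} frame"
                )

    def boxes_on_slice(self, index: int) -> list[Box]:
        return [b for b in self.boxes if b.slice_index == index]

    def __len__(self) -> int:
        return len(self.boxes)


# ---------------------------------------------------------------------------
# NIfTI volume I/O


def read_volume(path: str | os.PathLike) -> Volume:
    """Load a 3D NIfTI-1/2 file.

    Spacing comes from the header zooms; the slice axis is the axis with the
    largest spacing; intensities are returned unchanged.
    """
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except DimensionalityError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path} is not a 3D volume (observed shape {data.shape})"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    slice_axis = int(np.argmax(zooms))
    return Volume(data=data, spacing=zooms, slice_axis=slice_axis, id=path.name.split(".")[0])


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a :class:`Volume` as NIfTI-1; round-trips data bit-exactly."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, path)
    except Exception as exc:
        raise OSError(f"cannot write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Mask -> boxes


def boxes_from_mask(mask: Volume) -> AnnotationSet:
    """One tight box per 2D 8-connected component of a binary mask.

    Components are found slice by slice (never across slices: with 6.5 mm
    gaps a through-plane merge would join unrelated lesions).  Confidence of
    every generated box is 1.0.
    """
    values = np.unique(mask.data)
    if not np.all(np.isin(values, (0, 1))):
        raise ValidationError(
            f"mask must be binary (0/1), found values {values[:10].tolist()}"
        )
    boxes: list[Box] = []
    for k, sl in mask.iter_slices():
        labeled, n = ndi.label(sl > 0, structure=_CONN8)
        for obj in ndi.find_objects(labeled):
            if obj is None:
                continue
            rs, cs = obj
            boxes.append(
                Box(
                    slice_index=k,
                    cx=(cs.start + cs.stop - 1) / 2.0,
                    cy=(rs.start + rs.stop - 1) / 2.0,
                    w=float(cs.stop - cs.start),
                    h=float(rs.stop - rs.start),
                    confidence=1.0,
                )
            )
    return AnnotationSet(
        subject_id=mask.id,
        boxes=boxes,
        image_dims=mask.slice_dims,
        n_slices=mask.n_slices,
    )


# ---------------------------------------------------------------------------
# YOLO text records

_DEFAULT_CLASS_IDS: Mapping[str, int] = {"CMB": 0}


def to_yolo(
    ann: AnnotationSet,
    class_ids: Mapping[str, int] = _DEFAULT_CLASS_IDS,
    with_confidence: bool = False,
) -> dict[int, str]:
    """Serialize an annotation set to per-slice YOLO text records.

    One record per box: ``class cx/ncols cy/nrows w/ncols h/nrows`` with
    6-decimal fixed point; all normalized values must lie in [0, 1].  Returns
    a mapping from slice index to file content; slices without boxes map to
    an empty string when ``ann.n_slices`` is known.
    """
    nr, nc = ann.image_dims
    n_slices = ann.n_slices
    out: dict[int, list[str]] = {}
    if n_slices is not None:
        out = {k: [] for k in range(n_slices)}
    for b in ann.boxes:
        if b.x1 < -0.5 or b.x2 > nc - 0.5 or b.y1 < -0.5 or b.y2 > nr - 0.5:
            raise ValidationError(
                f"box on slice {b.slice_index} exceeds the {nr}x{nc} frame: "
                f"x [{b.x1:.1f}, {b.x2:.1f}], y [{b.y1:.1f}, {b.y2:.1f}]"
            )
        vals = (b.cx / nc, b.cy / nr, b.w / nc, b.h / nr)
        if any(v < 0.0 or v > 1.0 for v in vals):
            raise ValidationError(
                f"box on slice {b.slice_index} exceeds the frame after normalization: {vals}"
            )
        cls = class_ids.get(b.label, 0)
        rec = f"{cls} " + " ".join(f"{v:.6f}" for v in vals)
        if with_confidence:
            rec += f" {b.confidence:.6f}"
        out.setdefault(b.slice_index, []).append(rec)
    return {k: ("\n".join(lines) + "\n" if lines else "") for k, lines in out.items()}


def from_yolo(
    records: str,
    image_dims: tuple[int, int],
    slice_index: int,
    class_labels: Mapping[int, str] | None = None,
) -> list[Box]:
    """Parse YOLO text records back to pixel-space boxes.

    Each record holds 5 whitespace-separated fields (an optional 6th is read
    as the confidence); normalized coordinates must lie in [0, 1].
    """
    nr, nc = image_dims
    class_labels = class_labels or {0: "CMB"}
    boxes: list[Box] = []
    for ln, raw in enumerate(records.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise ParseError(f"expected 5 or 6 fields, got {len(fields)}: {raw!r}", ln)
        try:
            cls = int(fields[0])
            vals = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"non-numeric field in {raw!r}", ln) from exc
        coords, conf = vals[:4], (vals[4] if len(vals) == 5 else 1.0)
        if any(v < 0.0 or v > 1.0 for v in coords):
            raise ValidationError(
                f"line {ln}: normalized coordinate outside [0,1]: {coords}"
            )
        boxes.append(
            Box(
                slice_index=slice_index,
                cx=coords[0] * nc,
                cy=coords[1] * nr,
                w=coords[2] * nc,
                h=coords[3] * nr,
                confidence=conf,
                label=class_labels.get(cls, str(cls)),
            )
        )
    return boxes


def write_yolo_dir(
    ann: AnnotationSet,
    directory: str | os.PathLike,
    with_confidence: bool = False,
) -> list[Path]:
    """Write one ``<subject>_z<index>.txt`` per slice (UTF-8, LF endings)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, content in sorted(to_yolo(ann, with_confidence=with_confidence).items()):
        p = directory / f"{ann.subject_id}_z{k}.txt"
        p.write_bytes(content.encode("utf-8"))
        paths.append(p)
    return paths


def read_yolo_dir(
    directory: str | os.PathLike,
    subject_id: str,
    image_dims: tuple[int, int],
    n_slices: int | None = None,
) -> AnnotationSet:
    """Read every ``<subject>_z<index>.txt`` in a directory back into boxes."""
    directory = Path(directory)
    boxes: list[Box] = []
    seen = 0
    for p in sorted(directory.glob(f"{subject_id}_z*.txt")):
        k = int(p.stem.rsplit("_z", 1)[1])
        boxes.extend(from_yolo(p.read_text(encoding="utf-8"), image_dims, k))
        seen = max(seen, k + 1)
    return AnnotationSet(
        subject_id=subject_id,
        boxes=boxes,
        image_dims=image_dims,
        n_slices=n_slices if n_slices is not None else (seen or None),
    )


# ---------------------------------------------------------------------------
# Grid changes


def rescale_boxes(
    boxes: Iterable[Box],
    from_spacing: tuple[float, float],
    to_spacing: tuple[float, float],
) -> list[Box]:
    """Map boxes between two in-plane grids that share a field of view.

    Pixel centres of the two grids are aligned so that the physical position
    ``(i + 0.5) * spacing`` is preserved, matching the resampling convention
    used by the preprocessing stage.  Spacings are (row_mm, col_mm).
    """
    fr_r, fr_c = from_spacing
    to_r, to_c = to_spacing
    out = []
    for b in boxes:
        out.append(
            replace(
                b,
                cx=(b.cx + 0.5) * fr_c / to_c - 0.5,
                cy=(b.cy + 0.5) * fr_r / to_r - 0.5,
                w=b.w * fr_c / to_c,
                h=b.h * fr_r / to_r,
            )
        )
    return out
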