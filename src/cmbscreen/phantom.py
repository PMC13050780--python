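"""Synthetic GRE phantom: brain-like volumes with known microbleed truth.

The generator emulates the *appearance* a 2D multi-slice T2*-weighted GRE
acquisition presents to a detection pipeline, not the MR physics behind it:

* a bright elliptical "head" of tissue on dark background, with a smooth
  quadratic shading field standing in for coil/tissue intensity variation;
* microbleeds as round hypointense wells.  A well is multiplicative —
  ``I -> I * (1 - depth(r))`` — with a flat-bottomed radial profile
  ``depth(r) = contrast * (1 - (r/R)^8)`` whose full width at half depth is
  the lesion diameter, then blurred by a blooming kernel so the visible
  hypointensity spreads slightly beyond the physical lesion;
* optional vessel mimics: thin curved dark lines whose connected
  hypointense footprint is far more elongated than any microbleed;
* Rician-like noise (magnitude of the complex signal plus Gaussian noise in
  both channels), the noise floor characteristic of magnitude MRI.

Ground-truth boxes are the tight bounds of each lesion's half-depth contour
computed from the rendered (blurred, noise-free) profile, mirroring how
raters outline the visible hypointensity including blooming.  Lesion
diameters are drawn from a truncated normal (mean 4.7 mm, clipped to the
2–10 mm clinical band).  Everything is reproducible from a single seed;
independent random streams drive sizes, placement, mimics and noise so
that, e.g., adding mimics does not perturb the noise realization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import CapacityError, ValidationError
from .imaging_io import AnnotationSet, Box, Volume
from .mig import MultiChannelSlice

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "LesionRecord",
    "MimicRecord",
    "generate_subject",
    "insert_vessel_mimic",
    "generate_cohort",
    "make_oracle_backend",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic subject."""

    n_slices: int = 10
    dims: tuple[int, int] = (512, 512)
    spacing: tuple[float, float, float] = (0.429, 0.429, 6.5)
    n_lesions: int = 8
    diameter_mean_mm: float = 4.7
    diameter_sd_mm: float = 1.2
    diameter_range_mm: tuple[float, float] = (2.0, 10.0)
    lesion_contrast: float = 0.6
    blooming_sigma_mm: float = 0.3
    n_mimics: int = 0
    mimic_kind: str = "vessel"
    noise_sigma: float = 0.02
    burden_class_target: str | None = None
    seed: int = 0
    # appearance of the background "head"
    tissue_intensity: float = 600.0
    shading_amplitude: float = 0.15
    placement_radius: float = 0.70
    mimic_length_mm: float = 20.0
    mimic_width_mm: float = 1.0

    def __post_init__(self):
        if self.n_slices < 1 or min(self.dims) < 32:
            raise ValidationError("need n_slices >= 1 and dims >= 32 px")
        lo, hi = self.diameter_range_mm
        if not (2.0 <= lo < hi <= 10.0):
            raise ValidationError(
                f"diameter_range_mm must lie within [2, 10], got {self.diameter_range_mm}"
            )
        if not 0 < self.lesion_contrast <= 1:
            raise ValidationError("lesion_contrast must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.burden_class_target not in (None, "low", "elevated"):
            raise ValidationError("burden_class_target must be None, 'low' or 'elevated'")


@dataclass(frozen=True)
class LesionRecord:
    """Truth for one inserted microbleed."""

    center_row: float
    center_col: float
    slice_index: int
    diameter_mm: float
    region: str


@dataclass(frozen=True)
class MimicRecord:
    """Truth for one inserted mimic (never annotated as a lesion)."""

    kind: str
    slice_index: int
    area_px: int
    equivalent_diameter_mm: float
    elongation: float


@dataclass
class PhantomSubject:
    volume: Volume
    brain_mask: Volume
    annotations: AnnotationSet
    region_masks: Volume
    truth_table: list[LesionRecord]
    mimics: list[MimicRecord]

    @property
    def n_lesions(self) -> int:
        return len(self.truth_table)

    def lobar_count(self) -> int:
        return sum(1 for r in self.truth_table if r.region == "lobar")


# ---------------------------------------------------------------------------
# Geometry helpers

_HALF_DEPTH_U = 0.5 ** (1.0 / 8.0)  # radius fraction where (1 - u^8) = 1/2


def _elliptical_radius(dims: tuple[int, int]) -> np.ndarray:
    """Normalized elliptical radius of every pixel (1.0 on the head contour)."""
    nr, nc = dims
    a_r, a_c = 0.42 * nr, 0.34 * nc
    rr, cc = np.mgrid[0:nr, 0:nc]
    return np.sqrt(((rr - (nr - 1) / 2) / a_r) ** 2 + ((cc - (nc - 1) / 2) / a_c) ** 2)


def _lesion_patch(
    d_mm: float, contrast: float, px_mm: float, blooming_sigma_mm: float
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Rendered (blurred) depth profile of one lesion plus its half-depth bbox.

    Returns ``(depth patch, (r0, r1, c0, c1))`` with the bbox of the
    half-depth support in patch pixel coordinates (inclusive-exclusive).
    """
    r_support = 0.5 * d_mm / _HALF_DEPTH_U / px_mm  # support radius, px
    sigma_px = blooming_sigma_mm / px_mm
    half = int(math.ceil(r_support + 4 * sigma_px + 2))
    ax = np.arange(-half, half + 1, dtype=float)
    rr = np.sqrt(np.add.outer(ax**2, ax**2))
    u = rr / r_support
    depth = contrast * np.clip(1.0 - u**8, 0.0, None)
    if sigma_px > 0:
        depth = ndi.gaussian_filter(depth, sigma=sigma_px)
    support = depth >= 0.5 * depth.max()
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    bbox = (rows[0], rows[-1] + 1, cols[0], cols[-1] + 1)
    return depth, bbox


def _sample_diameter(rng: np.random.Generator, spec: PhantomSpec) -> float:
    lo, hi = spec.diameter_range_mm
    for _ in range(10_000):
        d = rng.normal(spec.diameter_mean_mm, spec.diameter_sd_mm)
        if lo <= d <= hi:
            return float(d)
    raise CapacityError("could not sample a diameter inside the allowed range")


# ---------------------------------------------------------------------------
# Mimics


def insert_vessel_mimic(
    slice_2d: np.ndarray,
    mask_2d: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    rng: np.random.Generator,
    length_mm: float = 20.0,
    width_mm: float = 1.0,
    contrast: float = 0.5,
    blooming_sigma_mm: float = 0.3,
    max_tries: int = 50,
) -> tuple[np.ndarray, MimicRecord]:
    """Draw one curved dark vessel-like line into a slice (in place).

    The footprint is sub-microbleed in width (< 2 mm) but supra-microbleed
    in length (> 10 mm), so a correct size filter judges it by its blurred
    equivalent diameter — which may fall inside the microbleed band, making
    vessels genuine false-positive bait.  The modified slice and a truth
    record (kind, area, equivalent diameter, elongation) are returned.
    """
    if not width_mm < 2.0:
        raise ValidationError(f"vessel width must be < 2 mm, got {width_mm}")
    if not length_mm > 10.0:
        raise ValidationError(f"vessel length must be > 10 mm, got {length_mm}")
    px_mm = float(np.mean(pixel_spacing_mm))
    nr, nc = slice_2d.shape
    half_len = 0.5 * length_mm / px_mm
    interior = np.asarray(mask_2d) > 0
    eroded = ndi.binary_erosion(interior, iterations=3)
    cand = np.argwhere(eroded)
    if cand.size == 0:
        raise CapacityError("mask too small to host a vessel mimic")
    for _ in range(max_tries):
        r0, c0 = cand[rng.integers(len(cand))]
        theta = rng.uniform(0, 2 * np.pi)
        dvec = np.array([np.sin(theta), np.cos(theta)])
        p_start = np.array([r0, c0]) - half_len * dvec
        p_end = np.array([r0, c0]) + half_len * dvec
        bow = rng.uniform(0.15, 0.4) * half_len
        perp = np.array([-dvec[1], dvec[0]])
        p_ctrl = np.array([r0, c0], float) + bow * perp
        ends_ok = all(
            0 <= p[0] < nr and 0 <= p[1] < nc and interior[int(p[0]), int(p[1])]
            for p in (p_start, p_end)
        )
        if not ends_ok:
            continue
        ts = np.linspace(0, 1, int(6 * half_len) + 8)[:, None]
        pts = (1 - ts) ** 2 * p_start + 2 * ts * (1 - ts) * p_ctrl + ts**2 * p_end
        canvas = np.zeros(slice_2d.shape, dtype=bool)
        r_stamp = max(0.55, 0.5 * width_mm / px_mm)
        ri = int(math.ceil(r_stamp))
        off_r, off_c = np.mgrid[-ri : ri + 1, -ri : ri + 1]
        disc = off_r**2 + off_c**2 <= r_stamp**2
        for pr, pc in pts:
            r, c = int(round(pr)), int(round(pc))
            rs, cs = slice(r - ri, r + ri + 1), slice(c - ri, c + ri + 1)
            if 0 <= r - ri and r + ri < nr and 0 <= c - ri and c + ri < nc:
                canvas[rs, cs] |= disc
        canvas &= interior
        if canvas.sum() < 4:
            continue
        depth = canvas.astype(float)
        sigma_px = blooming_sigma_mm / px_mm
        if sigma_px > 0:
            depth = ndi.gaussian_filter(depth, sigma=sigma_px)
            m = depth.max()
            if m > 0:
                depth /= m
        slice_2d *= 1.0 - contrast * depth
        area = int(canvas.sum())
        d_eq = 2.0 * math.sqrt(area * pixel_spacing_mm[0] * pixel_spacing_mm[1] / math.pi)
        return slice_2d, MimicRecord(
            kind="vessel",
            slice_index=-1,  # caller fills in
            area_px=area,
            equivalent_diameter_mm=d_eq,
            elongation=length_mm / width_mm,
        )
    raise CapacityError("could not place a vessel mimic inside the mask")


# ---------------------------------------------------------------------------
# Subject generation


def generate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Render one synthetic subject, fully reproducible from ``spec.seed``.

    Lesions are placed uniformly inside the head with a margin from the
    shading-dominated rim and at least one summed-diameter pairwise
    separation on each slice.  Raises :class:`CapacityError` (reporting the
    achieved count) when placement is infeasible.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_diam, rng_place, rng_mimic, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    nr, nc = spec.dims
    row_mm, col_mm = spec.spacing[0], spec.spacing[1]
    px_mm = float(np.mean((row_mm, col_mm)))

    re = _elliptical_radius(spec.dims)
    mask2d = re <= 1.0
    background = np.where(
        mask2d, spec.tissue_intensity * (1.0 - spec.shading_amplitude * re**2), 0.0
    )
    data = np.repeat(background[:, :, None], spec.n_slices, axis=2)
    mask3d = np.repeat(mask2d[:, :, None], spec.n_slices, axis=2)

    # regions: outer shell lobar (1), central blob deep (2), bottom slices
    # infratentorial (3) — geometric sectors, not an atlas
    regions2d = np.zeros(spec.dims, dtype=np.int16)
    regions2d[mask2d & (re > 0.55)] = 1
    regions2d[mask2d & (re <= 0.55)] = 2
    regions = np.repeat(regions2d[:, :, None], spec.n_slices, axis=2)
    n_infra = min(2, spec.n_slices)
    for k in range(n_infra):
        regions[:, :, k][mask2d] = 3
    region_names = {1: "lobar", 2: "deep", 3: "infratentorial"}

    placeable = np.argwhere(mask2d & (re <= spec.placement_radius))
    if placeable.size == 0:
        raise CapacityError("head too small for lesion placement", achieved=0)

    boxes: list[Box] = []
    truth: list[LesionRecord] = []
    placed: list[tuple[int, float, float, float]] = []  # (slice, row, col, d_mm)
    for _ in range(spec.n_lesions):
        d_mm = _sample_diameter(rng_diam, spec)
        ok = False
        for _try in range(500):
            k = int(rng_place.integers(spec.n_slices))
            r, c = placeable[rng_place.integers(len(placeable))]
            sep_ok = all(
                math.hypot((r - pr) * row_mm, (c - pc) * col_mm) >= (d_mm + pd)
                for (pk, pr, pc, pd) in placed
                if pk == k
            )
            if sep_ok:
                ok = True
                break
        if not ok:
            raise CapacityError(
                f"placed only {len(placed)} of {spec.n_lesions} lesions",
                achieved=len(placed),
            )
        depth, (br0, br1, bc0, bc1) = _lesion_patch(
            d_mm, spec.lesion_contrast, px_mm, spec.blooming_sigma_mm
        )
        half = depth.shape[0] // 2
        rs = slice(r - half, r + half + 1)
        cs = slice(c - half, c + half + 1)
        if rs.start < 0 or cs.start < 0 or rs.stop > nr or cs.stop > nc:
            continue  # patch clipped by the frame; placement band makes this rare
        data[rs, cs, k] *= 1.0 - depth
        placed.append((k, float(r), float(c), d_mm))
        boxes.append(
            Box(
                slice_index=k,
                cx=c - half + (bc0 + bc1 - 1) / 2.0,
                cy=r - half + (br0 + br1 - 1) / 2.0,
                w=float(bc1 - bc0),
                h=float(br1 - br0),
                confidence=1.0,
            )
        )
        truth.append(
            LesionRecord(
                center_row=float(r),
                center_col=float(c),
                slice_index=k,
                diameter_mm=d_mm,
                region=region_names.get(int(regions[r, c, k]), "excluded"),
            )
        )

    mimics: list[MimicRecord] = []
    for _ in range(spec.n_mimics):
        k = int(rng_mimic.integers(spec.n_slices))
        _, rec = insert_vessel_mimic(
            data[:, :, k],
            mask2d,
            (row_mm, col_mm),
            rng_mimic,
            length_mm=spec.mimic_length_mm,
            width_mm=spec.mimic_width_mm,
            contrast=spec.lesion_contrast * 0.8,
            blooming_sigma_mm=spec.blooming_sigma_mm,
        )
        mimics.append(replace(rec, slice_index=k))

    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * spec.tissue_intensity
        n1 = rng_noise.normal(0.0, sigma, size=data.shape)
        n2 = rng_noise.normal(0.0, sigma, size=data.shape)
        data = np.sqrt((data + n1) ** 2 + n2**2)  # Rician-like magnitude noise

    subject_id = f"phantom-{spec.seed:010d}"
    volume = Volume(data=data, spacing=spec.spacing, slice_axis=2, id=subject_id)
    return PhantomSubject(
        volume=volume,
        brain_mask=Volume(mask3d.astype(np.uint8), spec.spacing, 2, subject_id),
        annotations=AnnotationSet(
            subject_id=subject_id,
            boxes=boxes,
            image_dims=spec.dims,
            n_slices=spec.n_slices,
        ),
        region_masks=Volume(regions, spec.spacing, 2, subject_id),
        truth_table=truth,
        mimics=mimics,
    )


# ---------------------------------------------------------------------------
# Cohorts


def _sample_count(rng: np.random.Generator, target: str | None) -> int:
    if target == "low":
        return int(rng.integers(1, 4))
    if target == "elevated":
        return int(rng.integers(4, 16))
    # mixture covering both burden classes: geometric over 1..30
    return int(min(rng.geometric(0.25), 30))


def generate_cohort(
    n_subjects: int,
    template: PhantomSpec,
    seed: int | None = None,
) -> list[PhantomSubject]:
    """Generate a reproducible cohort from a template spec.

    Per-subject lesion counts follow the template's ``burden_class_target``
    (or a geometric mixture over 1..30 when unset); per-subject seeds are
    derived deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    master = template.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(n_subjects)
    subjects = []
    for child in children:
        state = child.generate_state(2)
        rng_count = np.random.default_rng(int(state[0]))
        n = _sample_count(rng_count, template.burden_class_target)
        sub_seed = int(state[1]) & 0x7FFFFFFF
        subjects.append(generate_subject(replace(template, seed=sub_seed, n_lesions=n)))
    return subjects


# ---------------------------------------------------------------------------
# Near-perfect detector backend (for patient-level experiments)


def make_oracle_backend(
    annotations: AnnotationSet,
    jitter_px: float = 0.0,
    confidence: float = 0.95,
    seed: int = 0,
) -> Callable[[MultiChannelSlice, int], list[Box]]:
    """Detector backend that returns the ground-truth boxes of a subject.

    With ``jitter_px > 0`` the box centres are perturbed by uniform noise —
    a stand-in for a near-perfect learned detector, used to exercise the
    patient-level evaluation protocol independently of detection quality.
    """
    rng = np.random.default_rng(seed)

    def backend(mc: MultiChannelSlice, slice_index: int) -> list[Box]:
        out = []
        for b in annotations.boxes_on_slice(slice_index):
            dx, dy = (rng.uniform(-jitter_px, jitter_px, size=2) if jitter_px else (0, 0))
            out.append(
                Box(
                    slice_index=slice_index,
                    cx=b.cx + dx,
                    cy=b.cy + dy,
                    w=b.w,
                    h=b.h,
                    confidence=confidence,
                )
            )
        return out

    return backend
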