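"""Multi-channel image generation (MIG) for microbleed enhancement.

One preprocessed GRE slice is expanded into a three-channel composite, each
channel emphasizing a different microbleed-relevant feature:

* **Channel 1 — selective enhancement.**  Slice-wise Z-score normalization
  within the brain mask, thresholding at Z < -1.0 (microbleeds are focal
  hypointensities), morphological size filtering keeping 8-connected
  components whose equivalent diameter ``2 * sqrt(area / pi)`` lies in the
  typical microbleed band (1–10 mm), then an interior Euclidean distance
  transform rescaled to [0, 1] so lesion centres are maximal.
* **Channel 2 — SWI-like contrast.**  Square-root intensity transform,
  selective attenuation of pixels below the in-mask 30th percentile of the
  transformed intensities, and light Gaussian smoothing — mimicking the
  dark-lesion/bright-tissue appearance of susceptibility-weighted imaging.
* **Channel 3 — CLAHE.**  Contrast-limited adaptive histogram equalization
  of the 8-bit quantized slice, preserving fine anatomical detail.

All channels are float images in [0, 1]; the stacking order is fixed
(ch1, ch2, ch3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_adapthist

from .errors import DegenerateSliceError, ValidationError
from .imaging_io import Volume

__all__ = [
    "MigConfig",
    "MultiChannelSlice",
    "zscore_slice",
    "candidate_mask",
    "channel1",
    "channel2",
    "channel3",
    "make_multichannel",
    "make_multichannel_volume",
]

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MigConfig:
    """Channel parameters.

    ``z_thresh`` (negative) is the hypointensity cut in Z units;
    ``d_min_mm``/``d_max_mm`` bound the equivalent diameter of retained
    candidates; ``p_attenuate`` and ``attenuation_factor`` control the
    channel-2 dark-pixel suppression; ``gauss_sigma_px`` is the channel-2
    smoothing width in pixels; ``clahe_clip``/``clahe_tiles`` parameterize
    channel 3 (clip limit in the conventional 256-bin histogram units, tiles
    per image side).
    """

    z_thresh: float = -1.0
    d_min_mm: float = 1.0
    d_max_mm: float = 10.0
    p_attenuate: float = 30.0
    attenuation_factor: float = 0.5
    gauss_sigma_px: float = 0.5
    clahe_clip: float = 2.0
    clahe_tiles: int = 8

    def __post_init__(self):
        if self.z_thresh >= 0:
            raise ValidationError(f"z_thresh must be negative, got {self.z_thresh}")
        if not 0 < self.d_min_mm < self.d_max_mm:
            raise ValidationError(
                f"need 0 < d_min_mm < d_max_mm, got ({self.d_min_mm}, {self.d_max_mm})"
            )
        if not 0 < self.p_attenuate < 100:
            raise ValidationError(f"p_attenuate must be in (0,100), got {self.p_attenuate}")
        if not 0 <= self.attenuation_factor <= 1:
            raise ValidationError("attenuation_factor must lie in [0,1]")
        if self.gauss_sigma_px <= 0:
            raise ValidationError("gauss_sigma_px must be positive")
        if self.clahe_tiles < 1:
            raise ValidationError("clahe_tiles must be >= 1")


@dataclass(frozen=True)
class MultiChannelSlice:
    """The three enhanced channels of one slice, all in [0, 1]."""

    ch1: np.ndarray
    ch2: np.ndarray
    ch3: np.ndarray
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self):
        if not (self.ch1.shape == self.ch2.shape == self.ch3.shape):
            raise ValidationError("the three channels must share dimensions")
        for name in ("ch1", "ch2", "ch3"):
            c = getattr(self, name)
            if c.size and (c.min() < -1e-9 or c.max() > 1 + 1e-9):
                raise ValidationError(f"{name} values outside [0,1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ch1.shape

    def stacked(self) -> np.ndarray:
        """(rows, cols, 3) array in the fixed channel order."""
        return np.stack([self.ch1, self.ch2, self.ch3], axis=-1)


def zscore_slice(slice_2d: np.ndarray, mask_2d: np.ndarray) -> np.ndarray:
    """Standardize one slice to in-mask mean 0 and population SD 1.

    Out-of-mask pixels are 0.  A slice with fewer than two in-mask pixels or
    zero in-mask variance cannot be standardized and raises
    :class:`DegenerateSliceError`.
    """
    m = np.asarray(mask_2d) > 0
    x = np.asarray(slice_2d, dtype=float)
    if m.sum() < 2:
        raise DegenerateSliceError("need at least 2 in-mask pixels to z-score")
    vals = x[m]
    sd = vals.std()  # population SD
    if sd == 0:
        raise DegenerateSliceError("zero in-mask variance: slice is constant")
    out = np.zeros_like(x)
    out[m] = (vals - vals.mean()) / sd
    return out


def candidate_mask(
    z: np.ndarray, cfg: MigConfig, pixel_spacing_mm: tuple[float, float]
) -> np.ndarray:
    """Hypointensity candidates: threshold then size-band filtering.

    Pixels with ``z < z_thresh`` are candidate material; 8-connected
    components are kept only when their equivalent diameter
    ``2 * sqrt(area_mm2 / pi)`` lies in ``[d_min_mm, d_max_mm]`` (inclusive).
    An empty result is valid.
    """
    row_mm, col_mm = pixel_spacing_mm
    binary = np.asarray(z) < cfg.z_thresh
    labeled, n = ndi.label(binary, structure=_CONN8)
    if n == 0:
        return np.zeros_like(binary)
    px_area = row_mm * col_mm
    areas = ndi.sum_labels(binary, labeled, index=np.arange(1, n + 1)) * px_area
    d_eq = 2.0 * np.sqrt(areas / np.pi)
    keep = (d_eq >= cfg.d_min_mm) & (d_eq <= cfg.d_max_mm)
    keep_labels = np.flatnonzero(keep) + 1
    return np.isin(labeled, keep_labels)


def channel1(
    slice_2d: np.ndarray,
    mask_2d: np.ndarray,
    cfg: MigConfig,
    pixel_spacing_mm: tuple[float, float],
) -> np.ndarray:
    """Distance-transform encoding of the size-filtered hypointensity candidates.

    Inside each candidate the value is the Euclidean distance (in pixels) to
    the nearest background pixel, rescaled to [0, 1] by the slice-wide
    maximum; zero outside candidates, and all-zero when no candidate
    survives the size band.
    """
    cm = candidate_mask(zscore_slice(slice_2d, mask_2d), cfg, pixel_spacing_mm)
    if not cm.any():
        return np.zeros(cm.shape, dtype=float)
    edt = ndi.distance_transform_edt(cm)
    return edt / edt.max()


def channel2(slice_2d: np.ndarray, mask_2d: np.ndarray, cfg: MigConfig) -> np.ndarray:
    """SWI-like contrast: sqrt transform, dark-tail attenuation, smoothing.

    ``y = sqrt(x)``; in-mask pixels strictly below the in-mask
    ``p_attenuate``-th percentile of ``y`` are multiplied by
    ``attenuation_factor`` (the percentile is taken after the square root;
    by monotonicity the attenuated pixel set is the same either way), then a
    Gaussian blur of ``gauss_sigma_px`` is applied and the result clipped to
    [0, 1] with zeros outside the mask.
    """
    m = np.asarray(mask_2d) > 0
    if not m.any():
        raise ValidationError("empty mask: channel 2 undefined")
    x = np.clip(np.asarray(slice_2d, dtype=float), 0.0, 1.0)
    y = np.sqrt(x)
    p30 = np.percentile(y[m], cfg.p_attenuate)
    att = y.copy()
    att[m & (y < p30)] *= cfg.attenuation_factor
    att[~m] = 0.0
    out = ndi.gaussian_filter(att, sigma=cfg.gauss_sigma_px)
    out = np.clip(out, 0.0, 1.0)
    out[~m] = 0.0
    return out


def channel3(slice_2d: np.ndarray, cfg: MigConfig) -> np.ndarray:
    """CLAHE on the 8-bit quantization of the slice, rescaled to [0, 1].

    The clip limit follows the conventional definition (multiples of the
    uniform bin height on a 256-bin tile histogram) and is converted to the
    normalized clip used by scikit-image.
    """
    x = np.clip(np.asarray(slice_2d, dtype=float), 0.0, 1.0)
    q = np.round(x * 255.0).astype(np.uint8)
    nr, nc = q.shape
    kernel = (max(1, nr // cfg.clahe_tiles), max(1, nc // cfg.clahe_tiles))
    out = equalize_adapthist(
        q, kernel_size=kernel, clip_limit=cfg.clahe_clip / 256.0, nbins=256
    )
    return np.clip(out, 0.0, 1.0)


def make_multichannel(
    slice_2d: np.ndarray,
    mask_2d: np.ndarray,
    cfg: MigConfig,
    pixel_spacing_mm: tuple[float, float],
) -> MultiChannelSlice:
    """Build the full three-channel composite for one slice (deterministic)."""
    return MultiChannelSlice(
        ch1=channel1(slice_2d, mask_2d, cfg, pixel_spacing_mm),
        ch2=channel2(slice_2d, mask_2d, cfg),
        ch3=channel3(slice_2d, cfg),
        pixel_spacing_mm=tuple(pixel_spacing_mm),
    )


def make_multichannel_volume(
    vol: Volume, mask: Volume, cfg: MigConfig | None = None
) -> np.ndarray:
    """Apply MIG to every slice; returns ``(slices, rows, cols, 3)``.

    Slices that cannot be standardized (no in-mask signal or constant
    intensity) yield three zero channels rather than aborting the volume.
    """
    cfg = cfg or MigConfig()
    spacing = vol.in_plane_spacing
    out = []
    for k, sl in vol.iter_slices():
        msl = mask.get_slice(k)
        try:
            mc = make_multichannel(sl, msl, cfg, spacing)
            out.append(mc.stacked())
        except (DegenerateSliceError, ValidationError):
            out.append(np.zeros(sl.shape + (3,)))
    return np.stack(out, axis=0)
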