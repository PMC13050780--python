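# Methods

This note documents the models, conventions and numerical choices behind
`cmbscreen`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic experiments do and do not show.

## Coordinate and box conventions

All boxes are per-slice, axis-aligned, 0-based and pixel-centred: pixel `i`
spans the continuous interval `[i − 0.5, i + 0.5]`, and a `w × h` box
centred at `(cx, cy)` spans `[cx − w/2, cx + w/2]` along columns and
`[cy − h/2, cy + h/2]` along rows. `cx`/`w` run along image columns (x),
`cy`/`h` along rows (y). This makes IoU arithmetic unambiguous: a box built
from a pixel run `cols 20–24` has `cx = 22`, `w = 5`.

Connected components are always 2D and 8-connected, never merged across
slices: with 6.5 mm slice gaps on a 2D multi-slice acquisition,
through-plane merging would join unrelated structures.

The YOLO text dialect is one file per slice, `"<subject>_z<index>.txt"`,
class id 0 = CMB, records `cls cx/ncols cy/nrows w/ncols h/nrows` with
6-decimal fixed point (round-trip error < 0.5 px at any matrix size); an
optional 6th field carries the detection confidence.

NIfTI headers do not name the axial axis, so the slice axis is inferred as
the axis with the largest voxel spacing — correct for thick-slice 2D GRE —
and can be overridden by constructing `Volume` explicitly.

## Preprocessing

Order is fixed: brain masking → percentile normalization → slice-wise
super-resolution → resampling.

* **Masking.** Brain extraction proper is out of scope; the pipeline takes
  a binary brain mask as input. The fallback (volume-wise Otsu threshold,
  largest 3D connected component, per-slice hole filling) is a crude
  surrogate adequate for phantoms and roughly skull-stripped data, and is
  labelled as such.
* **Normalization** maps the in-mask 1st–99th percentile range to `[0, 1]`
  with clipping. Percentiles are computed *within the brain mask* — with
  background air included, the low percentile would sit in air and the
  brain would be compressed into the top of the range. Scope is per-volume
  by default (`normalize_scope: slice` is available); per-volume keeps
  slice-to-slice intensity relationships intact.
* **Super-resolution** is a registry of pure `(2D image, factor) → 2D
  image` backends, applied slice-wise (the through-plane direction is far
  too coarse to interpolate meaningfully). The default backend is bicubic
  spline interpolation with odd-reflection padding, which reproduces affine
  images exactly (verified to 1e-6); a learned model can be registered
  under its own name. Cubic overshoot at sharp edges is clipped back to
  `[0, 1]` inside the chain.
* **Resampling** is trilinear onto the reference grid (default
  0.429 × 0.429 × 6.5 mm), with pixel-centre alignment
  `(i_out + 0.5)·s_out = (i_in + 0.5)·s_in`, preserving the field of view
  to within one voxel per axis; identical spacing is an exact identity.
  Note the default chain is resolution-neutral for data already on the
  reference grid: SR halves the pixel pitch and resampling restores it.
  Detections made on the processed grid are mapped back to the annotation
  grid through the same pixel-centre correspondence.

## Multi-channel enhancement

* **Channel 1 (CMB-selective).** Z-scoring is per slice within the brain
  mask (population SD), matching the slice-wise detector input; a slice
  with no in-mask variance cannot be standardized and contributes zero
  channels rather than aborting a volume. Thresholding at Z < −1.0 marks
  hypointensities; components are kept when their equivalent diameter
  2√(area/π) — rotation-invariant, appropriate for round/ovoid lesions —
  lies in [1, 10] mm inclusive. The retained mask is encoded as the
  interior Euclidean distance transform divided by the slice-wide maximum,
  so candidate centres are maximal and the deepest candidate on each slice
  scores 1.0.
* **Channel 2 (SWI-like).** `y = √x`, then in-mask pixels *strictly below*
  the in-mask 30th percentile of `y` are multiplied by the attenuation
  factor (default 0.5 — the attenuation strength is a free parameter,
  exposed in config), then Gaussian smoothing with σ = 0.5 interpreted in
  pixels. Whether the percentile is taken before or after the square root
  selects the same pixel set (√ is monotone); it is computed on `y`.
  On a constant slice nothing is strictly below the percentile, so the
  output is √c.
* **Channel 3 (CLAHE)** runs on the 8-bit quantization with an 8 × 8 tile
  grid and clip limit 2.0 in conventional 256-bin units (converted to the
  normalized clip used by scikit-image as `clip/256`).

Channels are stacked in this fixed order as float images in `[0, 1]`.

## Candidate detection and post-processing

The built-in classical backend boxes each 8-connected component of the
channel-1 support with its tight bounds and scores it by the component's
peak channel-1 value (`depth`; `zmean` — min-max-rescaled mean |Z| — is the
alternative). Confidence filtering is inclusive (≥ 0.2) and NMS is greedy
per slice at IoU 0.5, with equal-confidence ties broken by
(slice, cy, cx) so results are deterministic.

`box_scale` dilates the tight candidate bounds about their centre and
defaults to **1.0**. A dilation of 2.0 is meaningful as a box-regression
hyperparameter when training a neural detector, but for a
connected-component detector whose tight bounds already cover the visible
lesion, any dilation `s` caps the achievable IoU against a tight
ground-truth box near `1/s²` — at `s = 2` no detection could ever clear the
IoU-0.5 true-positive criterion, so the tight default is the only coherent
choice for the classical backend. The factor remains configurable for
backends whose raw boxes are systematically tight.

External backends receive the per-slice 3-channel image and return raw
scored boxes; all geometry and post-processing stay in this module, so the
evaluation is backend-agnostic.

## Evaluation protocol

* **Matching** is greedy in descending confidence; each prediction claims
  the unmatched ground-truth box with the highest IoU strictly greater
  than 0.5 ("exceeding" read strictly; the threshold is configurable).
  Greedy matching never exceeds the maximum-cardinality matching and is
  oracle-checked against exhaustive assignment on separated-lesion
  instances, where the two coincide.
* **Metrics.** Ratios with empty denominators are reported as *absent*
  (`None`/empty cells), never as 0 — a bin with no lesions has no
  sensitivity.
* **Diameter estimate** of a box is the mean of its two side lengths in mm
  (axis-wise spacing honoured); max side and geometric mean are reasonable
  alternatives and the estimator is kept in one function. Default size-bin
  edges are 0/2.5/3/4/5/6/∞ mm, half-open `[lo, hi)`.
* **Regional assignment** looks up the integer region label at the box
  centre (rounded); label 0 or labels outside the mapping are "excluded"
  and dropped from the regional table (the exclusion count is kept in the
  table metadata). Ground-truth lesions are assigned by the ground-truth
  box centre, false positives by the predicted box centre.
* **Patient level.** Subjects are dichotomized at ≥ 4 lesions
  (low 1–3 vs elevated); the 2×2 ratios use the same absent-on-0/0
  convention. ARIA-H severity bins a lobar count as none/mild (1–5)/
  moderate (6–10)/severe (≥ 11).

## Phantom

The generator reproduces what a detection pipeline *sees* on 2D GRE, not
MR physics (no TE/TR/susceptibility modelling, no anatomy):

* **Background**: a cylindrical head ellipse (semi-axes 0.42/0.34 of the
  matrix) of tissue intensity 600 a.u. with a quadratic radial shading
  field (15 % centre-to-rim), standing in for coil shading and bulk tissue
  variation. There is no GM/WM/CSF structure — one reason phantom results
  overestimate real-world precision.
* **Lesions**: multiplicative radial wells `I → I·(1 − depth(r))` with the
  flat-bottomed profile `depth(r) = contrast·(1 − (r/R)^8)`, whose full
  width at half depth defines the lesion diameter, blurred by a blooming
  kernel (default σ = 0.3 mm). The steep profile makes the visible
  hypointensity close to the nominal diameter, as for real susceptibility
  cores. Ground-truth boxes are the tight bounds of the rendered
  (blurred, noise-free) half-depth contour — mirroring raters outlining
  the visible hypointensity including blooming — so annotations are
  blur-robust by construction. Diameters are truncated-normal
  (mean 4.7 mm, SD 1.2 mm, clipped to 2–10 mm; the SD is a modelling
  choice, exposed in `PhantomSpec`). Placement is uniform inside 0.70 of the
  head radius with pairwise same-slice separation of one summed diameter.
* **Mimics**: curved vessel-like lines (default 20 mm × 1 mm) whose
  blurred hypointense footprint has an equivalent diameter that typically
  *falls inside* the 1–10 mm band — so a correct size filter keeps them
  and they become genuine false-positive bait, as vessels do on real GRE.
  Mimics are recorded in the truth tables but never annotated as lesions.
* **Noise** is Rician-like (magnitude of complex signal plus independent
  Gaussian noise in both channels, default σ = 2 % of tissue intensity).
  Sizes, placement, mimics and noise draw from independent child streams
  of one master seed, so adding mimics leaves the noise realization
  untouched and cohorts are bit-reproducible.
* **Regions** are geometric sectors (outer shell "lobar", central blob
  "deep", bottom two slices "infratentorial") — enough to exercise the
  regional protocol without an atlas, with no anatomical meaning.

### What the phantom experiments show — and do not

On seeded 20-subject cohorts (192 × 192 × 6 at the reference spacing,
contrast 0.6, noise 2 %), the classical channel-1 pipeline recovers
essentially all lesions at IoU > 0.5, and adding vessel mimics strictly
raises FPavg. These are *consistency* checks of the pipeline machinery —
the phantom's clean background makes detection far easier than real GRE,
and conversely the slice-max normalization of channel 1 makes the
classical detector fire on the largest noise cluster of every lesion-free
slice, so its phantom FPavg (tens per subject) is much worse than a
trained detector's. Neither number predicts clinical performance; the
patient-level experiment therefore uses a near-perfect ground-truth-backed
backend to exercise the burden-screening protocol itself.

Problem sizes throughout (192-px heads, 6 slices, 20–30 subjects) are the
package's desk-scale defaults chosen so the whole suite runs in well under
a minute per experiment on one CPU; the generator accepts full 512 × 512
geometries unchanged.

## Known limitations

* The Otsu fallback mask is not brain extraction; use a real mask when
  available.
* Channel-1's per-slice maximum normalization makes confidences relative
  within a slice, not comparable across slices.
* No cross-slice deduplication of detections (appropriate for 6.5 mm gaps,
  but thin-slice 3D data would need it).
* Greedy matching can in principle undercount TP versus optimal matching
  on adversarially overlapping predictions; the property suite bounds it
  from above by the brute-force optimum.
* The phantom's per-subject lesion-count mixture (geometric over 1..30) is
  a stand-in, not an estimate of any clinical cohort distribution.
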