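# Quickstart configuration: a small synthetic cohort through the full
# pipeline.  All protocol constants live here; see docs/methods.md.
seed: 7

phantom:
  n_subjects: 3
  dims: [192, 192]
  n_slices: 5
  n_lesions: 5
  noise_sigma: 0.02
  lesion_contrast: 0.6
  n_mimics: 2

preprocess:
  p_low: 1.0
  p_high: 99.0
  sr_factor: 2
  sr_backend: bicubic
  target_spacing: [0.429, 0.429, 6.5]

mig:
  z_thresh: -1.0
  d_min_mm: 1.0
  d_max_mm: 10.0
  p_attenuate: 30.0
  attenuation_factor: 0.5
  gauss_sigma_px: 0.5
  clahe_clip: 2.0
  clahe_tiles: 8

detector:
  backend: channel1
  conf_thresh: 0.2
  nms_iou: 0.5
  box_scale: 1.0
  score_mode: depth

evaluation:
  iou_thresh: 0.5
  elevated_min: 4
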