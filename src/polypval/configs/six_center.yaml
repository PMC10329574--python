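# Default six-center synthetic study: frame counts and polyp prevalences of a
# published six-center single-frame colonoscopy test collection, at 1920x1080.
# Identical to polypval.synth.default_study_spec().
seed: 0
centers:
  - {center_id: center_1, n_images: 256, prevalence: 0.98}
  - {center_id: center_2, n_images: 276, prevalence: 0.89}
  - {center_id: center_3, n_images: 457, prevalence: 0.99}
  - {center_id: center_4, n_images: 227, prevalence: 0.64}
  - {center_id: center_5, n_images: 208, prevalence: 0.99}
  - {center_id: center_6, n_images: 88, prevalence: 0.94}
perturbation:
  miss_midpoint_area: 400.0   # logistic midpoint in px^2 (20^2): only specks are missed outright
  miss_slope: 2.0
  jitter_mode: absolute       # "relative" is the negative control
  center_jitter_sd: 25.0      # px at 1920x1080
  relative_jitter_frac: 0.18  # * sqrt(area) in relative mode
  scale_noise_sd: 0.10
  fp_per_image: 0.1
  confidence_noise_sd: 0.1
  fp_confidence_beta: [2.0, 5.0]
rating:
  criterion_kind: mask_iou
  criterion_threshold: 0.0    # "any mask overlap" — the permissive position criterion
  label_noise: 0.0
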