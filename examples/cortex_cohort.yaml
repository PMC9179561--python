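# Synthetic cohort emulating a grey-matter (retrosplenial cortex) design:
# control plus 1/3/5 weeks of cuprizone, n = 5 animals per group.
groups:
  - {label: Ctrl, n_animals: 5, target_density: 92.31, density_sd: 13.46, target_mean_ri: 0.44, ri_sd: 0.04}
  - {label: 1w,   n_animals: 5, target_density: 87.27, density_sd: 17.79, target_mean_ri: 0.49, ri_sd: 0.04}
  - {label: 3w,   n_animals: 5, target_density: 99.13, density_sd: 14.54, target_mean_ri: 0.55, ri_sd: 0.04}
  - {label: 5w,   n_animals: 5, target_density: 207.32, density_sd: 39.2, target_mean_ri: 0.56, ri_sd: 0.03}
seed: 42
image_size_px: 700
pixel_size_um: 1.0
roi_margin_px: 40
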