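# Unrelated-condition transfer: different instrument resolution (feature grids
# differ, exercising the PCA harmonization path) and a larger shift.
name: nonhomologous-like
grid_points: 600
target_grid_points: 520
class_effect: 0.2
n_source: {0: 45, 1: 37}
n_target: {0: 68, 1: 72}
source_shift:
  baseline_coeffs: [0.5, 0.4, -0.3, 0.2]
  gain: 1.0
  noise_sd: 0.02
  peak_jitter_sd: 1.0
  seed: 1
target_shift:
  baseline_coeffs: [1.5, -1.0, 1.2, -0.5]
  gain: 0.8
  noise_sd: 0.03
  peak_jitter_sd: 1.5
  peak_shift: 6.0
  width_scale: 1.4
  seed: 2
seed: 0
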