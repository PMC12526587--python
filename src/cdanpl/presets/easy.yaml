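# Large class signal, small-but-real instrument shift: the adaptation task is
# learnable from the source domain and the domain gap is closable.
name: easy
grid_points: 600
target_grid_points: 520
class_effect: 0.35
n_source: {0: 34, 1: 72}
n_target: {0: 68, 1: 72}
source_shift:
  baseline_coeffs: [0.5, 0.4, -0.3, 0.2]
  gain: 1.0
  noise_sd: 0.01
  peak_jitter_sd: 2.0
  seed: 1
target_shift:
  baseline_coeffs: [1.2, -0.8, 1.0, -0.4]
  gain: 1.3
  noise_sd: 0.02
  peak_jitter_sd: 2.0
  peak_shift: 6.5
  width_scale: 1.1
  seed: 2
seed: 0
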