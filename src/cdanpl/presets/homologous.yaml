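# Related-condition transfer: same instrument class, moderate signal and shift.
name: homologous-like
grid_points: 600
class_effect: 0.2
n_source: {0: 34, 1: 72}
n_target: {0: 68, 1: 72}
source_shift:
  baseline_coeffs: [0.5, 0.4, -0.3, 0.2]
  gain: 1.0
  noise_sd: 0.02
  peak_jitter_sd: 0.8
  seed: 1
target_shift:
  baseline_coeffs: [0.9, -0.4, 0.6, -0.2]
  gain: 1.15
  noise_sd: 0.02
  peak_jitter_sd: 1.0
  peak_shift: 3.0
  width_scale: 1.15
  seed: 2
seed: 0
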