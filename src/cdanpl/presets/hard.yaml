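# Shift magnitude far above the class signal: a source-only model should
# degrade substantially on the target domain.
name: hard
grid_points: 600
class_effect: 0.06
n_source: {0: 34, 1: 72}
n_target: {0: 68, 1: 72}
source_shift:
  baseline_coeffs: [0.5, 0.4, -0.3, 0.2]
  gain: 1.0
  noise_sd: 0.02
  peak_jitter_sd: 1.0
  seed: 1
target_shift:
  baseline_coeffs: [2.0, -1.5, 2.0, -1.0]
  gain: 0.7
  noise_sd: 0.05
  peak_jitter_sd: 3.0
  peak_shift: 12.0
  width_scale: 1.8
  seed: 2
seed: 0
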