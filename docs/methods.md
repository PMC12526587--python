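# Methods

This note documents the model, the synthetic data it is validated on, and the
numerical choices the implementation makes.

## Problem setting

Serum Raman spectroscopy can discriminate disease from healthy-control samples,
but labeled spectra are scarce and spectra acquired on different instruments
(or for different diseases) follow different distributions.  The package
implements unsupervised domain adaptation (UDA) for this setting: a labeled
*source* dataset `D_s = {(x_s, y_s)}` and an unlabeled *target* dataset
`D_t = {x_t}` on a compatible feature grid, with the goal of an accurate
classifier on the target domain.  Target labels are never visible to training;
synthetic tasks carry *sealed* target labels used exclusively by evaluation.

## Model

Three networks play a conditional adversarial game:

* **Feature extractor G** — dual-branch 1-D encoder.  A token branch embeds
  non-overlapping spectral patches (default width 16) linearly, adds a learned
  positional table and applies a small pre-norm self-attention encoder
  (2 layers, 4 heads, width 64); the token mean is its output.  A multi-scale
  convolution branch applies parallel 1-D convolutions (kernels 3/7/15,
  16 channels each) and global-average-pools each channel; the per-position
  feature maps feed Grad-CAM.  The branch outputs are concatenated and fused
  by one fully connected layer, a ReLU and a LayerNorm into 64 features.
* **Classifier C** — one linear layer + softmax on G's features.
* **Discriminator D** — MLP (2 hidden layers of width 128, dropout 0.5,
  sigmoid) scoring the domain of multilinear vectors
  `phi(f, g) = f (x) g` — the flattened outer product of features and class
  probabilities, so domain alignment is conditioned on the class structure.

Losses (per batch):

* `L_cls` — cross-entropy of ground-truth source labels under `C(G(x_s))`.
* `L_adv = -E_s log(1 - D(phi_s)) - E_t log(D(phi_t))` — D descends on this
  (domain classification); G receives the gradient through a gradient
  reversal layer scaled by `-lambda`, driving domain confusion.  The reversal
  layer is always present in the path; `lambda = 0` blocks the adversarial
  gradient into G entirely rather than letting it leak unreversed.
* `L_MC` — metric-constraint loss.  With `T_m = (1/B) * sum_{u,v} ||f_u - f_v||^2`
  (ordered pairs; a pair-count-normalized variant is available behind
  `mc_pair_mean`), `L_MC = log [ sum_{y_u != y_v} e^{-d_uv/T_m} /
  sum_{y_u = y_v, u != v} e^{-d_uv/T_m} ]`.  It decreases as classes separate
  relative to the overall scatter and is invariant to translation, rotation
  and global rescaling of the features, and to class-code permutation.
* `L_CE` — cross-entropy of pseudo-labels on confidence-kept target samples.

The combined objective is `max_{G,C} min_D lambda (L_adv - L_MC) - L_cls`
(plus the pseudo-label term), realized as a single backward pass: D descends
`L_adv`; G and C descend `L_cls + L_CE + lambda * L_MC` and ascend `L_adv`
through the reversal layer.  A "literal-sign" ablation mode is not provided
separately because, under the gradient-reversal realization, the literal
reading of the printed objective and the standard adversarial game produce
identical updates (ascent of G on `L_adv` *is* the reversal of D's descent).

### Pseudo-labels

Each epoch, in evaluation mode:

1. neuron predictions: `C(G(x_t))` softmax rows;
2. KNN predictions: class frequencies among the K = 5 Euclidean nearest
   labeled source samples in G-feature space; vote ties break by smallest
   summed neighbor distance, then lowest class code;
3. decision fusion: `w * neuron + (1 - w) * knn` with `w = 0.5`; the fused
   argmax is the pseudo-label, the fused maximum its confidence;
4. filtering: keep samples whose fused confidence strictly exceeds
   `kappa = 0.9`.  The fused probability is filtered (not the neuron-only
   probability) because the fused prediction is the final prediction.

Kept samples contribute the pseudo-label cross-entropy and (by default) also
enter the MC-loss pool alongside the source batch (`mc_pool =
"source+pseudo"`; a source-only mode exists).  If the filter keeps nothing,
the CE term is skipped that round and flagged in the log.

### Training protocol

RMSprop (alpha 0.99, eps 1e-8) at learning rate 1e-5, batch 32, Xavier
initialization, 500 iterations, results averaged over 3 fresh-seed runs.
An *iteration* is read as one pass over the balanced source training set in
minibatches (`iteration_unit="epoch"`); the single-step reading is available
but cannot train at this learning rate: RMSprop normalizes gradient
magnitude, so each parameter moves at most ~lr per step, and 500 single steps
(~5e-3 total) cannot reorganize Xavier-scale weights (~0.17).  `lambda`
defaults to 1 with a warm-up ramp from 0 over the first 30% of steps, giving
D a supervised head start before confusion pressure reaches G.  Target
batches are drawn independently and uniformly, matching the source batch
size.  Training aborts with a component-naming diagnostic if any loss goes
non-finite.

## Preprocessing

Fixed order per spectrum: (1) iterative modified-polyfit baseline correction
(degree 3, at most 100 iterations, stopping when the relative change of the
fit residual falls below 1e-3) — each round fits a least-squares polynomial
and clips the working spectrum to it, so the fit settles under the peaks;
(2) centered mean smoothing (window 9, edges shrink to the valid range);
(3) per-spectrum min-max normalization to [0, 1].

Dataset construction: healthy controls are partitioned 1:1 between the
domains; each domain (its disease samples plus its controls) splits 7:3 into
train/test, stratified by class.  SMOTE balances the *labeled source*
training set to 300 per class (defaults; synthetic experiments use smaller
targets) by interpolating between a sample and one of its 5 same-class
nearest neighbors.  The unlabeled target training set cannot be
class-balanced under the unsupervised protocol, so SMOTE is not applied to
it.  When the two domains were acquired at different spectral resolutions,
both are interpolated onto the source grid and one PCA basis — fitted on the
pooled source+target training rows — projects all four datasets to 50
components (a warning is raised if under 99% of variance is kept).

## Synthetic data

The generator emulates the study conditions: two spectrometer setups, binary
disease-vs-control classes, class imbalance and small cohorts.  A spectrum is
`gain * sum_p A_p(class) * N(center_p + offset + jitter, (width_p * wscale)^2)
+ cubic baseline + noise`, where the disease class adds `class_effect` to the
amplitude of designated discriminative peaks (defaults at 924, 929, 991,
1317, 1444 and 1653 cm^-1, with six further class-neutral serum bands).  The
default grid is 600 points over 500–2000 cm^-1.  Domain shift channels:
baseline polynomial, global gain, noise level, per-sample peak jitter, a
systematic wavenumber calibration offset (`peak_shift`) and a resolution
ratio (`width_scale`).  The first three are largely removed by the
preprocessing stack — by design — so the calibration offset and resolution
ratio are the shift channels that survive preprocessing and create the
transfer gap, as they do between real instruments.

What the generator does **not** emulate: fluorescence photobleaching,
cosmic-ray artifacts, detector nonlinearity, wavenumber-dependent instrument
response, intra-patient repeat structure, or any real serum biochemistry.
Passing tests therefore demonstrate the correctness and qualitative behavior
of the method, not clinical performance.

## Numerical choices

* All computation is float64 on a small in-package reverse-mode autodiff
  engine; forward passes are pure functions of (parameters, input) in
  evaluation mode, and every run is bit-reproducible from (seed, config,
  data).  Seeds are derived from one master seed via `SeedSequence`.
* Probabilities are clamped to [1e-7, 1 - 1e-7] inside logarithms, keeping
  every loss finite on saturated outputs.
* KNN neighbor-set boundary ties resolve by source index order (stable sort);
  `T_m` uses the printed 1/B normalization by default.
* Grad-CAM uses the multi-scale convolution feature maps (the only branch
  with positional structure): channel weights are position-averaged gradients
  of the class score, the map is the rectified weighted channel sum,
  linearly interpolated onto the wavenumber grid and min-max normalized;
  local maxima with contribution > 0.5 are reported as key peaks.  Degenerate
  (all-zero-gradient) maps warn instead of failing.
* t-SNE exports use perplexity 30 (reduced for tiny sample counts), 1000
  iterations, PCA initialization and a fixed seed.

## Scaled-down experiment sizes

The end-to-end synthetic experiments run on one CPU, so the study-scale
counts are reduced while keeping the published training recipe (lr 1e-5,
batch 32, 500 iterations, 3 seeds): cohorts of 34–72 samples per class per
domain, SMOTE target 150 per class (300 in the full-scale default), PCA to
50 components, 600-point grids.  These sizes are stated here as the package's
experimental design; the thresholds the experiments are checked against are
unchanged.

## Known limitations

* The adversarial game at learning rate 1e-5 exerts weak alignment pressure
  per step; tasks whose post-preprocessing feature misalignment is large
  (e.g. calibration offsets beyond ~2 peak widths) are not reliably closed
  within 500 iterations — the "hard" preset demonstrates exactly this regime.
* SMOTE on spectra interpolates linearly and cannot create new peak shapes.
* The discriminator conditions on detached class probabilities (the standard
  conditional-adversarial practice); entropy weighting and randomized
  multilinear projection are deliberately out of scope.
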