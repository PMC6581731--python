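# Methods

## The model

Scalp EEG is treated as an instantaneous linear mixture of a small number of
cortical source signals,

    X = A S,

with `X` the 32-channel recording, `S` the 12 latent sources, and `A` a
32 × 12 full-column-rank mixing matrix.  Because a multi-layer autoencoder
with *linear* activations composes to a single linear map, training a
symmetric stacked autoencoder (SAE) to reconstruct the channel vectors
forces the bottleneck code `H = W I` to retain the information in `X`; when
`X` truly lies in a 12-dimensional subspace, the 12-unit code is an estimate
of `S` up to an invertible linear transform.  The default encoder is
32 → 64 → 12 with the mirrored decoder 12 → 64 → 32, all layers biased
(5804 trainable parameters).

Decomposition success is judged by the adjusted coefficient of
determination between held-out channel vectors and their reconstruction,

    R²_adj = 1 − (1 − R²)(N − 1)/(N − p − 1),   R² = 1 − Σ(X − X̂)²/Σ(X − X̄)²,

with `p = 32` predictors and `N` the number of held-out sample vectors; the
decomposition is considered successful once R²_adj ≥ 0.9.  Because blind
source recovery has no preferred basis or scale, recovery quality against
synthetic ground truth is measured by canonical correlations between the
code and the true sources, not by elementwise error.

Each decomposed trial is cut into 1 s frames with 0.5 s step (a 63 s,
128 Hz trial gives exactly 125 frames).  Per frame and source, the power
spectral density is estimated by Welch's method using a single
Hanning-windowed segment spanning the frame (1 Hz resolution at 128
samples — sub-segmenting a 1 s frame would blur the 4–7 Hz theta band), and
integrated over the rhythm bands theta (4–7 Hz), alpha (8–13 Hz), beta
(14–30 Hz) and gamma (31–50 Hz); band-edge bins are inclusive on both
sides.  Delta (0.5–3.5 Hz) is defined but inactive by default because the
emulated recordings are 4–45 Hz band-passed.  This yields 125 × 48
frequency-band-power (FBP) sequences; the alternative connectivity feature
is the per-frame Pearson correlation of each source against a reference
source (default source 0; width 11, or 66 pairwise).

The classifier is the emotion timing model: an LSTM with 125 hidden units
consumes the 125-frame sequence, every per-step hidden output is flattened
(125 × 125) and passed through a 125-unit tanh fully connected layer and a
single sigmoid output — 2,040,376 trainable parameters with 48-dimensional
input.  The FC layer reads the *whole* sequence of hidden states rather
than the last one; that is the wiring consistent with the published
parameter count.  Training minimises the MSE between the sigmoid output and
0/1 labels (0 = Low, 1 = High) by plain mini-batch gradient descent with a
two-stage learning rate (default 1e-2 then 1e-3) and inverted dropout
(default 0.2) on the flattened LSTM outputs and the FC activations.

Evaluation binarises the 1–9 ratings at > 5.5 (High) and < 4.5 (Low),
discarding the mid-scale (values exactly at a threshold are discarded — the
rule is defined by strict inequalities); the majority class is randomly
down-sampled to the minority size; accuracy is the mean over 10
cross-validation folds of the per-fold fraction correct; arms are compared
with paired t-tests over fold accuracies (t = d̄/(s_d/√n), df = n − 1,
two-sided).

## Synthetic data generator

The generator emulates a DEAP-like session: 40–200 trials of 63 s at
128 Hz, 32 channels, per-trial valence/arousal ratings on 1–9.  What it
emulates:

- **Band-limited rhythms.**  Each of the 12 sources is a sum of sinusoids
  (4 per band, frequency uniform inside the band, random phase, Rayleigh
  amplitudes) over the four 4–45 Hz bands with per-trial Dirichlet band
  weights, plus 5 % pink-noise background, so ≥ 70 % (typically ≥ 95 %) of
  4–45 Hz power lies in the configured bands.
- **Within-trial dynamics.**  Band gains are drawn independently for the
  early and late half of each trial with a 2 s raised-cosine crossfade, so
  band power has a temporal trajectory the sequence classifier can exploit.
- **Scalp mixing.**  `A` has exponential distance decay on a ring (2–4
  sources dominate each channel), ±30 % lognormal-ish jitter, and is
  rejection-sampled to condition number < 100; optional i.i.d. Gaussian
  sensor noise is added after mixing.
- **Rating coupling.**  Valence is 5 + effect_size · z(contrast) + noise,
  clipped to [1, 9], where the contrast is the late-half minus early-half
  alpha+gamma band power averaged over sources and z(·) standardises across
  trials; arousal uses the overall beta+gamma level.  Rating noise
  (default sd 1.0 on the 1–9 scale) produces both discardable mid-scale
  trials and clear High/Low trials.  effect_size = 0 gives ratings
  independent of the signals.

What it does **not** emulate: volume conduction/forward head models, EOG or
EMG artifacts (the emulated recordings are assumed artifact-cleaned),
non-stationarities beyond the two-epoch band gains, inter-subject
variability, or any claim about the actual spectral content of DEAP
sources.  Passing tests therefore demonstrate that the pipeline recovers
linear mixtures and temporally coded labels under its own model assumptions
— not that it attains any particular accuracy on real recordings.

The "strong coupling" condition used in the end-to-end check is
effect_size 4.0 with rating noise sd 0.5: there a logistic oracle reading
the true latent contrast labels ≈ 99 % of kept trials correctly, so
end-to-end accuracy measures pipeline recovery rather than rating noise.
With the default noise sd 1.0 even that oracle is capped near 0.91, because
the ±0.5 discard band around the scale midpoint is narrower than the rating
noise.

## Numerical and design choices

- **SAE training unit** is one time sample's 32-channel vector, pooled over
  trials and time, shuffled, with the last 10 % held out for validation.
  Channels are z-scored with training-split statistics (stored in the
  model, inverted on reconstruction); gradient descent on raw amplitudes is
  ill-conditioned.  A cap of 100k pooled samples (60k in the experiment
  runner) is ample for fitting a 12-dimensional subspace.
- **SAE optimizer**: mini-batch GD, batch 128, lr 1e-2 halved every 15
  epochs, L2 weight penalty 1e-5, L1 code sparsity 1e-4; uniform fan-in
  initialisation with zero biases, fixed seed.  Training stops when the
  validation R²_adj reaches 0.9 (the decomposition-success rule) or at
  max_epochs.  All-zero input is flagged (R² undefined at zero variance)
  rather than raised.
- **LSTM optimizer**: plain mini-batch GD (no momentum), batch 16 — small
  batches buy more updates per epoch at equal flops, reaching ~0.99
  training accuracy in 30 epochs where batch 32 reached ~0.95.  Forget-gate
  biases start at 1.  Features are z-scored per dimension over the training
  set (scaler stored in the model).  Training runs in single precision;
  gradients are analytic and verified against central finite differences at
  tolerance 1e-5 in both networks.
- **Cross-validation folds are class-stratified.**  With a globally
  balanced dataset and unstratified random folds, the training and test
  imbalances anti-correlate and cross-validated accuracy on label-free data
  is biased below chance (we observed ≈ 0.40); stratification removes the
  artifact.  `kfold_split` keeps the disjoint/union/size-within-1 contract
  either way.
- **Balancing happens once, globally, before splitting** (the alternative —
  re-balancing within folds — would let a trial's inclusion depend on the
  fold draw).
- **Ties**: a predicted probability exactly at the threshold is called Low.
- **PCC of a constant channel within a frame** is set to 0 (no linear
  synchrony) instead of NaN; scalar `pcc` on zero-variance input raises.
- **Problem sizes at test scale** (the package's own choices): the
  decomposition-recovery check uses 4 × 63 s trials per seed with a 30k
  sample cap; the end-to-end check uses 200 trials with LSTM budgets of 40
  epochs (coupled arm) and 15 (decoupled arm), learning-rate switch at 3/4
  of the budget.  The study-scale schedule (a few thousand epochs, switch
  after ~500) is available through the same parameters.
- **One pooled SAE** is trained over all trials (a per-subject mode is a
  matter of slicing the TrialSet before training).

## Known limitations

- The decomposition is linear by construction; nonlinearly mixed or
  over-complete (more sources than code units) scenes are out of scope.
- ICA and SVM comparison arms are adapters over scikit-learn
  (FastICA, SVC); their internals are not part of this package.
- The LSTM is unidirectional; training uses fixed-length (125-frame)
  sequences only.
- No EDF/BDF readers and no parsing of DEAP's native pickled files; data
  enter through the HDF5 container documented in `saelstm.io`.
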