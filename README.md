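# saelstm

Emotion recognition from multi-channel scalp EEG by linear source
decomposition and sequence classification — a reusable library and CLI for
the SAE+LSTM pipeline, exercised end to end on a built-in synthetic
generator with known ground truth.

## The problem and the model

Scalp electrodes record a mixture of cortical source signals: in the linear
EEG mixing model the 32-channel recording `X` is `X = A S` with `S` the
activity of 12 functional brain regions and `A` an unknown full-column-rank
mixing matrix.  Because a stacked autoencoder (SAE) with linear activations
composes to one linear map, training a symmetric 32–64–12–64–32 SAE to
reconstruct the channel vectors makes its bottleneck code an estimate of
`S` up to an invertible linear transform.  Decomposition is validated by
the adjusted R² between held-out data and its reconstruction,

    R²_adj = 1 − (1 − R²)(N − 1)/(N − p − 1),  p = 32,

and accepted once R²_adj ≥ 0.9.

The decomposed sources are framed (1 s window, 0.5 s step → 125 frames per
63 s trial at 128 Hz) and each frame is summarised by its Hanning-windowed
Welch band power in the theta/alpha/beta/gamma bands (125 × 48 sequences),
or alternatively by per-frame Pearson correlations against a reference
source.  An LSTM (125 hidden units, one cell per frame) reads the sequence;
all per-step outputs feed a 125-unit fully connected layer and a sigmoid
unit that scores the High class of a rated emotion dimension (valence or
arousal, binarised at > 5.5 / < 4.5 with the mid-scale discarded and
classes balanced by down-sampling).  Accuracy is the mean fraction correct
over 10 cross-validation folds; arms are compared with paired t-tests.
The default models carry 5,804 (SAE) and 2,040,376 (LSTM+FC) trainable
parameters.

Both networks are implemented in NumPy with analytic gradients (verified
against finite differences in the test suite) and trained by mini-batch
gradient descent with staged learning rates, matching the linear-map
semantics the mixing model requires.

## Worked example

```python
import numpy as np
from saelstm import decompose, evaluate, features, synth

# 40 synthetic trials: 12 band-limited sources mixed into 32 channels,
# ratings coupled to the sources' band-power dynamics
trials, panel, truth = synth.simulate_trialset(
    n_trials=40, effect_size=4.0, rating_noise_sd=0.5, seed=0, return_truth=True)
print(trials.data.shape)

sae = decompose.train_sae(trials, seed=0, max_samples=30_000)
print(f"validation adjusted R^2 = {sae.final_adjusted_r2:.4f}")

codes = decompose.decompose(sae, trials)
cc = decompose.canonical_correlations(
    codes.transpose(0, 2, 1).reshape(-1, 12),
    panel.sources.transpose(0, 2, 1).reshape(-1, 12))
print(f"mean canonical correlation to true sources = {cc.mean():.4f}")

seqs = features.extract_fbp_sequence(codes, trials.fs)
print(seqs[0].values.shape)

labels = evaluate.label_trials(trials.ratings, "valence")
print(f"High/Low/discarded: {(labels == 1).sum()}/{(labels == 0).sum()}/{(labels == -1).sum()}")
```

prints

```
(40, 32, 8064)
validation adjusted R^2 = 0.9087
mean canonical correlation to true sources = 1.0000
(125, 48)
High/Low/discarded: 20/18/2
```

The trials have the expected 40 × 32 × 8064 layout; the SAE passes the 0.9
reconstruction criterion and its 12-unit code is essentially a linear
re-basing of the true sources (mean canonical correlation ≈ 1); each trial
becomes a 125-frame, 48-feature sequence; and the 1–9 valence ratings
binarise into roughly balanced High/Low classes with the ambiguous
mid-scale discarded.  A full cross-validated run of one pipeline arm is one
call (`evaluate.run_experiment`) or one CLI invocation:

```sh
saelstm evaluate --decomposition sae --feature fbp --classifier lstm \
    --n-trials 200 --effect-size 4.0 --seed 1 --out report.json
```

The same CLI provides `simulate`, `decompose`, `features`, `train`, and
`report` subcommands; data live in plain HDF5 containers (`saelstm.io`),
and a DEAP-shaped container (40 × 32 × 8064 @ 128 Hz with 1–9 ratings)
supplied by the user runs through the identical pipeline.

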