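"""Linear stacked autoencoder (SAE) for EEG source decomposition.

Scalp EEG is modelled as a linear mixture X = A S of a small number of
cortical source signals.  A symmetric autoencoder with *linear* activations
is trained to reconstruct the 32-channel sample vectors; because the map is
linear throughout, the bottleneck code of the trained encoder plays the role
of the unmixed sources S (up to an invertible linear transform — blind
source recovery has no preferred basis, so recovery quality is measured by
canonical correlation against ground truth, and reconstruction quality by
the adjusted R² between held-out data and its reconstruction).

Default architecture: encoder 32 -> 64 -> 12 with the mirrored decoder
12 -> 64 -> 32, every layer biased (5804 trainable parameters).  Training is
plain mini-batch gradient descent on MSE with step-decayed learning rate,
an L2 penalty on the weights and an L1 sparsity penalty on the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import UndefinedMetricError
from .synth import TrialSet

__all__ = [
    "SAEModel",
    "ReconstructionMetrics",
    "TrainingError",
    "count_sae_params",
    "train_sae",
    "reconstruct",
    "decompose",
    "adjusted_r2",
    "canonical_correlations",
]


class TrainingError(RuntimeError):
    """Training diverged or could not proceed."""


@dataclass
class ReconstructionMetrics:
    """Variance-explained summary of a reconstruction."""

    r2: float
    adjusted_r2: float
    n_samples: int
    n_predictors: int
    mse: float


def _mirror(widths: list[int] | tuple[int, ...]) -> list[int]:
    """[32, 64, 12] -> [32, 64, 12, 64, 32]."""
    w = list(widths)
    return w + w[-2::-1]


def count_sae_params(layer_widths, mirrored: bool = True) -> int:
    """Closed-form trainable-parameter count: sum of in*out + out per layer.

    With ``mirrored=True`` the widths describe the encoder and the decoder
    mirrors them; the default encoder [32, 64, 12] gives 5804.
    """
    widths = list(layer_widths)
    if len(widths) < 2:
        raise ValueError("need at least two layer widths")
    if any(w <= 0 for w in widths):
        raise ValueError("layer widths must be positive")
    full = _mirror(widths) if mirrored else widths
    return sum(full[i] * full[i + 1] + full[i + 1] for i in range(len(full) - 1))


@dataclass
class SAEModel:
    """Weights of the symmetric linear autoencoder.

    ``weights``/``biases`` cover encoder then decoder layers in order; the
    first ``n_encoder_layers`` entries form the encoder.  ``mu``/``sigma``
    hold the per-channel z-scoring fitted on the training split (applied
    before encoding, inverted after decoding).
    """

    widths: list[int]  # encoder widths, e.g. [32, 64, 12]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    mu: np.ndarray
    sigma: np.ndarray
    trained: bool = False
    final_adjusted_r2: float | None = None
    history: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_encoder_layers(self) -> int:
        return len(self.widths) - 1

    @property
    def n_sources(self) -> int:
        return self.widths[-1]

    @property
    def input_dim(self) -> int:
        return self.widths[0]

    @classmethod
    def init_random(cls, widths, seed: int = 0) -> "SAEModel":
        full = _mirror(list(widths))
        rng = np.random.default_rng(seed)
        weights, biases = [], []
        for n_in, n_out in zip(full[:-1], full[1:]):
            bound = 1.0 / np.sqrt(n_in)
            weights.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
            biases.append(np.zeros(n_out))
        return cls(
            widths=list(widths),
            weights=weights,
            biases=biases,
            mu=np.zeros(full[0]),
            sigma=np.ones(full[0]),
            seed=seed,
        )

    @classmethod
    def from_weights(cls, widths, weights, biases=None, trained: bool = True) -> "SAEModel":
        """Build a model from explicit matrices (e.g. the pseudo-inverse of a
        known mixing matrix); no input scaling, zero biases by default."""
        full = _mirror(list(widths))
        weights = [np.asarray(W, dtype=float) for W in weights]
        if biases is None:
            biases = [np.zeros(W.shape[0]) for W in weights]
        for W, n_in, n_out in zip(weights, full[:-1], full[1:]):
            if W.shape != (n_out, n_in):
                raise ValueError(f"weight shape {W.shape} != ({n_out}, {n_in})")
        return cls(
            widths=list(widths),
            weights=weights,
            biases=[np.asarray(b, dtype=float) for b in biases],
            mu=np.zeros(full[0]),
            sigma=np.ones(full[0]),
            trained=trained,
        )

    def n_params(self) -> int:
        return sum(W.size for W in self.weights) + sum(b.size for b in self.biases)

    # --- linear maps (inputs are (n, width) arrays) -----------------------

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu) / self.sigma

    def _unscale(self, x: np.ndarray) -> np.ndarray:
        return x * self.sigma + self.mu

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = self._scale(np.asarray(x, dtype=float))
        for W, b in zip(self.weights[: self.n_encoder_layers],
                        self.biases[: self.n_encoder_layers]):
            h = h @ W.T + b
        return h

    def decode(self, code: np.ndarray) -> np.ndarray:
        h = np.asarray(code, dtype=float)
        for W, b in zip(self.weights[self.n_encoder_layers:],
                        self.biases[self.n_encoder_layers:]):
            h = h @ W.T + b
        return self._unscale(h)


def reconstruct(model: SAEModel, x: np.ndarray) -> np.ndarray:
    """decoder(encoder(x)) for channel vectors ``x`` of shape (..., input_dim)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.input_dim:
        raise ValueError(
            f"input width {x.shape[-1]} != model input layer {model.input_dim}"
        )
    flat = x.reshape(-1, model.input_dim)
    return model.decode(model.encode(flat)).reshape(x.shape)


def decompose(model: SAEModel, trials) -> np.ndarray:
    """Apply the trained encoder sample-wise: (trials, C, T) -> (trials, K, T)."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    data = trials.data if isinstance(trials, TrialSet) else np.asarray(trials)
    if data.ndim != 3 or data.shape[1] != model.input_dim:
        raise ValueError("expected (trials, n_channels, samples) matching the model")
    n_trials, _, n_samp = data.shape
    flat = data.transpose(0, 2, 1).reshape(-1, model.input_dim)
    codes = model.encode(flat)
    return codes.reshape(n_trials, n_samp, model.n_sources).transpose(0, 2, 1)


def adjusted_r2(
    x: np.ndarray, x_hat: np.ndarray, p: int = 32, n: int | None = None
) -> ReconstructionMetrics:
    """Adjusted R² between data and its reconstruction.

    R² = 1 - Σ(x - x̂)² / Σ(x - x̄)², pooled over all entries with
    per-channel means x̄; adjusted = 1 - (1 - R²)(N - 1)/(N - p - 1), where N
    is the number of sample vectors (rows) and p the number of predictors
    (32 channels by default).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have the same shape")
    N = int(n) if n is not None else x.shape[0]
    if N <= p + 1:
        raise ValueError(f"need N > p+1 (N={N}, p={p})")
    sst = float(np.sum((x - x.mean(axis=0)) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("R² undefined: data has zero variance")
    sse = float(np.sum((x - x_hat) ** 2))
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (N - 1) / (N - p - 1)
    return ReconstructionMetrics(
        r2=r2, adjusted_r2=adj, n_samples=N, n_predictors=p, mse=sse / x.size
    )


# --- training ------------------------------------------------------------


def _forward(weights, biases, x):
    acts = [x]
    h = x
    for W, b in zip(weights, biases):
        h = h @ W.T + b
        acts.append(h)
    return acts


def loss_and_grads(weights, biases, x, l2_weight=0.0, l1_code=0.0, code_layer=None):
    """MSE + L2(weights) + L1(code) loss and its analytic gradients.

    ``x`` is a (batch, input_dim) array already on the model's internal
    scale.  Returns (loss, grad_weights, grad_biases).
    """
    n_layers = len(weights)
    if code_layer is None:
        code_layer = n_layers // 2  # bottleneck of a symmetric stack
    acts = _forward(weights, biases, x)
    x_hat = acts[-1]
    code = acts[code_layer]
    B = x.shape[0]
    mse = float(np.mean((x_hat - x) ** 2))
    loss = mse
    if l2_weight:
        loss += l2_weight * sum(float(np.sum(W**2)) for W in weights)
    if l1_code:
        loss += l1_code * float(np.mean(np.abs(code)))

    gW = [np.zeros_like(W) for W in weights]
    gb = [np.zeros_like(b) for b in biases]
    delta = 2.0 * (x_hat - x) / x.size
    for i in range(n_layers - 1, -1, -1):
        gW[i] = delta.T @ acts[i]
        gb[i] = delta.sum(axis=0)
        if l2_weight:
            gW[i] += 2.0 * l2_weight * weights[i]
        delta = delta @ weights[i]
        if l1_code and i == code_layer:
            delta = delta + l1_code * np.sign(acts[code_layer]) / (B * code.shape[1])
    return loss, gW, gb


def _pool_samples(data: TrialSet) -> np.ndarray:
    """Stack every time sample's channel vector: (trials*T, n_channels)."""
    return data.data.transpose(0, 2, 1).reshape(-1, data.n_channels)


def train_sae(
    data: TrialSet,
    sae_layers=(32, 64, 12),
    seed: int = 0,
    batch_size: int = 128,
    lr: float = 1e-2,
    lr_decay: float = 0.5,
    decay_every: int = 15,
    max_epochs: int = 60,
    l2_weight: float = 1e-5,
    l1_code: float = 1e-4,
    val_fraction: float = 0.1,
    target_r2: float | None = 0.9,
    max_samples: int | None = 100_000,
    p: int | None = None,
) -> SAEModel:
    """Train the linear SAE on pooled channel vectors by mini-batch GD.

    Sample vectors from all trials and time points are pooled, shuffled with
    ``seed`` and split (last ``val_fraction`` as validation).  Channels are
    z-scored using training-split statistics.  After each epoch the
    validation MSE and adjusted R² are logged; training stops once the
    validation adjusted R² reaches ``target_r2`` (or after ``max_epochs``).

    ``max_samples`` caps the pooled sample count (a 12-dimensional linear
    subspace does not need hundreds of thousands of samples to be fit).
    """
    widths = list(sae_layers)
    if widths[0] != data.n_channels:
        raise ValueError(
            f"sae input width {widths[0]} != data channels {data.n_channels}"
        )
    if p is None:
        p = widths[0]
    rng = np.random.default_rng(seed)
    X = _pool_samples(data)
    perm = rng.permutation(X.shape[0])
    X = X[perm]
    if max_samples is not None and X.shape[0] > max_samples:
        X = X[:max_samples]
    n_val = max(int(round(val_fraction * X.shape[0])), 1)
    X_train, X_val = X[:-n_val], X[-n_val:]

    model = SAEModel.init_random(widths, seed=seed)
    model.mu = X_train.mean(axis=0)
    sigma = X_train.std(axis=0)
    model.sigma = np.where(sigma > 0, sigma, 1.0)

    Z_train = model._scale(X_train)
    Z_val = model._scale(X_val)
    n_train = Z_train.shape[0]
    code_layer = len(widths) - 1

    lr_t = lr
    for epoch in range(max_epochs):
        if epoch > 0 and epoch % decay_every == 0:
            lr_t *= lr_decay
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch_size):
            idx = order[start : start + batch_size]
            loss, gW, gb = loss_and_grads(
                model.weights, model.biases, Z_train[idx],
                l2_weight=l2_weight, l1_code=l1_code, code_layer=code_layer,
            )
            if not np.isfinite(loss):
                raise TrainingError(
                    f"NaN/inf loss at epoch {epoch} (lr={lr_t}); try a smaller "
                    "learning rate or stronger regularisation"
                )
            for W, g in zip(model.weights, gW):
                W -= lr_t * g
            for b, g in zip(model.biases, gb):
                b -= lr_t * g

        acts = _forward(model.weights, model.biases, Z_val)
        val_mse = float(np.mean((acts[-1] - Z_val) ** 2))
        try:
            metrics = adjusted_r2(Z_val, acts[-1], p=p)
            adj = metrics.adjusted_r2
        except UndefinedMetricError:
            adj = float("nan")
        model.history.append({"epoch": epoch, "lr": lr_t, "val_mse": val_mse,
                              "val_adjusted_r2": adj})
        model.final_adjusted_r2 = adj
        if np.isnan(adj):
            break  # zero-variance validation data: nothing to fit
        if target_r2 is not None and adj >= target_r2:
            break

    model.trained = True
    return model


def canonical_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Canonical correlations between two multivariate samples (n, p), (n, q).

    Used to score blind source recovery, which is only identified up to an
    invertible linear transform.  Computed from the singular values of
    Qx^T Qy with Qx, Qy orthonormal bases of the centered columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y need the same number of rows")
    qx, _ = np.linalg.qr(x - x.mean(axis=0))
    qy, _ = np.linalg.qr(y - y.mean(axis=0))
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return np.clip(s, 0.0, 1.0)
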