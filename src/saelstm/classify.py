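"""Emotion timing model: LSTM over the framed feature sequence.

The classifier treats a trial's 125-frame feature sequence as a time series
carrying emotional context: an LSTM layer (one cell per frame, hidden width
125) mines the temporal correlations, every per-step hidden output is
flattened and passed through a fully connected layer (125 tanh units), and a
single sigmoid unit emits the probability of the "High" class.  Training
minimises the MSE between the sigmoid output and 0/1 labels by mini-batch
gradient descent with a two-stage learning rate (high first, then low) and
dropout on the LSTM outputs and the fully connected layer.

With the default widths (48 input features x 125 steps, hidden 125, FC 125,
one output) the model has 2,040,376 trainable parameters.

All forward/backward passes are plain NumPy with analytic gradients; the
gate layout is [input, forget, cell, output] stacked along the first axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decompose import TrainingError
from .features import FeatureSequence

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "count_classifier_params",
    "forward",
    "train_classifier",
    "predict_label",
]


@dataclass(frozen=True)
class ClassifierSpec:
    input_dim: int = 48
    seq_len: int = 125
    lstm_hidden: int = 125
    fc_units: int = 125
    output_units: int = 1
    dropout_lstm: float = 0.2
    dropout_fc: float = 0.2

    def __post_init__(self) -> None:
        for name in ("input_dim", "seq_len", "lstm_hidden", "fc_units", "output_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout_lstm", "dropout_fc"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")


def count_classifier_params(spec: ClassifierSpec) -> int:
    """Closed-form trainable-parameter count.

    4 gates of (input_dim + hidden) x hidden weights + hidden biases, an FC
    layer over the flattened seq_len x hidden outputs, and the output unit:
    4((D + H)H + H) + (T H)F + F + F O + O.  Defaults give 2,040,376.
    """
    d, t = spec.input_dim, spec.seq_len
    h, f, o = spec.lstm_hidden, spec.fc_units, spec.output_units
    return 4 * ((d + h) * h + h) + (t * h) * f + f + f * o + o


def _init_params(spec: ClassifierSpec, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    d, h = spec.input_dim, spec.lstm_hidden
    flat = spec.seq_len * h

    def u(shape, fan_in):
        return rng.uniform(-1, 1, size=shape) / np.sqrt(fan_in)

    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0  # forget-gate bias starts open
    return {
        "W": u((4 * h, d), d + h),
        "U": u((4 * h, h), d + h),
        "b": b,
        "W_fc": u((spec.fc_units, flat), flat),
        "b_fc": np.zeros(spec.fc_units),
        "W_out": u((spec.output_units, spec.fc_units), spec.fc_units),
        "b_out": np.zeros(spec.output_units),
    }


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    params: dict[str, np.ndarray]
    feat_mu: np.ndarray | None = None
    feat_sd: np.ndarray | None = None
    trained: bool = False
    history: list[dict] = field(default_factory=list)
    seed: int | None = None

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def standardize(self, x: np.ndarray) -> np.ndarray:
        if self.feat_mu is None:
            return x
        return (x - self.feat_mu) / self.feat_sd


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_cache(params, spec, x):
    """LSTM + FC forward over a batch x of shape (B, T, D); returns
    (probabilities (B, O), cache for backprop)."""
    B, T, D = x.shape
    H = spec.lstm_hidden
    # input contribution for every step in one matmul
    zx = x.reshape(B * T, D) @ params["W"].T  # (B*T, 4H)
    zx = zx.reshape(B, T, 4 * H)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    gates = np.empty((T, B, 4 * H))
    cs = np.empty((T, B, H))
    tanh_cs = np.empty((T, B, H))
    hs = np.empty((T, B, H))
    c_prevs = np.empty((T, B, H))
    for t in range(T):
        z = zx[:, t] + h @ params["U"].T + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_prevs[t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[t] = np.concatenate([i, f, g, o], axis=1)
        cs[t] = c
        tanh_cs[t] = tc
        hs[t] = h
    flat = hs.transpose(1, 0, 2).reshape(B, T * H)
    return flat, {"x": x, "gates": gates, "cs": cs, "tanh_cs": tanh_cs,
                  "hs": hs, "c_prevs": c_prevs}


def _head_forward(params, flat, m_lstm=None, m_fc=None):
    flat_d = flat * m_lstm if m_lstm is not None else flat
    a = flat_d @ params["W_fc"].T + params["b_fc"]
    fc = np.tanh(a)
    fc_d = fc * m_fc if m_fc is not None else fc
    p = _sigmoid(fc_d @ params["W_out"].T + params["b_out"])
    return p, flat_d, fc, fc_d


def forward(model: TrainedClassifier, sequence: np.ndarray) -> np.ndarray | float:
    """Class probability for one (T, D) sequence or a (B, T, D) batch.

    Dropout is disabled at inference.
    """
    if isinstance(sequence, FeatureSequence):
        sequence = sequence.values
    x = np.asarray(sequence, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    spec = model.spec
    if x.shape[1] != spec.seq_len or x.shape[2] != spec.input_dim:
        raise ValueError(
            f"sequence shape {x.shape[1:]} != ({spec.seq_len}, {spec.input_dim})"
        )
    x = model.standardize(x)
    flat, _ = _forward_cache(model.params, spec, x)
    p, *_ = _head_forward(model.params, flat)
    p = p[:, 0] if spec.output_units == 1 else p
    return float(p[0]) if single else p


def loss_and_grads(params, spec, x, y, m_lstm=None, m_fc=None, l2_weight=0.0):
    """MSE loss between sigmoid outputs and 0/1 labels, with analytic
    gradients for every parameter.  ``x`` (B, T, D) is assumed already
    standardized; dropout masks (inverted-dropout scaled) are optional."""
    B, T, _ = x.shape
    H = spec.lstm_hidden
    y = np.asarray(y, dtype=x.dtype).reshape(B, spec.output_units)

    flat, cache = _forward_cache(params, spec, x)
    p, flat_d, fc, fc_d = _head_forward(params, flat, m_lstm, m_fc)

    loss = float(np.mean((p - y) ** 2))
    if l2_weight:
        loss += l2_weight * sum(
            float(np.sum(params[k] ** 2)) for k in ("W", "U", "W_fc", "W_out")
        )

    grads = {}
    dp = 2.0 * (p - y) / p.size
    dz_out = dp * p * (1.0 - p)
    grads["W_out"] = dz_out.T @ fc_d
    grads["b_out"] = dz_out.sum(axis=0)
    dfc_d = dz_out @ params["W_out"]
    dfc = dfc_d * m_fc if m_fc is not None else dfc_d
    da = dfc * (1.0 - fc**2)
    grads["W_fc"] = da.T @ flat_d
    grads["b_fc"] = da.sum(axis=0)
    dflat_d = da @ params["W_fc"]
    dflat = dflat_d * m_lstm if m_lstm is not None else dflat_d
    dhs = dflat.reshape(B, T, H).transpose(1, 0, 2)  # (T, B, H)

    gates, cs, tanh_cs, c_prevs = (cache["gates"], cache["cs"],
                                   cache["tanh_cs"], cache["c_prevs"])
    hs = cache["hs"]
    dz_all = np.empty((T, B, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    U = params["U"]
    for t in range(T - 1, -1, -1):
        i = gates[t][:, :H]
        f = gates[t][:, H : 2 * H]
        g = gates[t][:, 2 * H : 3 * H]
        o = gates[t][:, 3 * H :]
        dh = dhs[t] + dh_next
        tc = tanh_cs[t]
        do = dh * tc
        dc = dh * o * (1.0 - tc**2) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * c_prevs[t]
        dc_next = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        dz_all[t] = dz
        dh_next = dz @ U

    dz_flat = dz_all.transpose(1, 0, 2).reshape(B * T, 4 * H)
    grads["W"] = dz_flat.T @ x.reshape(B * T, -1)
    h_prevs = np.concatenate([np.zeros((1, B, H)), hs[:-1]], axis=0)
    grads["U"] = dz_flat.T @ h_prevs.transpose(1, 0, 2).reshape(B * T, H)
    grads["b"] = dz_flat.sum(axis=0)
    if l2_weight:
        for k in ("W", "U", "W_fc", "W_out"):
            grads[k] = grads[k] + 2.0 * l2_weight * params[k]
    return loss, grads


def _as_array(sequences) -> np.ndarray:
    if isinstance(sequences, np.ndarray):
        return np.asarray(sequences, dtype=float)
    return np.stack([
        s.values if isinstance(s, FeatureSequence) else np.asarray(s, dtype=float)
        for s in sequences
    ])


def train_classifier(
    sequences,
    labels,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    batch_size: int = 32,
    lr_high: float = 1e-2,
    lr_low: float = 1e-3,
    switch_epoch: int = 500,
    max_epochs: int = 1000,
    accuracy_goal: float = 0.995,
    l2_weight: float = 1e-5,
    standardize: bool = True,
    dtype=np.float32,
) -> TrainedClassifier:
    """Train the LSTM+FC emotion classifier by mini-batch gradient descent.

    Labels are coded 0 = Low, 1 = High for the MSE loss against the sigmoid
    output.  The learning rate is ``lr_high`` until ``switch_epoch`` and
    ``lr_low`` afterwards; training stops when the training accuracy reaches
    ``accuracy_goal`` or at ``max_epochs``.  Dropout (from the spec) is
    active during training only.  Features are z-scored per dimension over
    the training set; the scaler is stored in the returned model.

    ``dtype`` controls the training precision; single precision halves the
    cost and is ample for gradient descent on this loss.
    """
    X = _as_array(sequences)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 3 or X.shape[0] != y.shape[0]:
        raise ValueError("need (N, T, D) sequences and N labels")
    if spec is None:
        spec = ClassifierSpec(input_dim=X.shape[2], seq_len=X.shape[1])
    if X.shape[1] != spec.seq_len or X.shape[2] != spec.input_dim:
        raise ValueError("sequence shape does not match classifier spec")
    classes = np.unique(y)
    if len(classes) < 2:
        warnings.warn("training labels contain a single class", stacklevel=2)

    rng = np.random.default_rng(seed)
    model = TrainedClassifier(spec=spec, params=_init_params(spec, seed), seed=seed)
    if standardize:
        model.feat_mu = X.mean(axis=(0, 1))
        sd = X.std(axis=(0, 1))
        model.feat_sd = np.where(sd > 0, sd, 1.0)
        X = model.standardize(X)
    X = X.astype(dtype)
    model.params = {k: v.astype(dtype) for k, v in model.params.items()}

    n = X.shape[0]
    flat_dim = spec.seq_len * spec.lstm_hidden
    for epoch in range(max_epochs):
        lr = lr_high if epoch < switch_epoch else lr_low
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            m_lstm = m_fc = None
            if spec.dropout_lstm > 0:
                keep = 1.0 - spec.dropout_lstm
                m_lstm = ((rng.random((len(idx), flat_dim)) < keep) / keep).astype(dtype)
            if spec.dropout_fc > 0:
                keep = 1.0 - spec.dropout_fc
                m_fc = ((rng.random((len(idx), spec.fc_units)) < keep) / keep).astype(dtype)
            loss, grads = loss_and_grads(
                model.params, spec, xb, yb, m_lstm, m_fc, l2_weight=l2_weight
            )
            if not np.isfinite(loss):
                raise TrainingError(f"NaN/inf loss at epoch {epoch} (lr={lr})")
            for k, g in grads.items():
                model.params[k] -= lr * g
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        # training accuracy for the stopping rule
        probs = []
        for start in range(0, n, 256):
            flat, _ = _forward_cache(model.params, spec, X[start : start + 256])
            pb, *_ = _head_forward(model.params, flat)
            probs.append(pb[:, 0])
        pred = (np.concatenate(probs) > 0.5).astype(float)
        acc = float(np.mean(pred == y))
        model.history.append({"epoch": epoch, "lr": lr, "loss": epoch_loss,
                              "train_accuracy": acc})
        if acc >= accuracy_goal:
            break

    model.trained = True
    return model


def predict_label(model: TrainedClassifier, sequence, threshold: float = 0.5) -> str:
    """"High" iff the predicted probability exceeds ``threshold``; a tie at
    exactly the threshold is called "Low"."""
    p = forward(model, sequence)
    return "High" if p > threshold else "Low"
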