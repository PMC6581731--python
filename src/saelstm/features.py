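"""Frame-wise spectral and connectivity features for EEG-like signals.

Signals are cut into short overlapping frames (within which the signal is
treated as stationary), and each frame is summarised either by its power in
the classical EEG rhythm bands (frequency band power, FBP) or by the Pearson
correlation of each channel against a reference channel (PCC).  A 63 s trial
at 128 Hz framed with a 1 s window and 0.5 s step yields 125 frames, so a
12-source trial becomes a 125 x 48 FBP feature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FrameSpec",
    "BandSet",
    "FeatureSequence",
    "UndefinedMetricError",
    "frame_signal",
    "hanning",
    "welch_psd",
    "band_power",
    "pcc",
    "extract_fbp_sequence",
    "extract_pcc_sequence",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (e.g. zero variance)."""


#: Classical EEG rhythm bands in Hz (inclusive edges).
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.5),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 50.0),
}

#: Bands used for FBP features; delta is excluded because the data model
#: assumes a 4-45 Hz band-passed recording.
DEFAULT_ACTIVE_BANDS = ("theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class FrameSpec:
    """Sliding-window framing parameters.

    window_s : window length in seconds (default 1.0)
    step_s   : hop between window starts in seconds (default 0.5, i.e. 50 %
               overlap)
    """

    window_s: float = 1.0
    step_s: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.window_s):
            raise ValueError(
                f"require 0 < step_s <= window_s, got step_s={self.step_s}, "
                f"window_s={self.window_s}"
            )

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_s * fs))

    def n_frames(self, n_samples: int, fs: float) -> int:
        w, s = self.window_samples(fs), self.step_samples(fs)
        if n_samples < w:
            raise ValueError(f"signal of {n_samples} samples shorter than window ({w})")
        return (n_samples - w) // s + 1


@dataclass(frozen=True)
class BandSet:
    """Named frequency intervals and the subset active for FBP extraction."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(EEG_BANDS)
    )
    active: tuple[str, ...] = DEFAULT_ACTIVE_BANDS

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name, (lo, hi) in sorted(self.bands.items(), key=lambda kv: kv[1][0]):
            if lo >= hi:
                raise ValueError(f"band {name!r} has lo >= hi")
            if lo < prev_hi:
                raise ValueError(f"band {name!r} overlaps its lower neighbour")
            prev_hi = hi
        for name in self.active:
            if name not in self.bands:
                raise ValueError(f"active band {name!r} not defined")

    def interval(self, name: str) -> tuple[float, float]:
        return self.bands[name]


@dataclass
class FeatureSequence:
    """A per-trial feature matrix of shape (n_frames, feature_dim)."""

    values: np.ndarray
    feature_names: list[str]
    trial_id: int = 0
    label: int | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]


def frame_signal(x: np.ndarray, fs: float, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Slice ``x`` (..., samples) into overlapping frames.

    Returns an array of shape (..., n_frames, window_samples).  Trailing
    samples that do not fill a whole window are dropped.
    """
    x = np.asarray(x)
    w = spec.window_samples(fs)
    s = spec.step_samples(fs)
    n = spec.n_frames(x.shape[-1], fs)
    frames = np.lib.stride_tricks.sliding_window_view(x, w, axis=-1)
    return frames[..., ::s, :][..., :n, :]


def hanning(n: int) -> np.ndarray:
    """Hanning window w[k] = 0.5 (1 - cos(2 pi k / (n-1))), k = 0..n-1."""
    if n < 2:
        raise ValueError("hanning window needs n >= 2")
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n - 1)))


def welch_psd(frame: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density of ``frame`` (..., samples).

    A single Hanning-windowed segment spanning the whole frame is used, so a
    128-sample frame at 128 Hz gives 1 Hz resolution — fine enough to resolve
    the 4-7 Hz theta band.  Density scaling: integrating the PSD over
    frequency recovers the signal power (Parseval, up to window leakage).
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[-1]
    if n < 2:
        raise ValueError("frame must have at least 2 samples")
    freqs, psd = sps.welch(
        frame,
        fs=fs,
        window=hanning(n),
        nperseg=n,
        noverlap=0,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Integrate the PSD over ``band`` (edges inclusive): sum of psd * df."""
    lo, hi = band
    nyq = freqs[-1]
    if lo > nyq:
        raise ValueError(f"band {band} lies beyond Nyquist ({nyq} Hz)")
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    df = freqs[1] - freqs[0]
    return np.sum(psd[..., mask], axis=-1) * df


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length signals."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        raise UndefinedMetricError("PCC undefined for a zero-variance signal")
    return float(np.sum(xc * yc) / denom)


def _band_power_frames(
    frames: np.ndarray, fs: float, bands: BandSet
) -> np.ndarray:
    """Band powers for pre-framed data (..., n_frames, window) ->
    (..., n_frames, n_active_bands)."""
    freqs, psd = welch_psd(frames, fs)
    return np.stack(
        [band_power(freqs, psd, bands.interval(name)) for name in bands.active],
        axis=-1,
    )


def extract_fbp_sequence(
    source_trials: np.ndarray,
    fs: float,
    spec: FrameSpec = FrameSpec(),
    bands: BandSet = BandSet(),
    log_transform: bool = False,
) -> list[FeatureSequence]:
    """Frequency-band-power feature sequences, one per trial.

    Parameters
    ----------
    source_trials
        Array (n_trials, n_channels, n_samples); typically the decomposed
        source signals, optionally the raw scalp channels.
    log_transform
        If True, features are log(power + 1e-12).

    Returns
    -------
    One :class:`FeatureSequence` per trial with shape
    (n_frames, n_channels * n_active_bands); feature order is channel-major,
    then band (ch0:theta, ch0:alpha, ..., ch1:theta, ...).
    """
    data = np.asarray(source_trials, dtype=float)
    if data.ndim != 3:
        raise ValueError("source_trials must be (trials, channels, samples)")
    n_trials, n_ch, _ = data.shape
    frames = frame_signal(data, fs, spec)  # (trials, ch, frames, w)
    bp = _band_power_frames(frames, fs, bands)  # (trials, ch, frames, bands)
    if log_transform:
        bp = np.log(bp + 1e-12)
    # channel-major feature ordering
    seq = np.transpose(bp, (0, 2, 1, 3)).reshape(n_trials, bp.shape[2], -1)
    names = [f"ch{c}:{b}" for c in range(n_ch) for b in bands.active]
    return [
        FeatureSequence(values=seq[t], feature_names=list(names), trial_id=t)
        for t in range(n_trials)
    ]


def extract_pcc_sequence(
    source_trials: np.ndarray,
    fs: float,
    spec: FrameSpec = FrameSpec(),
    reference_channel: int = 0,
    pairwise: bool = False,
) -> list[FeatureSequence]:
    """Per-frame Pearson correlations against a reference channel.

    In reference mode the feature width is n_channels - 1; with
    ``pairwise=True`` all channel pairs are used (width n*(n-1)/2).  A frame
    in which a channel is constant contributes a 0 feature (correlation with
    a flat signal is undefined; zero encodes "no linear synchrony").
    """
    data = np.asarray(source_trials, dtype=float)
    if data.ndim != 3:
        raise ValueError("source_trials must be (trials, channels, samples)")
    n_trials, n_ch, _ = data.shape
    if not (0 <= reference_channel < n_ch):
        raise ValueError(f"reference channel {reference_channel} out of range")
    frames = frame_signal(data, fs, spec)  # (trials, ch, frames, w)
    centered = frames - frames.mean(axis=-1, keepdims=True)
    norms = np.sqrt(np.sum(centered**2, axis=-1))  # (trials, ch, frames)

    if pairwise:
        pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    else:
        pairs = [(reference_channel, j) for j in range(n_ch) if j != reference_channel]

    feats = np.empty((n_trials, frames.shape[2], len(pairs)))
    for k, (i, j) in enumerate(pairs):
        num = np.sum(centered[:, i] * centered[:, j], axis=-1)
        den = norms[:, i] * norms[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        feats[:, :, k] = r
    names = [f"pcc:{i}-{j}" for i, j in pairs]
    return [
        FeatureSequence(values=feats[t], feature_names=list(names), trial_id=t)
        for t in range(n_trials)
    ]
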