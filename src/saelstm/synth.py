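"""Synthetic multi-channel EEG with known linear-mixing ground truth.

The generator emulates a DEAP-like recording: 12 band-limited cortical
source signals are mixed linearly into 32 scalp channels (X = A S) with
optional additive sensor noise, and per-trial valence/arousal ratings on the
1-9 scale are statistically coupled to the sources' band-power dynamics.
Because the true sources and mixing matrix are retained, every downstream
stage (decomposition, features, classification) can be tested against ground
truth without any external download.

Each source is a sum of within-band sinusoids (random frequency inside the
band, random phase, Rayleigh amplitudes) plus a small pink-noise background.
Band amplitudes are drawn independently for the early and the late half of
each trial (with a smooth crossfade), so band power carries within-trial
temporal structure that the ratings can latch onto.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import EEG_BANDS, DEFAULT_ACTIVE_BANDS, band_power, welch_psd

__all__ = [
    "SourcePanel",
    "MixingGroundTruth",
    "TrialSet",
    "simulate_sources",
    "make_mixing",
    "mix",
    "attach_ratings",
    "simulate_trialset",
]

DEFAULT_CHANNEL_NAMES = [f"EEG{i:02d}" for i in range(32)]


@dataclass
class SourcePanel:
    """Latent band-limited source signals, (n_trials, n_sources, n_samples)."""

    sources: np.ndarray
    fs: float = 128.0
    band_profile: list[list[tuple[str, float]]] | None = None

    @property
    def n_trials(self) -> int:
        return self.sources.shape[0]

    @property
    def n_sources(self) -> int:
        return self.sources.shape[1]

    @property
    def n_samples(self) -> int:
        return self.sources.shape[2]

    def validate(self) -> None:
        if self.sources.ndim != 3:
            raise ValueError("sources must be (trials, sources, samples)")
        if not np.isfinite(self.sources).all():
            raise ValueError("sources contain non-finite values")
        var = self.sources.var(axis=-1)
        if (var == 0).any():
            raise ValueError("every source must have nonzero variance")


@dataclass
class MixingGroundTruth:
    """True mixing matrix A (n_channels x n_sources) plus sensor-noise level."""

    A: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self, cond_max: float = 100.0) -> None:
        n_ch, n_src = self.A.shape
        if n_src > n_ch:
            raise ValueError("need n_sources <= n_channels for full column rank")
        if np.linalg.matrix_rank(self.A) < n_src:
            raise ValueError("mixing matrix is column-rank deficient")
        if np.linalg.cond(self.A) > cond_max:
            raise ValueError(f"mixing matrix condition number exceeds {cond_max}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class TrialSet:
    """Scalp-level trials: data (trials, channels, samples) plus 1-9 ratings."""

    data: np.ndarray
    ratings: np.ndarray  # (trials, 2): valence, arousal
    fs: float = 128.0
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNEL_NAMES))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.ratings.shape != (self.n_trials, 2):
            raise ValueError("ratings must have shape (n_trials, 2)")
        if ((self.ratings < 1) | (self.ratings > 9)).any():
            raise ValueError("ratings must lie in [1, 9]")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid div by zero at DC
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def simulate_sources(
    n_trials: int,
    n_sources: int = 12,
    duration_s: float = 63.0,
    fs: float = 128.0,
    seed: int | None = None,
    band_profile: list[list[tuple[str, float]]] | None = None,
    n_osc_per_band: int = 4,
    pink_noise_rel: float = 0.05,
    crossfade_s: float = 2.0,
) -> SourcePanel:
    """Simulate band-limited cortical source signals.

    Parameters
    ----------
    band_profile
        Optional per-source list of (band_name, relative_power) pairs.  By
        default every source draws random weights over the four 4-45 Hz
        rhythm bands (theta/alpha/beta/gamma), redrawn per trial and per
        trial half so band power varies both across trials and within them.
    n_osc_per_band
        Sinusoids per band; frequencies uniform inside the band, phases
        uniform, amplitudes Rayleigh.
    pink_noise_rel
        Pink-noise background power relative to oscillatory power (small, so
        at least ~70 % of 4-45 Hz power stays inside the configured bands).
    crossfade_s
        Raised-cosine transition length between the early-half and the
        late-half band amplitudes.

    Returns
    -------
    :class:`SourcePanel` of shape (n_trials, n_sources, duration_s * fs).
    """
    if n_trials <= 0 or n_sources <= 0 or duration_s <= 0 or fs <= 0:
        raise ValueError("all dimensions and rates must be positive")
    n_samples = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs

    if band_profile is not None and len(band_profile) != n_sources:
        raise ValueError("band_profile must list one profile per source")

    # smooth early->late crossfade envelope in [0, 1]
    half = n_samples // 2
    n_fade = min(int(round(crossfade_s * fs)), n_samples)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, max(n_fade, 2))))
    env_late = np.zeros(n_samples)
    start = max(half - n_fade // 2, 0)
    env_late[start : start + len(ramp)] = ramp[: n_samples - start]
    env_late[start + len(ramp):] = 1.0
    env_early = 1.0 - env_late

    out = np.empty((n_trials, n_sources, n_samples))
    for trial in range(n_trials):
        for j in range(n_sources):
            if band_profile is not None:
                profile = band_profile[j]
            else:
                w = rng.dirichlet(np.ones(len(DEFAULT_ACTIVE_BANDS)))
                profile = list(zip(DEFAULT_ACTIVE_BANDS, w))
            sig = np.zeros(n_samples)
            for band_name, weight in profile:
                if weight <= 0:
                    continue
                lo, hi = EEG_BANDS[band_name]
                lo = max(lo, 0.1)
                hi = min(hi, fs / 2 * 0.98)
                # independent early/late gains give the band power a
                # within-trial time course
                g_early = rng.rayleigh(1.0)
                g_late = rng.rayleigh(1.0)
                gain = np.sqrt(weight) * (g_early * env_early + g_late * env_late)
                osc = np.zeros(n_samples)
                for _ in range(n_osc_per_band):
                    f0 = rng.uniform(lo, hi)
                    phase = rng.uniform(0, 2 * np.pi)
                    amp = rng.rayleigh(1.0) / np.sqrt(n_osc_per_band)
                    osc += amp * np.sin(2 * np.pi * f0 * t + phase)
                sig += gain * osc
            if pink_noise_rel > 0:
                osc_power = sig.var()
                if osc_power > 0:
                    sig += np.sqrt(pink_noise_rel * osc_power) * _pink_noise(
                        rng, n_samples
                    )
                else:
                    sig += np.sqrt(pink_noise_rel) * _pink_noise(rng, n_samples)
            out[trial, j] = sig

    panel = SourcePanel(sources=out, fs=fs, band_profile=band_profile)
    panel.validate()
    return panel


def make_mixing(
    n_channels: int = 32,
    n_sources: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
    cond_max: float = 100.0,
    decay: float = 0.12,
    max_tries: int = 200,
) -> MixingGroundTruth:
    """Draw a physiologically flavoured mixing matrix.

    Sources and channels are placed on a ring (a stand-in for scalp
    geometry); each channel weights nearby sources with an exponential
    distance decay, so 2-4 sources dominate each channel.  Candidates are
    rejection-sampled until the condition number is below ``cond_max``.
    """
    rng = np.random.default_rng(seed)
    src_pos = np.arange(n_sources) / n_sources  # positions on unit ring
    ch_pos = np.arange(n_channels) / n_channels
    d = np.abs(ch_pos[:, None] - src_pos[None, :])
    d = np.minimum(d, 1.0 - d)  # ring distance
    base = np.exp(-d / decay)
    for _ in range(max_tries):
        A = base * (1.0 + 0.3 * rng.standard_normal(base.shape))
        truth = MixingGroundTruth(A=A, noise_sd=noise_sd, seed=seed)
        try:
            truth.validate(cond_max=cond_max)
        except ValueError:
            continue
        return truth
    raise RuntimeError("could not sample a well-conditioned mixing matrix")


def mix(
    sources: SourcePanel,
    truth: MixingGroundTruth,
    ratings: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> TrialSet:
    """Mix sources into scalp channels: data[t] = A @ sources[t] + noise.

    ``ratings`` default to a neutral 5.0 for both dimensions; use
    :func:`attach_ratings` (or :func:`simulate_trialset`) for ratings coupled
    to the source dynamics.
    """
    truth.validate()
    n_ch, n_src = truth.A.shape
    if n_src != sources.n_sources:
        raise ValueError(
            f"mixing matrix expects {n_src} sources, panel has {sources.n_sources}"
        )
    rng = np.random.default_rng(truth.seed)
    data = np.einsum("cs,tsn->tcn", truth.A, sources.sources)
    if truth.noise_sd > 0:
        data = data + truth.noise_sd * rng.standard_normal(data.shape)
    if ratings is None:
        ratings = np.full((sources.n_trials, 2), 5.0)
    if channel_names is None:
        channel_names = [f"EEG{i:02d}" for i in range(n_ch)]
    ts = TrialSet(data=data, ratings=np.asarray(ratings, dtype=float),
                  fs=sources.fs, channel_names=channel_names)
    ts.validate()
    return ts


def _half_band_power(x: np.ndarray, fs: float, bands: list[str]) -> np.ndarray:
    """Total power of ``x`` (..., samples) in the named bands."""
    freqs, psd = welch_psd(x, fs)
    return sum(band_power(freqs, psd, EEG_BANDS[b]) for b in bands)


def attach_ratings(
    sources: SourcePanel,
    effect_size: float = 2.0,
    seed: int | None = None,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Generate 1-9 valence/arousal ratings coupled to the source dynamics.

    Valence tracks a temporal contrast — mean alpha+gamma power in the late
    half of the trial minus the early half — standardised across trials;
    arousal tracks the overall beta+gamma power level.  Each rating is
    5 + effect_size * z + N(0, noise_sd), clipped to [1, 9].  With
    ``effect_size=0`` the ratings are independent of the signals.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be nonnegative")
    rng = np.random.default_rng(seed)
    S, fs = sources.sources, sources.fs
    half = S.shape[-1] // 2
    early = _half_band_power(S[..., :half], fs, ["alpha", "gamma"]).mean(axis=1)
    late = _half_band_power(S[..., half:], fs, ["alpha", "gamma"]).mean(axis=1)
    contrast = late - early
    level = _half_band_power(S, fs, ["beta", "gamma"]).mean(axis=1)

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    valence = 5.0 + effect_size * _z(contrast) + noise_sd * rng.standard_normal(len(contrast))
    arousal = 5.0 + effect_size * _z(level) + noise_sd * rng.standard_normal(len(level))
    return np.clip(np.column_stack([valence, arousal]), 1.0, 9.0)


def simulate_trialset(
    n_trials: int = 40,
    n_channels: int = 32,
    n_sources: int = 12,
    duration_s: float = 63.0,
    fs: float = 128.0,
    noise_sd: float = 0.0,
    effect_size: float = 2.0,
    rating_noise_sd: float = 1.0,
    seed: int = 0,
    return_truth: bool = False,
):
    """One-call generator: sources -> mixing -> ratings -> TrialSet.

    Sub-seeds for the three stages are derived from ``seed`` so a single
    integer reproduces the whole dataset.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    panel = simulate_sources(n_trials, n_sources, duration_s, fs, seed=seeds[0])
    truth = make_mixing(n_channels, n_sources, noise_sd=noise_sd, seed=seeds[1])
    ratings = attach_ratings(panel, effect_size=effect_size, seed=seeds[2],
                             noise_sd=rating_noise_sd)
    trials = mix(panel, truth, ratings=ratings)
    if return_truth:
        return trials, panel, truth
    return trials
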