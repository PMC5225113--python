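"""Synthetic stimulus/EEG trial sets with known ground-truth TRFs.

The generator emulates the statistical structure the encoding analysis
assumes — 60-s trials at 128 Hz, a nonnegative slow acoustic envelope, a
motion signal partially correlated with the envelope, and non-overlapping
viseme intervals from ~12 categories — and synthesizes EEG by running the
forward convolution model with a known kernel plus band-limited noise.
Because the generating kernel is known, every downstream stage (fitting,
cross-validation, controls) can be checked for parameter recovery rather
than plausibility alone.

What it deliberately does **not** emulate: acoustically realistic speech,
articulatory motion statistics, volume conduction between channels
(channel noise is independent), or non-stationarity across a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .features import combine_features, visemes_to_feature
from .crossval import TrialSet
from .trf import LagWindow, TRFModel, predict
from .types import (
    EEGRecording,
    ParameterError,
    StimulusFeature,
    VisemeSequence,
)

__all__ = ["SimConfig", "gen_stimuli", "gen_ground_truth", "gen_eeg", "simulate_session", "SimSession"]

#: Fixed non-uniform category distribution for generated viseme sequences.
#: Viseme categories in natural speech are far from equiprobable; a three-tier
#: weighting (frequent / mid / rare) stands in for that skew.
VISEME_WEIGHTS = np.array([2, 2, 4, 1, 4, 2, 2, 4, 4, 2, 1, 1], dtype=float)


@dataclass
class SimConfig:
    """Study conditions for one simulated recording session.

    Defaults mirror the target recording setup: 15 trials of 60 s at 128 Hz.
    32 channels keep desk-scale runs fast; set ``n_channels=128`` for a
    montage-sized session.  ``envelope_motion_corr`` is the target Pearson
    correlation between the envelope and motion signals (mouth motion and
    the acoustic envelope are correlated in real speech); ``snr_db`` is the
    per-channel power ratio of the convolutional EEG component to the
    additive noise.
    """

    n_trials: int = 15
    duration: float = 60.0
    rate: float = 128.0
    n_channels: int = 32
    n_visemes: int = 12
    envelope_motion_corr: float = 0.5
    snr_db: float = 10.0
    seed: int = 0
    equal_viseme_amplitudes: bool = False

    def __post_init__(self):
        if min(self.n_trials, self.duration, self.rate, self.n_channels, self.n_visemes) <= 0:
            raise ParameterError("all size parameters must be positive")
        if not 0.0 <= self.envelope_motion_corr <= 1.0:
            raise ParameterError("envelope_motion_corr must be in [0, 1]")


def _rectified_slow_noise(rng: np.random.Generator, n: int, rate: float,
                          cutoff: float = 8.0) -> np.ndarray:
    """Nonnegative slow signal: |low-passed white noise|, unit variance-ish."""
    sos = signal.butter(4, cutoff, btype="low", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    x = np.abs(x)
    return x / x.std()


def _gen_viseme_sequence(rng: np.random.Generator, duration: float,
                         n_categories: int) -> VisemeSequence:
    """Non-overlapping intervals: durations ~ U(60, 300) ms, gaps ~ U(0, 100) ms."""
    weights = VISEME_WEIGHTS[:n_categories]
    if n_categories > VISEME_WEIGHTS.size:
        weights = np.concatenate([VISEME_WEIGHTS,
                                  np.ones(n_categories - VISEME_WEIGHTS.size)])
    p = weights / weights.sum()
    intervals = []
    t = float(rng.uniform(0.0, 0.1))
    while True:
        dur = float(rng.uniform(0.060, 0.300))
        if t + dur > duration:
            break
        vid = int(rng.choice(n_categories, p=p)) + 1
        intervals.append((vid, t, t + dur))
        t += dur + float(rng.uniform(0.0, 0.100))
    return VisemeSequence(intervals)


def gen_stimuli(cfg: SimConfig) -> tuple[list[dict[str, StimulusFeature]], list[VisemeSequence]]:
    """Per-trial E, M and V stimulus features plus the viseme sequences.

    E is rectified low-passed (<= 8 Hz) noise; M mixes E with an independent
    copy, ``M = a*E' + sqrt(1-a^2)*E2'`` (primes = standardized), so the
    population correlation of M with E equals ``cfg.envelope_motion_corr``
    while M stays nonnegative; V is the binary indicator of a generated
    viseme sequence (no timing shift — the generator works directly at the
    EEG rate).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    n = round(cfg.duration * cfg.rate)
    alpha = cfg.envelope_motion_corr
    features, sequences = [], []
    for _ in range(cfg.n_trials):
        env = _rectified_slow_noise(rng, n, cfg.rate)
        other = _rectified_slow_noise(rng, n, cfg.rate)
        motion = alpha * env + np.sqrt(1.0 - alpha**2) * other
        seq = _gen_viseme_sequence(rng, cfg.duration, cfg.n_visemes)
        v = visemes_to_feature(seq, cfg.duration, cfg.rate,
                               n_categories=cfg.n_visemes, shift=0.0)
        features.append({
            "E": StimulusFeature(env[:, None], cfg.rate, ["envelope"]),
            "M": StimulusFeature(motion[:, None], cfg.rate, ["motion"]),
            "V": v,
        })
        sequences.append(seq)
    return features, sequences


def _dog_kernel(lags_s: np.ndarray, t_pos: float, t_neg: float,
                width: float = 0.030) -> np.ndarray:
    """Difference-of-Gaussians kernel: positive peak then negative trough."""
    pos = np.exp(-0.5 * ((lags_s - t_pos) / width) ** 2)
    neg = np.exp(-0.5 * ((lags_s - t_neg) / width) ** 2)
    return pos - 0.8 * neg


def gen_ground_truth(cfg: SimConfig, window: LagWindow | None = None) -> TRFModel:
    """Known TRF tensor used to synthesize EEG.

    Each feature gets a difference-of-Gaussians kernel with a positive peak
    drawn in 125-140 ms and a negative trough in 210-235 ms — the P1/N1-like
    morphology typical of visual responses — scaled per channel by a smooth
    unimodal gain profile (largest over a contiguous "occipital-like" block
    of channels).  Viseme columns share one kernel shape per channel, scaled
    by category-specific amplitudes drawn in U(0.2, 1.8) (viseme TRF weights
    in real recordings differ by factors of several across categories); with
    ``cfg.equal_viseme_amplitudes`` all categories get amplitude 1, making
    the viseme response depend on timing only (the randomization control's
    null case).
    """
    if window is None:
        window = LagWindow(0.030, 0.380, cfg.rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    lags = window.lags_s
    n_feat = 2 + cfg.n_visemes

    # smooth unimodal channel gain, peak at 3/4 of the montage
    c = np.arange(cfg.n_channels)
    c0 = 0.75 * cfg.n_channels
    gains = 0.2 + 0.8 * np.exp(-0.5 * ((c - c0) / (cfg.n_channels / 6.0)) ** 2)
    gains *= rng.uniform(0.9, 1.1, size=cfg.n_channels)

    weights = np.zeros((window.n_lags, n_feat, cfg.n_channels))
    # envelope and motion kernels: independent latency draws
    for f in range(2):
        t_pos = rng.uniform(0.125, 0.140)
        t_neg = rng.uniform(0.210, 0.235)
        weights[:, f, :] = np.outer(_dog_kernel(lags, t_pos, t_neg), gains)
    # viseme kernels: one shared shape, category-specific amplitudes
    t_pos = rng.uniform(0.125, 0.140)
    t_neg = rng.uniform(0.210, 0.235)
    base = _dog_kernel(lags, t_pos, t_neg)
    if cfg.equal_viseme_amplitudes:
        amps = np.ones(cfg.n_visemes)
    else:
        amps = rng.uniform(0.2, 1.8, size=cfg.n_visemes)
    for k in range(cfg.n_visemes):
        weights[:, 2 + k, :] = amps[k] * np.outer(base, gains)

    labels = ["envelope", "motion"] + [f"v{k:02d}" for k in range(1, cfg.n_visemes + 1)]
    names = [f"ch{j + 1:03d}" for j in range(cfg.n_channels)]
    return TRFModel(weights, window, 0.0, labels, names)


def gen_eeg(
    stimuli: list[StimulusFeature],
    truth: TRFModel,
    snr_db: float,
    seed: int,
) -> list[EEGRecording]:
    """Forward-model EEG: convolution with the true TRF plus band-limited noise.

    Noise is Gaussian, band-limited to the 0.3-15 Hz analysis band, and
    scaled per channel so the sample power ratio of the convolutional signal
    to the noise matches ``snr_db`` exactly (``snr_db = inf`` disables
    noise).  Channels whose signal is identically zero receive unit-scale
    noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    sos = signal.butter(3, [0.3, 15.0], btype="bandpass",
                        fs=stimuli[0].rate, output="sos")
    out = []
    for stim in stimuli:
        clean = predict(truth, stim)
        if np.isinf(snr_db):
            out.append(clean)
            continue
        noise = signal.sosfiltfilt(sos, rng.standard_normal(clean.values.shape), axis=0)
        sig_rms = clean.values.std(axis=0)
        noise_rms = noise.std(axis=0)
        target = np.where(sig_rms > 0, sig_rms * 10.0 ** (-snr_db / 20.0), 1.0)
        noise = noise * (target / noise_rms)
        out.append(EEGRecording(clean.values + noise, clean.rate,
                                list(clean.channel_names)))
    return out


MODEL_FEATURES = {
    "E": ["E"], "M": ["M"], "V": ["V"],
    "EV": ["E", "V"], "MV": ["M", "V"], "EM": ["E", "M"],
    "EMV": ["E", "M", "V"],
}


@dataclass
class SimSession:
    """One simulated recording session: stimuli, sequences, truth, EEG."""

    cfg: SimConfig
    features: list[dict[str, StimulusFeature]]
    sequences: list[VisemeSequence]
    truth: TRFModel
    eeg: list[EEGRecording] = field(repr=False, default_factory=list)

    def trial_set(self, model: str = "EMV", subject_id: str = "sim") -> TrialSet:
        """Stimulus/EEG trial pairs for a named model (E, M, V, EV, MV, EM, EMV)."""
        if model not in MODEL_FEATURES:
            raise ParameterError(
                f"unknown model {model!r}; expected one of {sorted(MODEL_FEATURES)}"
            )
        parts = MODEL_FEATURES[model]
        trials = []
        for feats, eeg in zip(self.features, self.eeg):
            stim = combine_features([feats[p] for p in parts])
            trials.append((stim, eeg))
        return TrialSet(trials, subject_id=subject_id)


def simulate_session(cfg: SimConfig, window: LagWindow | None = None) -> SimSession:
    """Generate a full session: stimuli, ground-truth TRF, and noisy EEG."""
    if window is None:
        window = LagWindow(0.030, 0.380, cfg.rate)
    features, sequences = gen_stimuli(cfg)
    truth = gen_ground_truth(cfg, window)
    emv = [combine_features([f["E"], f["M"], f["V"]]) for f in features]
    eeg = gen_eeg(emv, truth, cfg.snr_db, cfg.seed)
    return SimSession(cfg, features, sequences, truth, eeg)
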