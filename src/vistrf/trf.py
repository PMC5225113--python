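"""Temporal response function (TRF) estimation and forward prediction.

The forward (encoding) model treats the EEG at channel *n* as a convolution
of the stimulus feature(s) with an unknown channel-specific kernel plus a
residual::

    r(t, n) = sum_tau  w(tau, n) s(t - tau)  +  eps(t, n)

with lags tau restricted to a window [t_min, t_max] (e.g. 30-380 ms).
Stacking lagged copies of the stimulus into a design matrix S turns kernel
estimation into ridge regression::

    w = (S'S + lambda I)^-1 S'r

where lambda controls shrinkage of the kernel weights.  ``lag_matrix``
builds S, ``fit_trf`` solves for w, ``predict`` applies Eq. (S w) forward,
and ``pearson_by_channel`` scores predictions against recorded EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .types import (
    EEGRecording,
    InputError,
    NumericalError,
    ParameterError,
    StimulusFeature,
)

__all__ = [
    "LagWindow",
    "LaggedDesign",
    "TRFModel",
    "lag_matrix",
    "fit_trf",
    "average_trfs",
    "predict",
    "pearson_by_channel",
]


@dataclass(frozen=True)
class LagWindow:
    """Stimulus-to-response lag range in seconds at a given sampling rate.

    Lags are quantized to samples by rounding ``t * rate`` to the nearest
    integer; the window spans ``round(t_min*rate) .. round(t_max*rate)``
    inclusive.  The default analysis window is 30-380 ms; a broad inspection
    window (e.g. -200..500 ms) is useful for locating response components.
    """

    t_min: float = 0.030
    t_max: float = 0.380
    rate: float = 128.0

    def __post_init__(self):
        if not self.t_min < self.t_max:
            raise ParameterError("t_min must be < t_max")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")

    @property
    def lag_samples(self) -> np.ndarray:
        """Integer lags in samples, ascending (negative = response leads)."""
        lo = round(self.t_min * self.rate)
        hi = round(self.t_max * self.rate)
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return self.lag_samples.size

    @property
    def lags_s(self) -> np.ndarray:
        return self.lag_samples / self.rate


@dataclass
class LaggedDesign:
    """Time x (features * lags) design matrix S.

    Columns are ordered feature-block-major: for feature *f* with L lags the
    block occupies columns ``f*L .. f*L + L - 1``, lags ascending within the
    block.  Rows where ``t - tau`` falls outside the trial are zero-padded,
    so the design has exactly as many rows as the stimulus.
    """

    matrix: np.ndarray
    window: LagWindow
    feature_labels: list[str] = field(default_factory=list)


@dataclass
class TRFModel:
    """Estimated TRF weights: a (lag, feature, channel) tensor."""

    weights: np.ndarray  # (n_lags, n_features, n_channels)
    window: LagWindow
    lam: float
    feature_labels: list[str]
    channel_names: list[str]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise InputError("weights must be (lag, feature, channel)")
        if not np.all(np.isfinite(self.weights)):
            raise InputError("weights contain non-finite values")
        L, F, C = self.weights.shape
        if L != self.window.n_lags:
            raise InputError(f"{L} lag rows but window has {self.window.n_lags} lags")
        if F != len(self.feature_labels) or C != len(self.channel_names):
            raise InputError("weight tensor shape inconsistent with labels")

    def flat_weights(self) -> np.ndarray:
        """Weights as the (features*lags, channels) matrix of the design layout."""
        L, F, C = self.weights.shape
        return self.weights.transpose(1, 0, 2).reshape(L * F, C)


def lag_matrix(stim: StimulusFeature, window: LagWindow) -> LaggedDesign:
    """Build the lagged design matrix S from a stimulus feature matrix.

    Row ``t``, column ``(f, tau)`` holds ``s_f(t - tau)``, zero where the
    index falls outside the trial.
    """
    if stim.n_samples == 0:
        raise InputError("stimulus is empty")
    if stim.rate != window.rate:
        raise InputError(
            f"stimulus rate {stim.rate} != window rate {window.rate}"
        )
    n, F = stim.values.shape
    lags = window.lag_samples
    L = lags.size
    M = np.zeros((n, F * L))
    for f in range(F):
        col = stim.values[:, f]
        for j, tau in enumerate(lags):
            dest = M[:, f * L + j]
            if tau > 0:
                dest[tau:] = col[:-tau]
            elif tau < 0:
                dest[:tau] = col[-tau:]
            else:
                dest[:] = col
    return LaggedDesign(M, window, list(stim.labels))


def fit_trf(
    stim: StimulusFeature,
    eeg: EEGRecording,
    window: LagWindow,
    lam: float,
) -> TRFModel:
    """Ridge-regression TRF estimate  w = (S'S + lam I)^-1 S'r.

    The penalty is a plain identity on the full lagged covariance (no
    intercept, no penalty exemptions).  Solved per channel with a symmetric
    positive-definite factorization; a least-squares fallback covers
    ill-conditioned systems, and a singular system at ``lam = 0`` raises
    :class:`NumericalError` advising a positive ridge.
    """
    if lam < 0:
        raise ParameterError("ridge parameter lam must be >= 0")
    if stim.n_samples != eeg.n_samples:
        raise InputError(
            f"stimulus has {stim.n_samples} samples but EEG has {eeg.n_samples}"
        )
    if stim.rate != eeg.rate:
        raise InputError("stimulus and EEG rates differ")

    design = lag_matrix(stim, window)
    S = design.matrix
    cov = S.T @ S
    cov[np.diag_indices_from(cov)] += lam
    xcov = S.T @ eeg.values
    flat = _solve_spd(cov, xcov, lam)
    L, F = window.n_lags, stim.n_features
    weights = flat.reshape(F, L, eeg.n_channels).transpose(1, 0, 2)
    return TRFModel(weights, window, lam, list(stim.labels), list(eeg.channel_names))


def _solve_spd(cov: np.ndarray, xcov: np.ndarray, lam: float) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(cov)
        return linalg.cho_solve((c, low), xcov)
    except linalg.LinAlgError:
        if lam == 0:
            raise NumericalError(
                "the lagged covariance is singular at lam = 0; "
                "set lam > 0 to regularize"
            ) from None
        return linalg.lstsq(cov, xcov)[0]


def average_trfs(models: list[TRFModel]) -> TRFModel:
    """Element-wise mean of TRF weight tensors (same window, labels, lam)."""
    if not models:
        raise InputError("no models to average")
    first = models[0]
    for m in models[1:]:
        if (
            m.weights.shape != first.weights.shape
            or m.window != first.window
            or m.feature_labels != first.feature_labels
            or m.lam != first.lam
        ):
            raise InputError("models differ in window, labels, lam or shape")
    weights = np.mean([m.weights for m in models], axis=0)
    return TRFModel(
        weights, first.window, first.lam, list(first.feature_labels),
        list(first.channel_names),
    )


def predict(model: TRFModel, stim: StimulusFeature) -> EEGRecording:
    """Forward prediction: the lagged design times the TRF weights."""
    if list(stim.labels) != list(model.feature_labels):
        raise InputError(
            f"stimulus labels {stim.labels} do not match model features "
            f"{model.feature_labels}"
        )
    design = lag_matrix(stim, model.window)
    values = design.matrix @ model.flat_weights()
    return EEGRecording(values, stim.rate, list(model.channel_names))


def pearson_by_channel(pred: EEGRecording, actual: EEGRecording) -> np.ndarray:
    """Pearson r between predicted and recorded EEG, per channel.

    Channels where either input has zero variance yield NaN (flagged
    undefined; downstream means exclude them).
    """
    if pred.values.shape != actual.values.shape:
        raise InputError(
            f"shape mismatch: {pred.values.shape} vs {actual.values.shape}"
        )
    x = pred.values - pred.values.mean(axis=0)
    y = actual.values - actual.values.mean(axis=0)
    sx = np.sqrt((x * x).sum(axis=0))
    sy = np.sqrt((y * y).sum(axis=0))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * y).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)
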