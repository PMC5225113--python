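"""Leave-one-out cross-validated EEG prediction with ridge-parameter search.

For a recording session of N trials (stimulus/EEG pairs), each fold fits one
TRF per training trial, averages the N-1 single-trial TRFs, predicts the
held-out trial's EEG, and records per-channel Pearson r.  The ridge
parameter lambda is selected per session (not per fold) as the value on a
log-spaced grid (2^-20 .. 2^20 by default) maximizing the mean prediction
accuracy over trials and a chosen electrode subset, optionally followed by a
refinement pass on a constricted grid around the winner.  The same lag
window is used for every model, including feature combinations, so model
comparisons are not confounded by window choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .trf import LagWindow, lag_matrix
from .trf import _solve_spd
from .types import (
    EEGRecording,
    EvaluationError,
    InputError,
    ParameterError,
    StimulusFeature,
)

__all__ = [
    "TrialSet",
    "PredictionResult",
    "ModelScore",
    "loo_predict",
    "lambda_grid",
    "optimize_lambda",
    "score_model",
]


@dataclass
class TrialSet:
    """Stimulus/EEG pairs from one recording session (one subject)."""

    trials: list[tuple[StimulusFeature, EEGRecording]]
    subject_id: str = ""

    def __post_init__(self):
        if len(self.trials) < 2:
            raise InputError("a TrialSet needs at least 2 trials")
        rates = {s.rate for s, _ in self.trials} | {e.rate for _, e in self.trials}
        if len(rates) != 1:
            raise InputError(f"trials disagree in sampling rate: {sorted(rates)}")
        names = {tuple(e.channel_names) for _, e in self.trials}
        if len(names) != 1:
            raise InputError("trials disagree in channel set")
        labels = {tuple(s.labels) for s, _ in self.trials}
        if len(labels) != 1:
            raise InputError("trials disagree in stimulus feature labels")
        for i, (s, e) in enumerate(self.trials):
            if s.n_samples != e.n_samples:
                raise InputError(f"trial {i}: stimulus/EEG length mismatch")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def channel_names(self) -> list[str]:
        return list(self.trials[0][1].channel_names)

    @property
    def feature_labels(self) -> list[str]:
        return list(self.trials[0][0].labels)


@dataclass
class PredictionResult:
    """Per-trial, per-channel prediction accuracies for one model."""

    per_trial_r: np.ndarray  # (n_trials, n_channels), NaN = undefined
    lam: float
    electrode_set: list[int] | None
    model_label: str = ""
    window: LagWindow = field(default_factory=LagWindow)

    def __post_init__(self):
        self.per_trial_r = np.asarray(self.per_trial_r, dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (np.abs(self.per_trial_r) > 1 + 1e-9) & ~np.isnan(self.per_trial_r)
        if bad.any():
            raise InputError("correlations outside [-1, 1]")


class ModelScore(NamedTuple):
    """Session-level mean r and the per-trial means behind it."""

    mean: float
    per_trial: np.ndarray


def _columnwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    denom = np.sqrt((x * x).sum(axis=0) * (y * y).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * y).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


class _LOOEngine:
    """Caches per-trial designs and covariances so a lambda grid reuses them."""

    def __init__(self, data: TrialSet, window: LagWindow):
        self.data = data
        self.window = window
        self.designs = [lag_matrix(stim, window).matrix for stim, _ in data.trials]
        self.covs = [S.T @ S for S in self.designs]
        self.xcovs = [S.T @ eeg.values for S, (_, eeg) in zip(self.designs, data.trials)]

    def per_trial_r(self, lam: float) -> np.ndarray:
        if lam < 0:
            raise ParameterError("ridge parameter lam must be >= 0")
        n = self.data.n_trials
        flats = []
        for cov, xcov in zip(self.covs, self.xcovs):
            cov_l = cov.copy()
            cov_l[np.diag_indices_from(cov_l)] += lam
            flats.append(_solve_spd(cov_l, xcov, lam))
        total = np.sum(flats, axis=0)
        rows = []
        for i, (_, eeg) in enumerate(self.data.trials):
            w_avg = (total - flats[i]) / (n - 1)
            pred = self.designs[i] @ w_avg
            rows.append(_columnwise_pearson(pred, eeg.values))
        return np.vstack(rows)

    def predictions(self, lam: float) -> list[EEGRecording]:
        """Held-out predicted EEG per fold (used by the chance-level control)."""
        n = self.data.n_trials
        flats = []
        for cov, xcov in zip(self.covs, self.xcovs):
            cov_l = cov.copy()
            cov_l[np.diag_indices_from(cov_l)] += lam
            flats.append(_solve_spd(cov_l, xcov, lam))
        total = np.sum(flats, axis=0)
        out = []
        for i in range(n):
            w_avg = (total - flats[i]) / (n - 1)
            pred = self.designs[i] @ w_avg
            out.append(
                EEGRecording(pred, self.data.trials[i][1].rate, self.data.channel_names)
            )
        return out


def loo_predict(
    data: TrialSet,
    window: LagWindow,
    lam: float,
    electrode_set: Sequence[int] | None = None,
    model_label: str = "",
) -> PredictionResult:
    """Leave-one-out cross-validated prediction at a fixed ridge parameter.

    For each held-out trial, single-trial TRFs are fit on the remaining
    trials, averaged, and used to predict the held-out EEG; the result holds
    the trial x channel matrix of Pearson r values.
    """
    engine = _LOOEngine(data, window)
    r = engine.per_trial_r(lam)
    return PredictionResult(r, lam, _norm_electrodes(electrode_set, r.shape[1]),
                            model_label, window)


def lambda_grid(exp_min: int = -20, exp_max: int = 20, exp_step: int = 4) -> list[float]:
    """Log-spaced ridge grid: 2^e for e = exp_min, exp_min+step, ..., exp_max."""
    if exp_min > exp_max:
        raise ParameterError("exp_min must be <= exp_max")
    if exp_step < 1:
        raise ParameterError("exp_step must be >= 1")
    return [float(2.0**e) for e in range(exp_min, exp_max + 1, exp_step)]


def _norm_electrodes(electrode_set, n_channels: int) -> list[int] | None:
    if electrode_set is None:
        return None
    idx = [int(i) for i in electrode_set]
    if not idx:
        raise ParameterError("electrode set is empty")
    if any(i < 0 or i >= n_channels for i in idx):
        raise ParameterError(f"electrode index out of range 0..{n_channels - 1}")
    return idx


def _mean_r(per_trial_r: np.ndarray, electrode_set: list[int] | None) -> float:
    sub = per_trial_r if electrode_set is None else per_trial_r[:, electrode_set]
    if np.isnan(sub).all():
        return np.nan
    return float(np.nanmean(sub))


def optimize_lambda(
    data: TrialSet,
    window: LagWindow,
    grid: Sequence[float],
    electrode_set: Sequence[int] | None = None,
    refine: bool = False,
    model_label: str = "",
) -> tuple[float, PredictionResult]:
    """Grid-search the ridge parameter by cross-validated mean accuracy.

    Runs :func:`loo_predict` at every grid value and returns the lambda with
    the highest mean r over trials and the electrode subset (ties go to the
    smaller lambda).  With ``refine=True`` a second pass evaluates a
    constricted grid of +/-2 exponent units (step 1) around the winner.
    """
    if not grid:
        raise ParameterError("lambda grid is empty")
    n_channels = data.trials[0][1].n_channels
    electrodes = _norm_electrodes(electrode_set, n_channels)
    engine = _LOOEngine(data, window)

    def search(values: Sequence[float], best=None):
        for lam in sorted(values):
            r = engine.per_trial_r(lam)
            score = _mean_r(r, electrodes)
            if best is None or (not np.isnan(score) and score > best[1]):
                best = (lam, score, r)
        return best

    best = search(grid)
    if refine:
        center = np.log2(best[0])
        fine = [float(2.0 ** (center + d)) for d in range(-2, 3)]
        best = search(fine, best)

    lam, _, r = best
    return lam, PredictionResult(r, lam, electrodes, model_label, window)


def score_model(
    result: PredictionResult, electrode_set: Sequence[int] | None = None
) -> ModelScore:
    """Mean prediction accuracy over trials and an electrode subset.

    Undefined (NaN) entries are excluded.  Returns the grand mean together
    with per-trial means, which feed paired statistics across models.
    """
    r = result.per_trial_r
    electrodes = _norm_electrodes(
        electrode_set if electrode_set is not None else result.electrode_set,
        r.shape[1],
    )
    sub = r if electrodes is None else r[:, electrodes]
    if np.isnan(sub).all():
        raise EvaluationError("every prediction accuracy is undefined")
    with np.errstate(invalid="ignore"):
        per_trial = np.nanmean(sub, axis=1)
    return ModelScore(float(np.nanmean(sub)), per_trial)
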