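"""Chance-level estimation, paired model comparisons, and the viseme control.

Three inferential tools accompany the cross-validated prediction engine:

* :func:`chance_level` — an empirical null for prediction accuracy: each
  held-out prediction is correlated against randomly chosen *mismatched*
  recorded trials, the per-prediction averages are pooled across models, and
  a high percentile (95th by default) of that pool is the chance threshold.
* :func:`paired_ttest` — classical two-tailed paired t-test for comparing
  model scores paired by subject (or by trial within a session).
* :func:`randomization_control` — re-runs the cross-validation after
  shuffling viseme identities within their exact time intervals.  A drop in
  accuracy shows that the viseme model's performance reflects *which*
  viseme occurs, not merely the timing of visual speech events.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .crossval import (
    ModelScore,
    PredictionResult,
    TrialSet,
    _LOOEngine,
    _columnwise_pearson,
    _norm_electrodes,
    loo_predict,
    score_model,
)
from .features import randomize_visemes, visemes_to_feature
from .trf import LagWindow
from .types import (
    InputError,
    ParameterError,
    StimulusFeature,
    VisemeSequence,
)

__all__ = [
    "chance_level",
    "paired_ttest",
    "TTestResult",
    "randomization_control",
    "ControlResult",
]


def chance_level(
    data: TrialSet | Sequence[TrialSet],
    results: Sequence[PredictionResult],
    n_mismatch: int = 5,
    pct: float = 95.0,
    seed: int = 0,
) -> float:
    """Empirical chance threshold for mean prediction accuracy.

    For every model result, the leave-one-out predictions are recomputed at
    that model's ridge parameter; each prediction is then scored (mean r over
    the result's electrode set) against ``n_mismatch`` recorded trials drawn
    without replacement from the non-matching trials, truncating to the
    shorter length when lengths differ.  The per-prediction mismatch averages
    are pooled over all models and the ``pct``-th percentile is returned.

    ``data`` may be a single :class:`TrialSet` (shared by all results) or a
    sequence aligned with ``results`` — combined models carry different
    stimuli, so each result may need its own trial set.
    """
    if not results:
        raise InputError("no prediction results supplied")
    if isinstance(data, TrialSet):
        datasets = [data] * len(results)
    else:
        datasets = list(data)
        if len(datasets) != len(results):
            raise InputError("one TrialSet per PredictionResult required")
    if not 0 < pct < 100:
        raise ParameterError("percentile must be in (0, 100)")
    n_trials = datasets[0].n_trials
    if not 1 <= n_mismatch < n_trials:
        raise ParameterError(
            f"n_mismatch must be in 1..{n_trials - 1}, got {n_mismatch}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    pooled = []
    for dset, result in zip(datasets, results):
        engine = _LOOEngine(dset, result.window)
        preds = engine.predictions(result.lam)
        electrodes = _norm_electrodes(result.electrode_set, preds[0].n_channels)
        for i, pred in enumerate(preds):
            others = [j for j in range(dset.n_trials) if j != i]
            chosen = rng.choice(others, size=n_mismatch, replace=False)
            vals = []
            for j in chosen:
                actual = dset.trials[j][1].values
                n = min(pred.n_samples, actual.shape[0])
                r = _columnwise_pearson(pred.values[:n], actual[:n])
                sub = r if electrodes is None else r[electrodes]
                vals.append(np.nanmean(sub))
            pooled.append(float(np.mean(vals)))
    return float(np.percentile(pooled, pct))


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed paired t-test on per-subject (or per-trial) score pairs.

    Returns the t statistic, two-tailed p from the t distribution with
    ``n - 1`` degrees of freedom, and a ``degenerate`` flag when the paired
    differences have zero variance (identical inputs give t = 0, p = 1; a
    constant nonzero difference gives an infinite t).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("inputs must be equal-length 1-D score vectors")
    if a.size < 2:
        raise InputError("need at least 2 pairs")
    d = a - b
    df = d.size - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TTestResult(0.0, 1.0, df, degenerate=True)
        return TTestResult(float(np.sign(d.mean()) * np.inf), 0.0, df, degenerate=True)
    res = sps.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue), df)


class ControlResult(NamedTuple):
    true_score: float
    shuffled_scores: np.ndarray
    true_result: PredictionResult


def randomization_control(
    data: TrialSet,
    sequences: Sequence[VisemeSequence],
    window: LagWindow,
    lam: float,
    n_shuffles: int = 10,
    seed: int = 0,
    electrode_set: Sequence[int] | None = None,
    shift: float = 0.0,
    shift_offsets: bool = True,
) -> ControlResult:
    """Viseme-identity randomization control.

    Recomputes the leave-one-out prediction score after replacing, per trial,
    the viseme indicator columns with ones rebuilt from a label-shuffled
    sequence (onset/offset time points preserved exactly; per-shuffle,
    per-trial seeds derived from ``seed``).  Returns the true score and the
    list of shuffled scores: genuine category-specific encoding shows
    ``true > shuffled``, while timing-only encoding shows no separation.

    ``shift``/``shift_offsets`` must match how the viseme feature in ``data``
    was built so the shuffled indicator is constructed identically.
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    if len(sequences) != data.n_trials:
        raise InputError("one VisemeSequence per trial required")

    labels = data.feature_labels
    vis_cols = [j for j, lab in enumerate(labels) if lab.startswith("v") and lab[1:].isdigit()]
    if not vis_cols:
        raise InputError("stimuli carry no viseme columns (labels v01, v02, ...)")
    n_categories = len(vis_cols)

    true_result = loo_predict(data, window, lam, electrode_set, "V-true")
    true_score = score_model(true_result).mean

    rate = data.trials[0][0].rate
    ss = np.random.SeedSequence([seed, 505])
    shuffle_seeds = ss.generate_state(n_shuffles * data.n_trials) % (2**31)
    shuffled_scores = np.empty(n_shuffles)
    for s in range(n_shuffles):
        trials = []
        for i, ((stim, eeg), seq) in enumerate(zip(data.trials, sequences)):
            shuf_seq = randomize_visemes(seq, int(shuffle_seeds[s * data.n_trials + i]))
            duration = stim.n_samples / rate
            v = visemes_to_feature(shuf_seq, duration, rate, n_categories,
                                   shift=shift, shift_offsets=shift_offsets)
            values = stim.values.copy()
            values[:, vis_cols] = v.values
            trials.append((StimulusFeature(values, rate, list(labels)), eeg))
        shuf_data = TrialSet(trials, subject_id=data.subject_id)
        result = loo_predict(shuf_data, window, lam, electrode_set, f"V-shuffle{s}")
        shuffled_scores[s] = score_model(result).mean

    return ControlResult(true_score, shuffled_scores, true_result)
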