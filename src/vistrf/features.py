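"""Stimulus representations of continuous visual speech.

Three feature streams are built from raw media and phoneme alignments, each
sampled at the EEG rate (128 Hz by default):

* **E — acoustic envelope.** The broadband amplitude envelope of the speech
  audio, computed as the mean of narrowband Hilbert envelopes over a
  gammatone filterbank with log-spaced center frequencies.  During silent
  lipreading the envelope acts as a proxy for speech-related mouth motion,
  with which it is known to be correlated.
* **M — motion.** The global frame-to-frame motion flow of the video: per
  frame pair, block-matching motion vectors are estimated with the Adaptive
  Rood Pattern Search (ARPS) algorithm and their Euclidean lengths summed.
* **V — visemes.** A multivariate binary indicator of viseme occupancy,
  obtained by collapsing a phoneme alignment onto viseme categories (groups
  of phonemes that are visually indistinguishable on the lips, e.g.
  /b/, /p/, /m/) and marking each category's intervals, optionally shifted
  earlier to compensate for the audio-visual timing offset.

Concatenating streams column-wise yields the combined models (EV, MV, EM,
EMV) used by the encoding analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import (
    AudioSignal,
    FrameStack,
    InputError,
    MotionField,
    ParameterError,
    PhonemeAlignment,
    StimulusFeature,
    VisemeMap,
    VisemeSequence,
)

__all__ = [
    "compute_envelope",
    "arps_match",
    "full_search_match",
    "compute_motion",
    "phonemes_to_visemes",
    "visemes_to_feature",
    "combine_features",
    "randomize_visemes",
]

#: Default viseme-model time shift in seconds: viseme timings derive from the
#: acoustic alignment, and visible articulation leads the acoustics by roughly
#: this much, so intervals are translated 150 ms earlier by default.
VISEME_SHIFT_S = 0.150


# --------------------------------------------------------------------------
# envelope (E)
# --------------------------------------------------------------------------

def _resample_to(x: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    """Polyphase (anti-aliased) resampling of a 1-D signal."""
    if in_rate == out_rate:
        return x.copy()
    from fractions import Fraction

    frac = Fraction(out_rate / in_rate).limit_denominator(10**6)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def compute_envelope(
    audio: AudioSignal,
    n_bands: int = 256,
    f_min: float = 80.0,
    f_max: float = 3000.0,
    out_rate: float = 128.0,
) -> StimulusFeature:
    """Broadband amplitude envelope of a speech waveform.

    The waveform is decomposed by a bank of 4th-order gammatone filters whose
    center frequencies are logarithmically spaced on ``[f_min, f_max]``.  The
    magnitude of the analytic signal (Hilbert envelope) is taken per band,
    averaged over bands, and resampled to ``out_rate``.

    Returns a single nonnegative feature column labeled ``"envelope"``.
    """
    if audio.samples.size == 0:
        raise InputError("audio is empty")
    if n_bands < 1:
        raise ParameterError("n_bands must be >= 1")
    if not 0 < f_min < f_max:
        raise ParameterError("need 0 < f_min < f_max")
    if f_max >= audio.rate / 2:
        raise ParameterError(
            f"f_max = {f_max} Hz must be below the Nyquist rate {audio.rate / 2} Hz"
        )

    centers = np.geomspace(f_min, f_max, n_bands)
    nfft = int(2 ** np.ceil(np.log2(max(audio.samples.size, 2))))
    env = np.zeros(audio.samples.size)
    for fc in centers:
        b, a = signal.gammatone(fc, "iir", fs=audio.rate)
        band = signal.lfilter(b, a, audio.samples)
        analytic = signal.hilbert(band, N=nfft)[: audio.samples.size]
        env += np.abs(analytic)
    env /= n_bands

    out = _resample_to(env, audio.rate, out_rate)
    np.maximum(out, 0.0, out=out)  # polyphase ringing can dip below zero
    return StimulusFeature(out[:, None], out_rate, ["envelope"])


# --------------------------------------------------------------------------
# motion (M)
# --------------------------------------------------------------------------

def _mad(ref_block: np.ndarray, target: np.ndarray, y: int, x: int, bs: int) -> float:
    return float(np.mean(np.abs(ref_block - target[y : y + bs, x : x + bs])))


class _BlockSearch:
    """Shared candidate evaluation with the package-wide tie-break rule.

    A candidate displacement beats the incumbent if its cost is strictly
    lower, or costs are equal and its squared magnitude is smaller; remaining
    ties keep the earlier-evaluated candidate (row-major candidate order).
    """

    def __init__(self, ref_block, target, y0, x0, bs, search_range):
        self.ref_block = ref_block
        self.target = target
        self.y0, self.x0, self.bs = y0, x0, bs
        self.r = search_range
        self.rows, self.cols = target.shape
        self.seen: dict[tuple[int, int], float] = {}
        self.best: tuple[int, int] | None = None
        self.best_cost = np.inf

    def feasible(self, dy: int, dx: int) -> bool:
        if max(abs(dy), abs(dx)) > self.r:
            return False
        y, x = self.y0 + dy, self.x0 + dx
        return 0 <= y <= self.rows - self.bs and 0 <= x <= self.cols - self.bs

    def try_candidate(self, dy: int, dx: int) -> None:
        if (dy, dx) in self.seen or not self.feasible(dy, dx):
            return
        cost = _mad(self.ref_block, self.target, self.y0 + dy, self.x0 + dx, self.bs)
        self.seen[(dy, dx)] = cost
        if self.best is None:
            self.best, self.best_cost = (dy, dx), cost
            return
        mag, best_mag = dy * dy + dx * dx, sum(v * v for v in self.best)
        if cost < self.best_cost or (cost == self.best_cost and mag < best_mag):
            self.best, self.best_cost = (dy, dx), cost


def _block_grid(shape: tuple[int, int], block_size: int):
    rows, cols = shape
    return rows // block_size, cols // block_size


def arps_match(
    ref: np.ndarray,
    target: np.ndarray,
    block_size: int = 16,
    search_range: int = 7,
) -> MotionField:
    """Adaptive Rood Pattern Search block-matching motion estimation.

    For each non-overlapping ``block_size`` x ``block_size`` block of ``ref``
    (blocks fully inside the frame only), finds the displacement within
    ``+/- search_range`` pixels that minimizes the mean absolute difference
    (MAD) against ``target``.  The initial rood arm length is set from the
    left neighbor's motion vector (the adaptive prediction), followed by
    unit-rood refinement until the center wins.  Ties go to the smaller
    displacement magnitude, then to the earlier candidate.
    """
    ref = np.asarray(ref, dtype=float)
    target = np.asarray(target, dtype=float)
    if ref.shape != target.shape:
        raise InputError("ref and target frames must have the same shape")
    if block_size > min(ref.shape):
        raise ParameterError(
            f"block_size {block_size} exceeds frame dims {ref.shape}"
        )

    n_by, n_bx = _block_grid(ref.shape, block_size)
    vectors = np.zeros((n_by, n_bx, 2))

    for by in range(n_by):
        for bx in range(n_bx):
            y0, x0 = by * block_size, bx * block_size
            ref_block = ref[y0 : y0 + block_size, x0 : x0 + block_size]
            search = _BlockSearch(ref_block, target, y0, x0, block_size, search_range)

            # stage 1: adaptive rood sized by the predicted (left-neighbor) vector
            if bx > 0:
                pdy, pdx = int(vectors[by, bx - 1, 0]), int(vectors[by, bx - 1, 1])
                arm = max(abs(pdy), abs(pdx))
            else:
                pdy = pdx = 0
                arm = 2
            search.try_candidate(0, 0)
            if arm > 0:
                for dy, dx in ((-arm, 0), (arm, 0), (0, -arm), (0, arm)):
                    search.try_candidate(dy, dx)
            search.try_candidate(pdy, pdx)

            # stage 2: unit rood descent until the center is the minimum
            while True:
                cy, cx = search.best
                for dy, dx in ((cy - 1, cx), (cy + 1, cx), (cy, cx - 1), (cy, cx + 1)):
                    search.try_candidate(dy, dx)
                if search.best == (cy, cx):
                    break
            vectors[by, bx] = search.best

    return MotionField(vectors, block_size)


def full_search_match(
    ref: np.ndarray,
    target: np.ndarray,
    block_size: int = 16,
    search_range: int = 7,
) -> MotionField:
    """Exhaustive full-search block matching (reference baseline).

    Enumerates every feasible displacement in the search window per block,
    with the same MAD cost and tie-break rule as :func:`arps_match`.  Slow
    but exact; used to validate the ARPS descent.
    """
    ref = np.asarray(ref, dtype=float)
    target = np.asarray(target, dtype=float)
    if ref.shape != target.shape:
        raise InputError("ref and target frames must have the same shape")
    if block_size > min(ref.shape):
        raise ParameterError(
            f"block_size {block_size} exceeds frame dims {ref.shape}"
        )

    n_by, n_bx = _block_grid(ref.shape, block_size)
    vectors = np.zeros((n_by, n_bx, 2))
    for by in range(n_by):
        for bx in range(n_bx):
            y0, x0 = by * block_size, bx * block_size
            ref_block = ref[y0 : y0 + block_size, x0 : x0 + block_size]
            search = _BlockSearch(ref_block, target, y0, x0, block_size, search_range)
            for dy in range(-search_range, search_range + 1):
                for dx in range(-search_range, search_range + 1):
                    search.try_candidate(dy, dx)
            vectors[by, bx] = search.best
    return MotionField(vectors, block_size)


def compute_motion(
    video: FrameStack,
    block_size: int = 16,
    search_range: int = 7,
    out_rate: float = 128.0,
) -> StimulusFeature:
    """Global motion flow of a video, resampled to the EEG rate.

    For each consecutive frame pair the block motion field is estimated with
    ARPS and the Euclidean lengths of all vectors are summed, giving one
    nonnegative value per frame transition.  The first sample is defined as 0
    so the series has one sample per frame; it is then linearly interpolated
    from the video frame rate to ``out_rate``.
    """
    if video.n_frames < 2:
        raise InputError("need at least 2 frames to estimate motion")

    sums = np.zeros(video.n_frames)
    for t in range(video.n_frames - 1):
        field = arps_match(video.frames[t], video.frames[t + 1], block_size, search_range)
        sums[t + 1] = field.lengths().sum()

    n_out = round(video.duration * out_rate)
    t_in = np.arange(video.n_frames) / video.rate
    t_out = np.arange(n_out) / out_rate
    out = np.interp(t_out, t_in, sums)
    return StimulusFeature(out[:, None], out_rate, ["motion"])


# --------------------------------------------------------------------------
# visemes (V)
# --------------------------------------------------------------------------

def phonemes_to_visemes(alignment: PhonemeAlignment, vmap: VisemeMap) -> VisemeSequence:
    """Collapse a phoneme alignment onto viseme categories.

    Interval boundaries are kept; labels are replaced by viseme ids.  Adjacent
    intervals that land in the same category are *not* merged, so each phoneme
    token remains one viseme occurrence.
    """
    return VisemeSequence([(vmap[label], on, off) for label, on, off in alignment.entries])


def _sample_span(onset: float, offset: float, rate: float) -> tuple[int, int]:
    # half-open [onset, offset) -> samples floor(onset*rate) .. floor(offset*rate)-1;
    # the epsilon guards boundaries that are exact in real arithmetic but sit
    # a few ulps low in floating point
    first = int(np.floor(onset * rate + 1e-9))
    last = int(np.floor(offset * rate + 1e-9)) - 1
    return first, last


def visemes_to_feature(
    seq: VisemeSequence,
    duration: float,
    rate: float = 128.0,
    n_categories: int = 12,
    shift: float = VISEME_SHIFT_S,
    shift_offsets: bool = True,
    onset_impulse: bool = False,
) -> StimulusFeature:
    """Binary time x category indicator matrix for a viseme sequence.

    Each interval is translated ``shift`` seconds earlier (onsets clipped at
    0) to compensate for visible articulation leading the acoustic alignment;
    with ``shift_offsets=False`` only onsets move.  Sample ``i`` covers
    ``[i/rate, (i+1)/rate)`` and an interval ``[a, b)`` activates samples
    ``floor(a*rate) .. floor(b*rate)-1``.  With ``onset_impulse=True`` only
    the onset sample of each interval is marked.
    """
    if shift < 0:
        raise ParameterError("shift must be >= 0")
    n_samples = round(duration * rate)
    values = np.zeros((n_samples, n_categories))
    for vid, on, off in seq.intervals:
        if vid > n_categories:
            raise ParameterError(
                f"viseme id {vid} exceeds n_categories = {n_categories}"
            )
        on_s = max(on - shift, 0.0)
        off_s = max(off - shift, 0.0) if shift_offsets else off
        if off_s <= on_s:
            continue
        first, last = _sample_span(on_s, off_s, rate)
        if onset_impulse:
            last = first
        first = max(first, 0)
        last = min(last, n_samples - 1)
        if last >= first:
            values[first : last + 1, vid - 1] = 1.0
    labels = [f"v{k:02d}" for k in range(1, n_categories + 1)]
    return StimulusFeature(values, rate, labels)


def combine_features(parts: list[StimulusFeature]) -> StimulusFeature:
    """Column-wise concatenation of feature streams (e.g. E + M + V -> EMV)."""
    if not parts:
        raise InputError("no features to combine")
    rows = {p.n_samples for p in parts}
    rates = {p.rate for p in parts}
    if len(rows) != 1 or len(rates) != 1:
        raise InputError(
            f"features disagree in length ({sorted(rows)}) or rate ({sorted(rates)})"
        )
    values = np.hstack([p.values for p in parts])
    labels = [lab for p in parts for lab in p.labels]
    return StimulusFeature(values, parts[0].rate, labels)


def randomize_visemes(seq: VisemeSequence, seed: int) -> VisemeSequence:
    """Permute viseme identities across intervals, keeping all boundaries.

    The onset/offset time points and the multiset of category ids are
    preserved exactly; only the assignment of ids to intervals is shuffled
    (uniformly at random, reproducible from ``seed``).  This is the timing
    control: a model that only tracks visual onset timing scores the same on
    the shuffled sequence, while a model with genuinely category-specific
    responses loses accuracy.
    """
    if not seq.intervals:
        raise InputError("cannot randomize an empty sequence")
    rng = np.random.default_rng(seed)
    ids = np.array(seq.ids())
    shuffled = ids[rng.permutation(ids.size)]
    return VisemeSequence(
        [(int(v), on, off) for v, (_, on, off) in zip(shuffled, seq.intervals)]
    )
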