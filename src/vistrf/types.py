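"""Core containers for stimulus features, EEG and viseme sequences.

All time coordinates are in seconds, sample indexing is 0-based, and labeled
intervals are half-open ``[onset, offset)``.  Sample ``i`` of a signal at rate
``fs`` covers the interval ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class VistrfError(Exception):
    """Base class for all package errors."""


class InputError(VistrfError, ValueError):
    """Malformed or inconsistent input data."""


class ParameterError(VistrfError, ValueError):
    """Invalid parameter value."""


class MappingError(VistrfError, KeyError):
    """A phoneme label has no viseme category."""


class NumericalError(VistrfError, ArithmeticError):
    """A linear solve failed; usually fixable with regularization."""


class EvaluationError(VistrfError, ValueError):
    """A score could not be computed (e.g. every entry undefined)."""


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != ndim:
        raise InputError(f"{name} must be {ndim}-D, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    return a


@dataclass
class AudioSignal:
    """Single-channel audio waveform (arbitrary amplitude units)."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        self.samples = _as_float_array(self.samples, "samples", 1)
        if self.rate <= 0:
            raise ParameterError("audio rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class FrameStack:
    """Grayscale video as a (n_frames, rows, cols) intensity array."""

    frames: np.ndarray
    rate: float = 30.0

    def __post_init__(self):
        self.frames = _as_float_array(self.frames, "frames", 3)
        if self.rate <= 0:
            raise ParameterError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate


@dataclass
class MotionField:
    """Per-block displacement vectors for one frame pair.

    ``vectors`` has shape (n_block_rows, n_block_cols, 2) holding (dy, dx)
    displacements in pixels of each non-overlapping block.
    """

    vectors: np.ndarray
    block_size: int

    def __post_init__(self):
        self.vectors = _as_float_array(self.vectors, "vectors", 3)
        if self.vectors.shape[-1] != 2:
            raise InputError("vectors last axis must hold (dy, dx) pairs")

    def lengths(self) -> np.ndarray:
        """Euclidean length of each block displacement."""
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


@dataclass
class PhonemeAlignment:
    """Time-aligned phoneme labels: sorted, non-overlapping intervals."""

    entries: list[tuple[str, float, float]]

    def __post_init__(self):
        prev_off = -np.inf
        for i, (label, on, off) in enumerate(self.entries):
            if not on < off:
                raise InputError(
                    f"alignment row {i} ({label!r}): onset {on} >= offset {off}"
                )
            if on < prev_off:
                raise InputError(
                    f"alignment row {i} ({label!r}): overlaps previous interval"
                )
            prev_off = off


@dataclass
class VisemeMap:
    """Total mapping from phoneme labels to viseme category ids 1..K."""

    mapping: dict[str, int]

    def __post_init__(self):
        ids = sorted(set(self.mapping.values()))
        if not ids:
            raise InputError("viseme map is empty")
        if ids != list(range(1, ids[-1] + 1)):
            raise InputError(f"viseme ids must be contiguous 1..K, got {ids}")

    @property
    def n_categories(self) -> int:
        return max(self.mapping.values())

    def __getitem__(self, phoneme: str) -> int:
        try:
            return self.mapping[phoneme]
        except KeyError:
            raise MappingError(f"phoneme {phoneme!r} has no viseme mapping") from None


@dataclass
class VisemeSequence:
    """Ordered non-overlapping viseme occurrences: (id, onset_s, offset_s)."""

    intervals: list[tuple[int, float, float]]

    def __post_init__(self):
        prev_off = -np.inf
        for i, (vid, on, off) in enumerate(self.intervals):
            if vid < 1:
                raise InputError(f"interval {i}: viseme id {vid} < 1")
            if not on < off:
                raise InputError(f"interval {i}: onset {on} >= offset {off}")
            if on < prev_off:
                raise InputError(f"interval {i}: overlaps previous interval")
            prev_off = off

    def ids(self) -> list[int]:
        return [vid for vid, _, _ in self.intervals]


@dataclass
class StimulusFeature:
    """Time x feature matrix sampled at ``rate`` Hz with column labels."""

    values: np.ndarray
    rate: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(_as_float_array(self.values, "values", 2))
        if self.rate <= 0:
            raise ParameterError("stimulus rate must be positive")
        if not self.labels:
            self.labels = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise InputError(
                f"{len(self.labels)} labels for {self.values.shape[1]} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class EEGRecording:
    """Time x channel matrix (microvolts) sampled at ``rate`` Hz."""

    values: np.ndarray
    rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(_as_float_array(self.values, "values", 2))
        if self.rate <= 0:
            raise ParameterError("EEG rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{j + 1:03d}" for j in range(self.values.shape[1])]
        if len(self.channel_names) != self.values.shape[1]:
            raise InputError(
                f"{len(self.channel_names)} names for {self.values.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]
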