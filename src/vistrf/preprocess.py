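"""Minimal EEG conditioning: band-limit, downsample, re-reference.

The encoding analysis operates on low-frequency EEG (0.3-15 Hz) at 128 Hz
with an average reference.  All three operations are linear, so their order
commutes up to numerical tolerance.  Artifact handling (bad-channel
interpolation, ICA) is assumed to have happened upstream.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .types import EEGRecording, ParameterError

__all__ = ["bandpass", "resample", "average_reference"]


def bandpass(eeg: EEGRecording, low: float = 0.3, high: float = 15.0) -> EEGRecording:
    """Zero-phase Butterworth bandpass (order 3 per pass, forward-backward).

    Zero-phase filtering avoids latency distortion of the response functions
    estimated downstream; the effective magnitude response is the squared
    order-3 Butterworth, giving > 30 dB attenuation one octave outside the
    band.
    """
    nyq = eeg.rate / 2
    if not 0 < low < high < nyq:
        raise ParameterError(
            f"need 0 < low < high < Nyquist ({nyq} Hz); got ({low}, {high})"
        )
    sos = signal.butter(3, [low, high], btype="bandpass", fs=eeg.rate, output="sos")
    values = signal.sosfiltfilt(sos, eeg.values, axis=0)
    return EEGRecording(values, eeg.rate, list(eeg.channel_names))


def resample(eeg: EEGRecording, out_rate: float) -> EEGRecording:
    """Anti-aliased polyphase resampling to ``out_rate`` Hz."""
    if out_rate <= 0:
        raise ParameterError("out_rate must be positive")
    if out_rate == eeg.rate:
        return EEGRecording(eeg.values.copy(), eeg.rate, list(eeg.channel_names))
    frac = Fraction(out_rate / eeg.rate).limit_denominator(10**6)
    values = signal.resample_poly(eeg.values, frac.numerator, frac.denominator, axis=0)
    return EEGRecording(values, out_rate, list(eeg.channel_names))


def average_reference(eeg: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel.

    After re-referencing each row (time sample) sums to zero.
    """
    if eeg.n_channels < 2:
        raise ParameterError("average reference needs at least 2 channels")
    values = eeg.values - eeg.values.mean(axis=1, keepdims=True)
    return EEGRecording(values, eeg.rate, list(eeg.channel_names))
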