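"""Slow-amplitude (envelope) channel extraction and integrated activity.

Two envelope estimators are provided:

* :func:`rms_envelope` — sliding root-mean-square over a centred window
  (default 50 samples, i.e. 50 ms at 1 kHz), the default channel feeding
  the envelope spectrograms;
* :func:`hilbert_envelope` — magnitude of the analytic signal, the
  instantaneous amplitude for narrow-band inputs.

For a sinusoidal carrier the two differ by a fixed sqrt(2) factor (RMS
vs peak amplitude); both demodulate AM test signals to the same shape.

:func:`delta_integrated_activity` is the scalar burst-activity measure:
the change in mean rectified amplitude from baseline, with the
instrument noise floor subtracted from each term first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import AlignmentError, ArgumentError
from .simulate import Labels, Recording


@dataclass
class EnvelopeSignal:
    """Non-negative slow-amplitude trace derived from a Recording."""

    samples: np.ndarray
    fs: float
    method: str  # 'rms' | 'hilbert'
    source_labels: Labels
    window_samples: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < -1e-12):
            raise ArgumentError("envelope samples must be non-negative")
        self.samples = np.clip(self.samples, 0.0, None)


def _centered_moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centred window of ``window`` samples, shrunk at the edges.

    Sample i averages x[max(0, i-left) : min(n, i+right+1)] with
    left = (window-1)//2 and right = window//2; interior windows contain
    exactly ``window`` samples.
    """
    n = len(x)
    left = (window - 1) // 2
    right = window // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    hi = np.minimum(np.arange(n) + right + 1, n)
    lo = np.maximum(np.arange(n) - left, 0)
    return (c[hi] - c[lo]) / (hi - lo)


def rms_envelope(recording: Recording, window_samples: int = 50) -> EnvelopeSignal:
    """Sliding-window RMS envelope (upper-limit semantics, centred window)."""
    n = len(recording.samples)
    if window_samples < 1:
        raise ArgumentError("window_samples must be >= 1")
    if window_samples > n:
        raise ArgumentError(f"window_samples={window_samples} exceeds signal length {n}")
    env = np.sqrt(_centered_moving_mean(recording.samples**2, window_samples))
    return EnvelopeSignal(env, recording.fs, "rms", recording.labels, window_samples)


def hilbert_envelope(recording: Recording, demean: bool = False) -> EnvelopeSignal:
    """Analytic-signal magnitude.

    The envelope of an offset signal is offset-dominated, so ``demean``
    optionally removes the mean before the transform (off by default).
    """
    x = recording.samples
    if demean:
        x = x - x.mean()
    env = np.abs(signal.hilbert(x))
    return EnvelopeSignal(env, recording.fs, "hilbert", recording.labels)


def integrated_activity(recording: Recording, floor_rectified_mean: float = 0.0) -> float:
    """Mean rectified amplitude with the scalar noise floor removed (AU)."""
    return float(np.mean(np.abs(recording.samples))) - floor_rectified_mean


def delta_integrated_activity(
    test_recording: Recording,
    baseline_recording: Recording,
    floor_rectified_mean: float = 0.0,
) -> float:
    """Change (Delta) in integrated activity from baseline, in arbitrary units.

    Delta = (test - floor) - (baseline - floor); the sign carries the
    direction of the change.
    """
    if test_recording.fs != baseline_recording.fs:
        raise AlignmentError("test and baseline sampling rates differ")
    return integrated_activity(test_recording, floor_rectified_mean) - integrated_activity(
        baseline_recording, floor_rectified_mean
    )
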