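"""Signal conditioning for nerve recordings.

The standard chain mirrors the acquisition pipeline of multiunit
sympathetic recordings: polyphase down-sampling to 1 kHz, an IIR comb
notch removing the 60 Hz power line and its harmonics, and an order-12
Chebyshev type-I band-pass (2 dB ripple, 1-200 Hz).  All IIR filters are
applied forward-backward (zero phase) so that envelope timing is not
distorted; this doubles the effective ripple and stop-band attenuation,
which the contracts below account for.

Noise-floor subtraction operates at the integrated-activity level: the
floor recording's mean rectified amplitude (and mean-square power) are
stored as scalars and subtracted from integrated measures downstream,
never sample-wise, because an independent floor waveform is uncorrelated
with the nerve signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import AlignmentError, ArgumentError, DesignError
from .simulate import Recording

POWERLINE_HZ = 60.0
#: Per-notch quality factor at the fundamental; harmonic k uses Q*k so
#: every notch has the same absolute bandwidth (~1.7 Hz at Q=35).
COMB_Q = 35.0


@dataclass(frozen=True)
class FilterSpec:
    """Serializable description of one applied filter."""

    kind: str  # 'resample' | 'comb_notch' | 'bandpass'
    params: tuple = ()

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": list(self.params)}


@dataclass
class PreprocessedRecording(Recording):
    """A Recording plus the filters applied to it and any floor statistics."""

    applied_filters: list = field(default_factory=list)
    original_fs: float | None = None
    floor_rectified_mean: float | None = None
    floor_power: float | None = None


def _as_preprocessed(rec: Recording, samples, fs, spec: FilterSpec) -> PreprocessedRecording:
    prior = list(rec.applied_filters) if isinstance(rec, PreprocessedRecording) else []
    orig = rec.original_fs if isinstance(rec, PreprocessedRecording) and rec.original_fs else rec.fs
    out = PreprocessedRecording(
        samples=samples,
        fs=fs,
        labels=rec.labels,
        provenance=rec.provenance,
        applied_filters=prior + [spec],
        original_fs=orig,
    )
    if isinstance(rec, PreprocessedRecording):
        out.floor_rectified_mean = rec.floor_rectified_mean
        out.floor_power = rec.floor_power
    return out


def resample(recording: Recording, target_fs: float) -> PreprocessedRecording:
    """Polyphase resampling with a Kaiser-windowed anti-alias filter.

    ``target_fs == fs`` is the identity (bit-equal samples).  Rational
    up/down factors are derived from the rate ratio, so non-integer
    ratios are handled by the polyphase structure.
    """
    if target_fs <= 0:
        raise ArgumentError("target_fs must be positive")
    spec = FilterSpec("resample", (recording.fs, target_fs))
    if target_fs == recording.fs:
        return _as_preprocessed(recording, recording.samples.copy(), recording.fs, spec)
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    y = signal.resample_poly(recording.samples, up, down, window=("kaiser", 5.0))
    return _as_preprocessed(recording, y, target_fs, spec)


def _check_stable(sos: np.ndarray) -> None:
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise DesignError("unstable IIR design (pole on or outside unit circle)")


def comb_notch_sos(fs: float, fundamental: float = POWERLINE_HZ, q: float = COMB_Q) -> np.ndarray:
    """Cascade of second-order notches at the fundamental and harmonics below Nyquist."""
    if fundamental >= fs / 2:
        raise DesignError("comb fundamental must lie below Nyquist")
    sections = []
    k = 1
    while k * fundamental < fs / 2:
        b, a = signal.iirnotch(k * fundamental, q * k, fs=fs)
        sections.append(np.hstack([b, a]))
        k += 1
    sos = np.vstack(sections)
    _check_stable(sos)
    return sos


def comb_notch(recording: Recording, fundamental: float = POWERLINE_HZ, q: float = COMB_Q) -> PreprocessedRecording:
    """Zero-phase comb notch removing the power line and all harmonics below Nyquist."""
    sos = comb_notch_sos(recording.fs, fundamental, q)
    y = signal.sosfiltfilt(sos, recording.samples)
    return _as_preprocessed(recording, y, recording.fs, FilterSpec("comb_notch", (fundamental, q)))


def bandpass_sos(fs: float, low: float = 1.0, high: float = 200.0, order: int = 12, ripple_db: float = 2.0) -> np.ndarray:
    """Chebyshev type-I band-pass of the given *total* order (order/2 per edge)."""
    if not 0 < low < high < fs / 2:
        raise DesignError(f"invalid band ({low}, {high}) for fs={fs}")
    if order < 2 or order % 2:
        raise DesignError("band-pass order must be an even integer >= 2")
    sos = signal.cheby1(order // 2, ripple_db, [low, high], btype="bandpass", fs=fs, output="sos")
    _check_stable(sos)
    return sos


def bandpass(
    recording: Recording,
    low: float = 1.0,
    high: float = 200.0,
    order: int = 12,
    ripple_db: float = 2.0,
    zero_phase: bool = True,
) -> PreprocessedRecording:
    """Equiripple (Chebyshev-I) band-pass, applied zero-phase by default."""
    sos = bandpass_sos(recording.fs, low, high, order, ripple_db)
    if zero_phase:
        y = signal.sosfiltfilt(sos, recording.samples)
    else:
        y = signal.sosfilt(sos, recording.samples)
    return _as_preprocessed(
        recording, y, recording.fs, FilterSpec("bandpass", (low, high, order, ripple_db))
    )


def standard_chain(recording: Recording, target_fs: float = 1000.0) -> PreprocessedRecording:
    """resample -> comb notch -> band-pass, the default conditioning chain."""
    rec = resample(recording, target_fs)
    rec = comb_notch(rec)
    return bandpass(rec)


@dataclass(frozen=True)
class NoiseFloorStats:
    """Scalar floor statistics used for integrated-activity subtraction."""

    rectified_mean: float
    power: float
    duration: float


def noise_floor_stats(floor: Recording) -> NoiseFloorStats:
    x = floor.samples
    return NoiseFloorStats(
        rectified_mean=float(np.mean(np.abs(x))),
        power=float(np.mean(x * x)),
        duration=floor.duration,
    )


def subtract_noise_floor(recording: Recording, floor: Recording) -> PreprocessedRecording:
    """Attach the floor's scalar statistics to the recording.

    Samples are untouched; downstream integrated-activity measures
    subtract the stored scalars (power-level subtraction).
    """
    if recording.fs != floor.fs:
        raise AlignmentError(f"sampling rates differ: {recording.fs} vs {floor.fs}")
    if floor.duration < 10.0:
        raise ArgumentError("noise floor must be at least 10 s long")
    stats = noise_floor_stats(floor)
    out = _as_preprocessed(
        recording, recording.samples.copy(), recording.fs, FilterSpec("noise_floor", ())
    )
    out.floor_rectified_mean = stats.rectified_mean
    out.floor_power = stats.power
    return out


def net_signal_power(recording: Recording, floor: Recording) -> float:
    """Mean-square power of the recording with the floor power removed.

    For an additive independent floor, E[(s+n)^2] - E[n^2] = E[s^2], so
    this recovers the signal power without sample-wise subtraction.
    """
    if recording.fs != floor.fs:
        raise AlignmentError("sampling rates differ")
    return float(np.mean(recording.samples**2)) - noise_floor_stats(floor).power
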