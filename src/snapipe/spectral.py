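"""Sliding-window power spectral density estimation and band statistics.

A temporal window covering a fixed *fraction* of the recording (default
0.5%) slides along the signal with 20% overlap; each window position
yields one Hann-tapered periodogram row (density scaling, one-sided).
For a 10-min recording at 1 kHz this gives 3,000-sample windows, a
2,400-sample step and exactly 249 rows.  Because the window is a
fraction of the signal, the row count is duration-invariant.

The per-window estimator is a single tapered periodogram: the sliding
rows themselves provide the averaging that a nested Welch scheme would,
and keeping rows un-averaged is what exposes them as "trials" to the
canonical discriminant analysis downstream.

Band powers integrate the PSD over half-open intervals [low, high) with
linear interpolation at the band edges, so adjacent sub-bands partition
their parent exactly ([0,4) + [4,10) = [0,10)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

from .errors import AlignmentError, ArgumentError
from .envelope import EnvelopeSignal
from .simulate import Labels, Recording

MIN_WINDOW_SAMPLES = 64


@dataclass(frozen=True)
class SpectralWindowing:
    window_fraction: float = 0.005
    overlap_fraction: float = 0.2
    taper: str = "hann"
    nfft_policy: str = "next_pow2"  # 'next_pow2' | 'exact'

    def __post_init__(self):
        if not 0.0 < self.window_fraction < 1.0:
            raise ArgumentError("window_fraction must lie in (0, 1)")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ArgumentError("overlap_fraction must lie in [0, 1)")
        if self.taper != "hann":
            raise ArgumentError("only the hann taper is supported")
        if self.nfft_policy not in ("next_pow2", "exact"):
            raise ArgumentError("nfft_policy must be 'next_pow2' or 'exact'")

    def window_samples(self, n: int) -> int:
        return int(round(self.window_fraction * n))

    def step_samples(self, n: int) -> int:
        return max(1, int(round(self.window_samples(n) * (1.0 - self.overlap_fraction))))

    def n_rows(self, n: int) -> int:
        w = self.window_samples(n)
        return (n - w) // self.step_samples(n) + 1


@dataclass
class Spectrogram:
    """Per-window power (amplitude^2/Hz) by frequency, with label metadata."""

    power: np.ndarray  # (n_windows, n_bins)
    freqs: np.ndarray
    window_times: np.ndarray  # window-centre times, s
    labels: Labels
    channel: str  # 'envelope' | 'burst'

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ArgumentError("spectrogram power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ArgumentError("frequency grid must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class PSDSet:
    """Group-mean PSD with a 95% t-interval of the mean per frequency bin."""

    freqs: np.ndarray
    mean_power: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_trials: int
    degenerate: bool = False  # single trial: CI undefined, returned as the mean


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency interval [low, high)."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ArgumentError("band low must be < high")


#: Envelope-channel sub-bands and burst-channel sub-bands of the analysis.
ENVELOPE_BANDS = (BandDefinition("0-4Hz", 0.0, 4.0), BandDefinition("4-10Hz", 4.0, 10.0))
BURST_BANDS = (BandDefinition("1-60Hz", 1.0, 60.0), BandDefinition("60-200Hz", 60.0, 200.0))


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def sliding_psd(
    source: Recording | EnvelopeSignal | np.ndarray,
    windowing: SpectralWindowing = SpectralWindowing(),
    fs: float | None = None,
    channel: str = "burst",
    labels: Labels | None = None,
) -> Spectrogram:
    """One Hann periodogram per sliding-window position.

    Each window is demeaned before tapering, so the integral of a row
    over frequency approximates the windowed-signal variance (Parseval).
    """
    if isinstance(source, (Recording, EnvelopeSignal)):
        x = source.samples
        fs = source.fs
        if labels is None:
            labels = source.labels if isinstance(source, Recording) else source.source_labels
    else:
        x = np.asarray(source, dtype=float)
        if fs is None:
            raise ArgumentError("fs is required for bare arrays")
    if labels is None:
        labels = Labels("CTRL", "renal", "BAS", 0)

    n = len(x)
    w = windowing.window_samples(n)
    if w < MIN_WINDOW_SAMPLES:
        need = int(np.ceil(MIN_WINDOW_SAMPLES / windowing.window_fraction))
        raise ArgumentError(
            f"window of {w} samples is below the {MIN_WINDOW_SAMPLES}-sample minimum; "
            f"signal must be at least {need} samples long at window_fraction="
            f"{windowing.window_fraction}"
        )
    step = windowing.step_samples(n)
    rows = windowing.n_rows(n)

    starts = np.arange(rows) * step
    segs = np.lib.stride_tricks.sliding_window_view(x, w)[starts].copy()
    segs -= segs.mean(axis=1, keepdims=True)

    taper = hann(w, sym=False)
    nfft = _next_pow2(w) if windowing.nfft_policy == "next_pow2" else w
    spec = rfft(segs * taper, n=nfft, axis=1)
    scale = 1.0 / (fs * np.sum(taper**2))
    power = (spec.real**2 + spec.imag**2) * scale
    power[:, 1:] *= 2.0
    if nfft % 2 == 0:
        power[:, -1] /= 2.0

    freqs = rfftfreq(nfft, 1.0 / fs)
    times = (starts + w / 2.0) / fs
    return Spectrogram(power, freqs, times, labels, channel)


def mean_psd(spectrograms: list[Spectrogram] | Spectrogram, ci_level: float = 0.95) -> PSDSet:
    """Per-bin mean over all windows of all trials, with a t-based CI of the mean."""
    if isinstance(spectrograms, Spectrogram):
        spectrograms = [spectrograms]
    if not spectrograms:
        raise ArgumentError("no spectrograms given")
    freqs = spectrograms[0].freqs
    for sg in spectrograms[1:]:
        if len(sg.freqs) != len(freqs) or not np.allclose(sg.freqs, freqs):
            raise AlignmentError("spectrograms have mismatched frequency grids")
    rows = np.vstack([sg.power for sg in spectrograms])
    n = rows.shape[0]
    mean = rows.mean(axis=0)
    if n < 2:
        return PSDSet(freqs, mean, mean.copy(), mean.copy(), n, degenerate=True)
    sem = rows.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = sstats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    return PSDSet(freqs, mean, mean - tcrit * sem, mean + tcrit * sem, n)


def _band_integral(freqs: np.ndarray, power: np.ndarray, band: BandDefinition) -> float:
    """Trapezoidal integral over [low, high) with interpolated edge values."""
    lo, hi = band.low, band.high
    if lo < freqs[0] or hi > freqs[-1]:
        raise ArgumentError(
            f"band [{lo}, {hi}) outside frequency grid [{freqs[0]}, {freqs[-1]}]"
        )
    interior = (freqs > lo) & (freqs < hi)
    f = np.concatenate([[lo], freqs[interior], [hi]])
    p = np.concatenate(
        [[np.interp(lo, freqs, power)], power[interior], [np.interp(hi, freqs, power)]]
    )
    return float(np.trapezoid(p, f))


def band_power(
    source: Spectrogram | PSDSet, band: BandDefinition
) -> np.ndarray | float:
    """Integrated power in a band: one scalar per spectrogram row, or one per PSD."""
    if isinstance(source, Spectrogram):
        return np.array([_band_integral(source.freqs, row, band) for row in source.power])
    return _band_integral(source.freqs, source.mean_power, band)


def peak_frequency(source: PSDSet | Spectrogram, band: BandDefinition) -> float:
    """Frequency of maximum power within [low, high); ties break to lower frequency.

    For a Spectrogram the row-mean PSD is used.
    """
    freqs = source.freqs
    power = source.mean_power if isinstance(source, PSDSet) else source.power.mean(axis=0)
    mask = (freqs >= band.low) & (freqs < band.high)
    if not np.any(mask):
        raise ArgumentError(f"band [{band.low}, {band.high}) is empty on this grid")
    sub = power[mask]
    return float(freqs[mask][int(np.argmax(sub))])
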