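"""Synthetic sympathetic-nerve recordings with amplitude-modulated burst structure.

Multiunit postganglionic nerve activity is organised as bursts of
high-frequency action potentials (spectral mass between ~60 and 200 Hz)
whose amplitude is modulated by slow "virtual envelope" oscillations
(< 10 Hz).  The generator reproduces exactly that two-channel structure
with a multiplicative AM model::

    x(t) = A * m(t) * c(t) + eps(t)

where ``m(t) >= 0`` is a rectified sum of slow sinusoids (the envelope
modulator), ``c(t)`` is zero-mean unit-variance noise spectrally shaped
into the configured high-frequency carrier peaks, and ``eps`` is a white
instrument-noise floor (the analogue of a ganglionic-blockade recording).

Default spectral parameters encode the study conditions:

* baseline (BAS): envelope peaks in the 0-2 Hz and 6-8 Hz bands, carrier
  peaks near 150 and 190 Hz; the losartan-treated hypertensive group
  carries extra envelope power at 5 and 8 Hz;
* after GABA-A antagonist disinhibition (BIC): envelope power collapses
  onto a dominant 0.5 Hz component with a weaker 1.5 Hz component,
  shared across groups; the hypertensive splanchnic carrier shifts
  to ~90 Hz.

Every draw is routed through a ``numpy`` Generator seeded from the
config, so identical ``(config, seed)`` gives bit-identical samples.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import signal

from .errors import ArgumentError, ConfigError, InvalidLabelError

GROUPS = ("CTRL", "2K1C", "2K1C_LOS")
NERVES = ("renal", "splanchnic")
CONDITIONS = ("BAS", "BIC")

#: Time constant (s) of the Ornstein-Uhlenbeck phase drift that emulates
#: slow baroreceptor-entrainment jitter of the envelope rhythms.
PHASE_DRIFT_TAU_S = 10.0


@dataclass(frozen=True)
class EnvelopeComponent:
    """One slow modulator sinusoid: frequency (Hz), relative amplitude,
    and the stationary s.d. (rad) of its random phase drift."""

    freq_hz: float
    amplitude: float
    phase_jitter_sd: float = 0.1


@dataclass(frozen=True)
class CarrierPeak:
    """One band-limited noise component of the burst carrier."""

    center_hz: float
    bandwidth_hz: float
    rel_power: float


@dataclass(frozen=True)
class Labels:
    group: str
    nerve: str
    condition: str
    animal_id: int = 0

    def class_label(self) -> str:
        """Composite class used by the discriminant analysis, e.g. ``R-CTRL``."""
        prefix = "R" if self.nerve == "renal" else "S"
        short = {"CTRL": "CTRL", "2K1C": "2K1C", "2K1C_LOS": "LOS"}[self.group]
        return f"{prefix}-{short}"


@dataclass(frozen=True)
class GeneratorConfig:
    group: str
    nerve: str
    condition: str
    duration: float = 600.0
    fs: float = 1000.0
    envelope_components: tuple[EnvelopeComponent, ...] = ()
    carrier_peaks: tuple[CarrierPeak, ...] = ()
    noise_floor_sd: float = 0.05
    modulation_depth: float = 0.6
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidLabelError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.nerve not in NERVES:
            raise InvalidLabelError(f"unknown nerve {self.nerve!r}; expected one of {NERVES}")
        if self.condition not in CONDITIONS:
            raise InvalidLabelError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        for name in ("duration", "fs", "noise_floor_sd", "modulation_depth", "amplitude"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v!r}")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if self.fs <= 0:
            raise ConfigError("fs must be > 0")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ConfigError("modulation_depth must lie in [0, 1]")
        if self.noise_floor_sd < 0:
            raise ConfigError("noise_floor_sd must be >= 0")
        for comp in self.envelope_components:
            if not (comp.freq_hz > 0 and math.isfinite(comp.freq_hz)):
                raise ConfigError("envelope component frequencies must be positive and finite")
        for peak in self.carrier_peaks:
            if peak.center_hz <= 0 or peak.bandwidth_hz <= 0:
                raise ConfigError("carrier peak center and bandwidth must be positive")
            if self.fs <= 2 * (peak.center_hz + peak.bandwidth_hz / 2):
                raise ConfigError(
                    f"fs={self.fs} must exceed twice the top carrier edge "
                    f"({peak.center_hz + peak.bandwidth_hz / 2} Hz)"
                )

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Recording:
    """A labelled single-channel voltage trace, the pipeline's atomic input."""

    samples: np.ndarray
    fs: float
    labels: Labels
    provenance: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ArgumentError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ArgumentError("samples must be finite")
        if self.fs <= 0:
            raise ArgumentError("fs must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


# ---------------------------------------------------------------------------
# default study conditions

# Per-class baseline envelope components (freq Hz, relative amplitude).
# Both nerves sit in the 0-2 and 6-8 Hz bands; classes differ in exact
# peak position and amplitude ratio, giving each (group, nerve) a
# distinct PSD shape.  The treated-hypertensive group adds the extra
# 5 and 8 Hz components it exhibits.
_BAS_ENVELOPE = {
    ("CTRL", "renal"): ((1.0, 1.0), (7.0, 0.7)),
    ("CTRL", "splanchnic"): ((1.5, 1.0), (6.5, 0.7)),
    ("2K1C", "renal"): ((0.8, 1.0), (7.5, 0.9)),
    ("2K1C", "splanchnic"): ((1.2, 0.8), (6.8, 1.0)),
    ("2K1C_LOS", "renal"): ((1.0, 0.7), (5.0, 1.0), (8.0, 0.9)),
    ("2K1C_LOS", "splanchnic"): ((1.5, 0.6), (5.0, 0.9), (8.0, 1.0)),
}

# Shared post-disinhibition envelope pattern: dominant 0.5 Hz, weaker
# 1.5 Hz at a 2:1 amplitude ratio.  The overall level exceeds the
# baseline sub-4 Hz power, reproducing the disinhibition-driven rise of
# the 0-4 Hz envelope band and the fall of the 4-10 Hz band.
_BIC_ENVELOPE = ((0.5, 1.4), (1.5, 0.7))

# Relative power of the secondary 190 Hz carrier peak per class; the
# dominant peak stays at 150 Hz with unit relative power.
_P190 = {
    ("CTRL", "renal"): 0.5,
    ("CTRL", "splanchnic"): 0.6,
    ("2K1C", "renal"): 0.8,
    ("2K1C", "splanchnic"): 0.7,
    ("2K1C_LOS", "renal"): 0.4,
    ("2K1C_LOS", "splanchnic"): 0.45,
}


def default_config(
    group: str,
    nerve: str,
    condition: str,
    *,
    convergence: float = 1.0,
    duration: float = 600.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> GeneratorConfig:
    """Study-condition generator defaults for one (group, nerve, condition) cell.

    ``convergence`` (BIC only, in [0, 1]) interpolates the envelope
    spectrum between the class-specific baseline pattern (0) and the
    fully shared 0.5 / 1.5 Hz post-disinhibition pattern (1).  At the
    default of 1 every class shares the same slow rhythm, which is what
    collapses the between-class centroid distances in canonical space.
    """
    if group not in GROUPS:
        raise InvalidLabelError(f"unknown group {group!r}")
    if nerve not in NERVES:
        raise InvalidLabelError(f"unknown nerve {nerve!r}")
    if condition not in CONDITIONS:
        raise InvalidLabelError(f"unknown condition {condition!r}")
    if not 0.0 <= convergence <= 1.0:
        raise ConfigError("convergence must lie in [0, 1]")

    bas = tuple(EnvelopeComponent(f, a) for f, a in _BAS_ENVELOPE[(group, nerve)])
    if condition == "BAS":
        env = bas
    else:
        env = tuple(EnvelopeComponent(f, a) for f, a in _BIC_ENVELOPE)
        if convergence < 1.0:
            env = env + tuple(
                EnvelopeComponent(c.freq_hz, c.amplitude * (1.0 - convergence))
                for c in bas
            )

    if condition == "BIC" and group == "2K1C" and nerve == "splanchnic":
        carriers = (CarrierPeak(90.0, 20.0, 1.0),)
    else:
        carriers = (
            CarrierPeak(150.0, 20.0, 1.0),
            CarrierPeak(190.0, 15.0, _P190[(group, nerve)]),
        )

    return GeneratorConfig(
        group=group,
        nerve=nerve,
        condition=condition,
        duration=duration,
        fs=fs,
        envelope_components=env,
        carrier_peaks=carriers,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# synthesis


def _ou_phase(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck phase drift, s.d. ``sd`` rad, time
    constant PHASE_DRIFT_TAU_S, simulated by its exact AR(1) discretisation."""
    if sd <= 0:
        return np.zeros(n)
    a = math.exp(-1.0 / (fs * PHASE_DRIFT_TAU_S))
    b = sd * math.sqrt(1.0 - a * a)
    z = rng.standard_normal(n)
    phi = signal.lfilter([b], [1.0, -a], z)
    phi[0] = sd * z[0]  # start from the stationary distribution
    return phi


def envelope_modulator(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """The rectified slow modulator m(t) >= 0 (unit offset, clipped at zero)."""
    n = config.n_samples
    t = np.arange(n) / config.fs
    mod = np.zeros(n)
    for comp in config.envelope_components:
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        drift = _ou_phase(rng, n, comp.phase_jitter_sd, config.fs)
        mod += comp.amplitude * np.sin(2.0 * np.pi * comp.freq_hz * t + phi0 + drift)
    return np.clip(1.0 + config.modulation_depth * mod, 0.0, None)


def _shaped_carrier(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance noise shaped into the configured carrier peaks.

    Bursts are broadband, so each peak is white noise through a
    second-order Butterworth band-pass, not a sinusoid.
    """
    n = config.n_samples
    carrier = np.zeros(n)
    for peak in config.carrier_peaks:
        low = peak.center_hz - peak.bandwidth_hz / 2.0
        high = peak.center_hz + peak.bandwidth_hz / 2.0
        sos = signal.butter(2, [low, high], btype="bandpass", fs=config.fs, output="sos")
        comp = signal.sosfilt(sos, rng.standard_normal(n))
        comp *= math.sqrt(peak.rel_power) / comp.std()
        carrier += comp
    if carrier.any():
        carrier /= carrier.std()
    return carrier


def generate_recording(config: GeneratorConfig) -> Recording:
    """Synthesize one nerve trace: ``amplitude * m(t) * c(t) + eps(t)``."""
    rng = np.random.default_rng(config.seed)
    m = envelope_modulator(config, rng)
    c = _shaped_carrier(config, rng)
    x = config.amplitude * m * c
    if config.noise_floor_sd > 0:
        x = x + config.noise_floor_sd * rng.standard_normal(config.n_samples)
    labels = Labels(config.group, config.nerve, config.condition, animal_id=0)
    return Recording(x, config.fs, labels, provenance=f"simulate:{config.config_hash()}:seed={config.seed}")


def generate_cohort(
    n_animals: int,
    group: str,
    nerve: str,
    condition: str,
    base_seed: int = 0,
    **config_kwargs,
) -> list[Recording]:
    """A cohort of independent animals; per-animal seed = base_seed + animal_id."""
    if n_animals < 1:
        raise ArgumentError("n_animals must be >= 1")
    cohort = []
    for animal_id in range(1, n_animals + 1):
        cfg = default_config(group, nerve, condition, seed=base_seed + animal_id, **config_kwargs)
        rec = generate_recording(cfg)
        rec.labels = replace(rec.labels, animal_id=animal_id)
        cohort.append(rec)
    return cohort


def generate_noise_floor(config: GeneratorConfig) -> Recording:
    """A pure instrument-noise trace (the ganglionic-blockade analogue).

    Same sampling rate, duration and labels as the config, drawn from a
    stream decorrelated from (but determined by) the config seed, and
    tagged ``noise_floor`` in provenance.
    """
    rng = np.random.default_rng((config.seed, 0xF100))
    n = config.n_samples
    x = config.noise_floor_sd * rng.standard_normal(n) if config.noise_floor_sd > 0 else np.zeros(n)
    labels = Labels(config.group, config.nerve, config.condition, animal_id=0)
    return Recording(x, config.fs, labels, provenance=f"noise_floor:{config.config_hash()}:seed={config.seed}")
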