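import dataclasses

import numpy as np
import pytest

from snapipe.simulate import Labels, Recording, default_config, generate_recording

FS = 1000.0


@pytest.fixture
def labels():
    return Labels("CTRL", "renal", "BAS", 1)


@pytest.fixture
def make_tone(labels):
    """Factory for pure-sinusoid recordings."""

    def _make(freq_hz, duration=10.0, amplitude=1.0, fs=FS):
        t = np.arange(round(duration * fs)) / fs
        return Recording(amplitude * np.sin(2 * np.pi * freq_hz * t), fs, labels)

    return _make


@pytest.fixture
def short_recording():
    """A 30-s default baseline recording, cheap enough for unit tests."""
    cfg = default_config("CTRL", "renal", "BAS", duration=30.0, seed=42)
    return generate_recording(cfg)


@pytest.fixture
def make_config():
    """Factory for tweaked generator configs."""

    def _make(group="CTRL", nerve="renal", condition="BAS", seed=0, duration=60.0, **overrides):
        cfg = default_config(group, nerve, condition, duration=duration, seed=seed)
        return dataclasses.replace(cfg, **overrides) if overrides else cfg

    return _make
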