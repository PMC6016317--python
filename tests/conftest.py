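import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from kindleeg import EEGRecord, GroupProfile, PhaseProfile, SimConfig


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture
def tone_factory():
    """Build pure-tone records: tone(freqs_amps, fs, duration)."""

    def _make(components, fs=200.0, duration=8.0):
        t = np.arange(int(duration * fs)) / fs
        x = np.zeros_like(t)
        for freq, amp in components:
            x = x + amp * np.sin(2 * np.pi * freq * t)
        return EEGRecord(samples=x, sampling_rate=fs)

    return _make


@pytest.fixture
def tiny_profile() -> GroupProfile:
    """A small single-group calibration for fast session tests."""
    return GroupProfile(
        group_label="Kindle",
        n_animals=2,
        phases={
            "ISS": PhaseProfile((0.83, 0.08, 0.09), 8.0, 1.0, 4),
            "LSS": PhaseProfile((0.71, 0.13, 0.16), 12.0, 1.0, 3),
            "GSS": PhaseProfile((0.60, 0.15, 0.25), 20.0, 1.5, 3),
        },
    )
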