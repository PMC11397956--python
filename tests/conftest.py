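"""Shared fixtures: small ground-truthed synthetic signals.

Everything is generated at test time; session scope keeps the heavier
protocol-shaped signals from being rebuilt per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgval import (
    MorphologyConfig,
    ProtocolProfile,
    Segment,
    generate_beat_times,
    synthesize_ecg,
)

BASE_EPOCH_MS = 1_700_000_000_000.0


@pytest.fixture(scope="session")
def steady_beats() -> np.ndarray:
    """60 bpm, 60 s, no jitter: beats exactly 1 s apart."""
    profile = ProtocolProfile(segments=(Segment(60, 60, 60, "rest_pre", 0.0),), seed=0)
    beats, _ = generate_beat_times(profile)
    return beats + BASE_EPOCH_MS


@pytest.fixture(scope="session")
def protocol_beats() -> tuple[np.ndarray, np.ndarray]:
    """Compressed protocol-shaped beat sequence (rest/ramp/rest) with labels."""
    profile = ProtocolProfile.default(seed=3, scale=0.2)
    beats, labels = generate_beat_times(profile)
    return beats + BASE_EPOCH_MS, labels


@pytest.fixture(scope="session")
def clean_record(protocol_beats):
    """Clean 500 Hz rendering of the protocol beats (tiny sensor noise)."""
    beats, _ = protocol_beats
    return synthesize_ecg(beats, fs=500.0, morphology=MorphologyConfig(noise_sd_uv=5.0), seed=3)
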