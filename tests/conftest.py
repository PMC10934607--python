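"""Shared fixtures: one clean synthetic recording reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import fcgbeats as f
from fcgbeats import pipeline


@pytest.fixture(scope="session")
def clean_config() -> f.SynthConfig:
    """A clean 5-minute recording at 1 kHz (~300 beats, low noise)."""
    return f.SynthConfig(duration=300.0, seed=1)


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    """(fcg, ecg, truth) triple generated once for the session."""
    fcg, truth = f.generate_fcg(clean_config)
    ecg = f.generate_ecg(clean_config, truth)
    return fcg, ecg, truth


@pytest.fixture(scope="session")
def clean_results(clean_config, clean_recording):
    """Full analysis of the clean recording against ground-truth beats."""
    fcg, _, truth = clean_recording
    reference = f.EventSeries(times=truth.r_times, label="R")
    return pipeline.analyze_recording(fcg, reference), truth


@pytest.fixture(scope="session")
def heart_sounds(clean_recording):
    """Band-passed heart-sound component of the clean recording."""
    fcg, _, _ = clean_recording
    return pipeline.heart_sound_component(fcg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
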