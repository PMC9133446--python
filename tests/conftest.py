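"""Shared fixtures: one full-length default synthetic recording, its
preprocessed form and its staging, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import vigileeg as vg


@pytest.fixture(scope="session")
def default_simulation():
    """Default 20-min synthetic recording with ground truth (fixed seed)."""
    cfg = vg.SimulationConfig(seed=7)
    trajectory = vg.sample_stage_trajectory(cfg)
    recording, truth = vg.synthesize_recording(trajectory, cfg)
    return cfg, recording, truth


@pytest.fixture(scope="session")
def preprocessed_default(default_simulation):
    _, recording, _ = default_simulation
    cleaned, table = vg.preprocess(recording, run_ica=True, ica_seed=1)
    return cleaned, table


@pytest.fixture(scope="session")
def staged_default(preprocessed_default):
    cleaned, table = preprocessed_default
    return vg.classify_recording(cleaned, table)


@pytest.fixture(scope="session")
def short_simulation():
    """A 5-min recording without ICA-scale preprocessing, for cheap tests."""
    cfg = vg.SimulationConfig(duration=300.0, seed=13)
    trajectory = vg.sample_stage_trajectory(cfg)
    recording, truth = vg.synthesize_recording(trajectory, cfg)
    return cfg, recording, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
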