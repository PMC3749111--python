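"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from ecogarm import (
    PipelineConfig,
    SimulationSpec,
    segment_trials,
    simulate_session,
    tangential_velocity,
)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small high-fidelity session spec: 4 channels, 2 trials."""
    return SimulationSpec(
        n_channels=4,
        n_trials=2,
        trial_duration_s=10.0,
        envelope_snr=10.0,
        carrier_type="sinusoid",
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_spec):
    session, truth = simulate_session(tiny_spec)
    return session, truth


@pytest.fixture(scope="session")
def tiny_trials(tiny_session):
    session, _ = tiny_session
    cfg = PipelineConfig()
    speed = tangential_velocity(
        session.marker_xyz("elbow"), session.fs_markers, cfg.velocity_smooth_cutoff
    )
    return segment_trials(
        speed, session.fs_markers, cfg.velocity_threshold_fraction,
        cfg.min_gap_s, cfg.min_duration_s,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
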