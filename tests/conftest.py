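"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from pacpipe.data_model import EpochSet
from pacpipe.spectral import analytic_band
from pacpipe.synthetic import (CouplingSpec, RhythmSpec, SomatotopySpec,
                               SyntheticConfig, TaskSpec, make_session)

PHI0 = 3 * np.pi / 4


@pytest.fixture(scope="session")
def rest_coupled_session():
    """One channel, rest only, d=0.5 coupling to a 12-20 Hz rhythm."""
    cfg = SyntheticConfig(
        n_channels=1, rate=500.0, duration_s=120.0, chi=2.0,
        rhythms=[RhythmSpec(band=(12.0, 20.0), amplitude=2.0)],
        couplings=[CouplingSpec(channel=0, depth=0.5, phase0=PHI0)],
        noise_floor=1e-3, seed=21)
    return make_session(cfg)


@pytest.fixture(scope="session")
def task_session():
    """Four channels, two-finger task, movement-gated rhythm and coupling."""
    cfg = SyntheticConfig(
        n_channels=4, rate=500.0, chi=2.0,
        rhythms=[RhythmSpec(band=(12.0, 20.0), amplitude=2.0,
                            movement_multiplier=0.4, shared_phase=False)],
        couplings=[CouplingSpec(channel=c, depth=0.6, phase0=PHI0,
                                movement_multiplier=0.2) for c in range(4)],
        task=TaskSpec(fingers=("thumb", "index"), cues_per_finger=15),
        somatotopy=SomatotopySpec(mapping={"thumb": 0, "index": 1}, gain=2.0),
        noise_floor=1e-3, seed=5)
    return make_session(cfg)


@pytest.fixture(scope="session")
def beta_phase_rest(rest_coupled_session):
    s = rest_coupled_session
    return analytic_band(s.samples[0], (12.0, 20.0), s.rate).phase


@pytest.fixture()
def rest_epochs(rest_coupled_session):
    return EpochSet.around_events(rest_coupled_session, "rest", 1.0)
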