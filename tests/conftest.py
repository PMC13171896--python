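"""Shared fixtures: small synthetic sessions generated once per test run."""

from __future__ import annotations

import numpy as np
import pytest

import trialhist as th


@pytest.fixture(scope="session")
def base_session() -> th.Session:
    """Mixed population with planted history and movement coding."""
    cfg = th.SessionConfig(
        n_trials=150,
        n_video_components=16,
        population=th.PopulationConfig(n_neurons=20, noise_sd=0.5),
    )
    return th.make_session(cfg, seed=7)


@pytest.fixture(scope="session")
def base_tensor(base_session) -> th.AlignedTensor:
    return th.align_activity(
        base_session.recording.spike_rate,
        base_session.config.frame_rate,
        base_session.trial_table,
        smooth=True,
    )


@pytest.fixture(scope="session")
def null_session() -> th.Session:
    """Chance-performing agent, no planted history coding."""
    cfg = th.SessionConfig(
        n_trials=170,
        n_video_components=8,
        behavior=th.BehaviorParams(
            beta1=0.0, beta_hist=(0.0, 0.0, 0.0, 0.0), p_early_withdrawal=0.1
        ),
        population=th.PopulationConfig(
            n_neurons=6, frac_history=0.0, frac_movement=0.0, frac_mixed=0.0
        ),
    )
    return th.make_session(cfg, seed=3)


@pytest.fixture(scope="session")
def null_tensor(null_session) -> th.AlignedTensor:
    return th.align_activity(
        null_session.recording.spike_rate,
        null_session.config.frame_rate,
        null_session.trial_table,
        smooth=True,
    )


@pytest.fixture(scope="session")
def quick_protocol() -> th.DecoderProtocol:
    """Reduced-round protocol for unit tests (full protocol in acceptance)."""
    return th.DecoderProtocol(n_rounds=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
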