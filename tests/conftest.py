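import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from orgdyn.synthgen import SynthParams, render_stack, simulate_trajectories


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_movie():
    """One standard small movie with events, shared across read-only tests."""
    p = SynthParams(
        seed=11,
        n_organelles=30,
        fission_rate_per_org_per_min=0.3,
        n_frames=40,
    )
    truth = simulate_trajectories(p)
    stack = render_stack(truth, p)
    return p, truth, stack


@pytest.fixture(scope="session")
def quiet_frame():
    """A single noise-free frame of well-separated discs with its truth."""
    p = SynthParams(
        seed=21,
        n_organelles=20,
        fission_rate_per_org_per_min=0.0,
        n_frames=2,
        photon_scale=None,
    )
    truth = simulate_trajectories(p)
    stack = render_stack(truth, p)
    return p, truth, stack
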