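import numpy as np
import pytest

from gliawave import synthetic, tracking


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def run_turn_chain(traj, **detect_kwargs):
    """Full trajectory-analysis chain: smooth, curvature, low-pass, detect."""
    traj = tracking.smooth_trajectory(traj)
    traj.curvature = tracking.compute_curvature(traj)
    traj.filtered_curvature = tracking.lowpass_curvature(
        traj.curvature, traj.dt, 30.0)
    return traj, tracking.detect_turns(traj, **detect_kwargs)


@pytest.fixture
def small_motility():
    return synthetic.MotilityParams(total_duration=30.0, seed=7)


@pytest.fixture
def default_waves():
    return synthetic.WaveParams(seed=7)
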