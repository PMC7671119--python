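import numpy as np
import pytest

from vromm import (
    StrikeParams,
    fit_body_plane,
    fit_rigid_poses,
    make_camera_rig,
    render_observations,
    simulate_strike,
    triangulate_tracks,
)


@pytest.fixture(scope="session")
def default_truth():
    """One default synthetic strike (skin slip 0.90, 500 fps, 200 ms)."""
    return simulate_strike(StrikeParams())


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free, slip-free strike with an on-grid strain peak (16 ms lag)."""
    return simulate_strike(
        StrikeParams(skin_slip_alpha=1.0, pixel_noise_sd=0.0, strain_peak_lag=0.016)
    )


@pytest.fixture(scope="session")
def rig2():
    return make_camera_rig(2)


@pytest.fixture(scope="session")
def clean_pipeline(clean_truth, rig2):
    """Noiseless render -> triangulation -> pose fits for the clean strike."""
    obs = render_observations(clean_truth, rig2, pixel_noise_sd=0.0)
    trajs = triangulate_tracks(rig2, obs)
    body_pose = fit_body_plane(clean_truth.body_def, trajs)
    neuro_pose = fit_rigid_poses(clean_truth.neuro_def, trajs)
    return {
        "truth": clean_truth,
        "obs": obs,
        "trajs": trajs,
        "body_pose": body_pose,
        "neuro_pose": neuro_pose,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
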