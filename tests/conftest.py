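"""Shared fixtures: synthetic cameras, bead fixtures, fitted models, scenes.

All fixtures are generated programmatically and seeded; session scope keeps
the heavier calibration fits and scene renders to one evaluation each.
"""

import numpy as np
import pytest

import dyadtrack as dt


@pytest.fixture(scope="session")
def sim_config():
    return dt.SimConfig(seed=11, n_frames=300)


@pytest.fixture(scope="session")
def cameras(sim_config):
    return dt.make_cameras(sim_config)


@pytest.fixture(scope="session")
def beads(sim_config, cameras):
    return dt.make_bead_fixture(sim_config, cameras)


@pytest.fixture(scope="session")
def model(beads):
    return dt.fit_calibration(beads)


@pytest.fixture(scope="session")
def clean_scene(sim_config):
    """300 noise-free frames of a freely swimming dyad."""
    return dt.make_scene(sim_config)


@pytest.fixture(scope="session")
def affine_config():
    """Cameras without distortion: every calibration map is exactly affine."""
    return dt.SimConfig(seed=12, n_frames=100, camera_distortion_px=0.0)


@pytest.fixture(scope="session")
def affine_cameras(affine_config):
    return dt.make_cameras(affine_config)


@pytest.fixture(scope="session")
def affine_model(affine_config, affine_cameras):
    return dt.fit_calibration(dt.make_bead_fixture(affine_config, affine_cameras))


@pytest.fixture(scope="session")
def noisy_scene():
    """1 px detection noise, shuffled detection order, no other corruption."""
    return dt.make_scene(dt.SimConfig(seed=13, n_frames=200, noise_sigma_px=1.0))


@pytest.fixture()
def smooth_tracks():
    """A small clean TrackTable built directly from ground-truth kinematics."""
    cfg = dt.SimConfig(seed=14, n_frames=400)
    truth = dt.simulate_dyad(cfg)
    return dt.TrackTable(np.arange(cfg.n_frames), ("1", "2"), truth.copy())
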