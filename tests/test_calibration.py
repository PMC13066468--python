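"""Calibration: polynomial fitting, the five maps, round trips, errors."""

import numpy as np
import pytest

import dyadtrack as dt
from dyadtrack.calibration import (
    BeadSet,
    DegenerateGeometryError,
    PolyMap,
    UnderdeterminedFitError,
    n_monomials,
)


@pytest.mark.parametrize("input_dim,degree", [(3, 2), (4, 3), (6, 2)])
def test_polymap_parameter_recovery(input_dim, degree):
    """OLS on full-rank inputs recovers a generating polynomial exactly."""
    rng = np.random.default_rng(100 + input_dim + degree)
    m = n_monomials(input_dim, degree)
    gen = PolyMap(input_dim, 2, degree, rng.normal(size=(m, 2)))
    X = rng.uniform(-10, 10, (3 * m, input_dim))
    fit = PolyMap.fit(X, gen(X), degree)
    assert fit.rms_residual < 1e-8
    rel = np.abs(fit.raw_coefficients() - gen.coeffs) / np.abs(gen.coeffs).max()
    assert rel.max() < 1e-8


def test_five_maps_reproduce_heldout_beads(affine_config, affine_cameras):
    """Orthographic beads: all five maps reproduce held-out points ~exactly."""
    beads = dt.make_bead_fixture(affine_config, affine_cameras)
    train = BeadSet(
        world=beads.world[::2], images={v: p[::2] for v, p in beads.images.items()}
    )
    model = dt.fit_calibration(train)
    held_w = beads.world[1::2]
    held_img = np.stack([beads.images[v][1::2] for v in dt.VIEWS], axis=1)
    assert np.abs(dt.map_to_views(model, held_w) - held_img).max() < 1e-6
    assert np.abs(dt.map_to_world(model, held_img) - held_w).max() < 1e-6
    pred_xy = dt.map_views_pairwise(
        model, "XZ", "YZ", held_img[:, 2], held_img[:, 1]
    )
    assert np.abs(pred_xy - held_img[:, 0]).max() < 1e-6


def test_to_views_recovers_camera_coefficients(sim_config, cameras, model):
    """Fitted world->views map matches the generating degree-2 cameras."""
    gen = np.concatenate([cameras[v].coeffs for v in dt.VIEWS], axis=1)
    raw = model.to_views.raw_coefficients()
    assert np.abs(raw - gen).max() / np.abs(gen).max() < 1e-8


def test_world_roundtrip_on_bead_cloud(beads, model):
    """to_world o to_views is the identity on the bead cloud to < 1e-6 cm."""
    back = dt.map_to_world(model, dt.map_to_views(model, beads.world))
    assert np.abs(back - beads.world).max() < 1e-6


def test_view_roundtrip_on_bead_images(beads, model):
    """to_views o to_world returns the original image triplets (< 1e-3 px)."""
    img = np.stack([beads.images[v] for v in dt.VIEWS], axis=1)
    back = dt.map_to_views(model, dt.map_to_world(model, img))
    assert np.abs(back - img).max() < 1e-3


def test_pairwise_prediction_on_beads(beads, model):
    """(XZ, YZ) image points predict the XY point within the residual bound."""
    pred = dt.map_views_pairwise(
        model, "XZ", "YZ", beads.images["XZ"], beads.images["YZ"]
    )
    assert np.abs(pred - beads.images["XY"]).max() < 1e-6


def test_underdetermined_fit_raises(sim_config, cameras):
    """5 beads cannot determine 35 degree-3 view-map coefficients."""
    full = dt.make_bead_fixture(sim_config, cameras, n_orientations=1)
    keep = [0, 9, 23, 31, 46]  # spread over the grid: geometry is fine,
    tiny = BeadSet(  # the bead count is not
        world=full.world[keep], images={v: p[keep] for v, p in full.images.items()}
    )
    with pytest.raises(UnderdeterminedFitError, match="to_world|to_views|view_map"):
        dt.fit_calibration(tiny)
    # the view maps alone are also underdetermined: 5 beads < 35 monomials
    from dyadtrack.calibration import PolyMap

    with pytest.raises(UnderdeterminedFitError):
        PolyMap.fit(
            np.concatenate([tiny.images["XY"], tiny.images["YZ"]], axis=1),
            tiny.images["XZ"],
            3,
            "view_map_XZ",
        )


def test_coplanar_beads_rejected():
    """All beads at one height cannot constrain the vertical axis."""
    rng = np.random.default_rng(3)
    world = rng.uniform(-10, 10, (49, 3))
    world[:, 2] = 5.0
    with pytest.raises(DegenerateGeometryError):
        BeadSet(world=world, images={v: world[:, :2].copy() for v in dt.VIEWS})


def test_missing_coordinates_propagate(model):
    """NaN inputs yield NaN outputs through all three mapping operations."""
    triplet = np.array([[500.0, 400.0], [np.nan, 400.0], [500.0, 300.0]])
    assert np.isnan(dt.map_to_world(model, triplet)).all()
    assert np.isnan(dt.map_to_views(model, np.array([1.0, np.nan, 5.0]))).all()
    out = dt.map_views_pairwise(
        model, "XY", "YZ", np.array([np.nan, 1.0]), np.array([2.0, 3.0])
    )
    assert np.isnan(out).all()


def test_identical_source_views_rejected(model):
    with pytest.raises(ValueError, match="differ"):
        dt.map_views_pairwise(model, "XY", "XY", np.zeros(2), np.zeros(2))


def test_centroid_maps_to_centroid_under_exact_affine(affine_config, affine_cameras):
    """With exact affine cameras the fitted map is linear: it commutes with
    averaging, so the bead-cloud centroid maps to the world centroid."""
    beads = dt.make_bead_fixture(affine_config, affine_cameras)
    model = dt.fit_calibration(beads)
    img = np.stack([beads.images[v] for v in dt.VIEWS], axis=1)
    w_of_mean = dt.map_to_world(model, img.mean(axis=0))
    assert np.abs(w_of_mean - beads.world.mean(axis=0)).max() < 1e-6


def test_residual_grows_with_pixel_noise(sim_config, cameras):
    """RMS residual is monotone in i.i.d. Gaussian noise added to bead pixels."""
    beads = dt.make_bead_fixture(sim_config, cameras)
    rng = np.random.default_rng(4)
    resids = []
    for sigma in (0.0, 0.5, 2.0):
        noisy = BeadSet(
            world=beads.world,
            images={
                v: p + rng.normal(0, sigma, p.shape) for v, p in beads.images.items()
            },
        )
        resids.append(dt.fit_calibration(noisy).to_world.rms_residual)
    assert resids[0] < resids[1] < resids[2]


def test_model_json_roundtrip(tmp_path, model, beads):
    """Serialized model evaluates identically after reload."""
    path = tmp_path / "model.json"
    dt.save_calibration(model, path)
    loaded = dt.load_calibration(path)
    np.testing.assert_allclose(
        dt.map_to_world(loaded, np.stack([beads.images[v] for v in dt.VIEWS], axis=1)),
        dt.map_to_world(model, np.stack([beads.images[v] for v in dt.VIEWS], axis=1)),
        rtol=0,
        atol=1e-12,
    )
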