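"""QC: anatomy filters, jump classification, gap closing, smoothing."""

import numpy as np
import pytest

import dyadtrack as dt
from dyadtrack.fusion import (
    FLAG_FISH_JUMP,
    FLAG_HEAD_PEC_LEN,
    FLAG_ID_SWAP,
    FLAG_INTERPOLATED,
    FLAG_PEC_TAIL_LEN,
    FLAG_POINT_JUMP,
)
from dyadtrack.qc import (
    QcConfig,
    close_gaps_and_smooth,
    coverage_summary,
    detect_jumps,
    filter_anatomy,
)


def _table(n=20):
    """Straight-swimming dyad with exact segment lengths (0.8 / 1.7 cm)."""
    frames = np.arange(n)
    xyz = np.zeros((n, 2, 3, 3))
    for j, y in enumerate((0.0, 5.0)):
        x = 0.05 * frames
        xyz[:, j, 0] = np.stack([x + 0.8, np.full(n, y), np.full(n, 10.0)], axis=1)
        xyz[:, j, 1] = np.stack([x, np.full(n, y), np.full(n, 10.0)], axis=1)
        xyz[:, j, 2] = np.stack([x - 1.7, np.full(n, y), np.full(n, 10.0)], axis=1)
    return dt.TrackTable(frames, ("1", "2"), xyz)


@pytest.mark.parametrize(
    "point,offset,flag,removed",
    [
        ("head", 1.5, FLAG_HEAD_PEC_LEN, True),
        ("head", 1.3, FLAG_HEAD_PEC_LEN, False),
        ("tail", 2.6, FLAG_PEC_TAIL_LEN, True),
        ("tail", 2.4, FLAG_PEC_TAIL_LEN, False),
    ],
)
def test_anatomy_thresholds(point, offset, flag, removed):
    """Segments above 1.4 cm (head-pec) / 2.5 cm (pec-tail) are removed."""
    tab = _table()
    p = 0 if point == "head" else 2
    tab.xyz[5, 0, p] = tab.xyz[5, 0, 1] + np.array([offset, 0, 0])
    out = filter_anatomy(tab, QcConfig())
    assert (flag in out.flags[5, 0]) == removed
    assert np.isnan(out.xyz[5, 0, p]).all() == removed


def test_anatomy_filter_idempotent():
    tab = _table()
    tab.xyz[3, 1, 0] += 2.0
    once = filter_anatomy(tab, QcConfig())
    twice = filter_anatomy(once, QcConfig())
    np.testing.assert_array_equal(once.xyz, twice.xyz)
    assert all(
        once.flags[i, j] == twice.flags[i, j]
        for i in range(once.n_frames)
        for j in range(2)
    )


def test_all_missing_skeleton_unchanged():
    tab = _table()
    tab.xyz[7, 0] = np.nan
    out = filter_anatomy(tab, QcConfig())
    assert out.flags[7, 0] == set()


def test_smooth_tracks_produce_no_jump_flags(smooth_tracks):
    out = detect_jumps(smooth_tracks, QcConfig())
    assert all(not out.flags[i, j] for i in range(out.n_frames) for j in range(2))


def test_teleported_fish_flagged_alone():
    """One fish displaced 5 cm for one frame -> FISH_JUMP for that fish only."""
    tab = _table(30)
    tab.xyz[15, 0] += np.array([0.0, 5.0, 0.0])
    out = detect_jumps(tab, QcConfig())
    assert FLAG_FISH_JUMP in out.flags[15, 0]
    assert np.isnan(out.xyz[15, 0]).all()
    assert not out.flags[15, 1]


def test_injected_identity_swap_flags_both_fish():
    """Exchanging the two trajectories at a frame flags both as ID_SWAP."""
    tab = _table(30)
    tab.xyz[18:] = tab.xyz[18:, ::-1]
    out = detect_jumps(tab, QcConfig())
    assert FLAG_ID_SWAP in out.flags[18, 0] and FLAG_ID_SWAP in out.flags[18, 1]
    assert np.isnan(out.xyz[18]).all()
    assert not out.flags[17, 0] and not out.flags[19, 0]


def test_single_point_jump_flags_point_only():
    """A lone displaced body point is nulled without touching the fish."""
    tab = _table(30)
    tab.xyz[10, 1, 0] += np.array([0.0, 3.0, 0.0])
    out = detect_jumps(tab, QcConfig())
    assert FLAG_POINT_JUMP in out.flags[10, 1]
    assert np.isnan(out.xyz[10, 1, 0]).all()
    assert np.isfinite(out.xyz[10, 1, 1:]).all()


def test_gap_closing_respects_seven_frame_limit():
    """Gaps of 7 frames on a linear ramp are filled exactly; 8 are not."""
    tab = _table(60)
    tab.xyz[10:17, 0] = np.nan  # 7-frame gap
    tab.xyz[30:38, 0] = np.nan  # 8-frame gap
    out = close_gaps_and_smooth(tab, QcConfig(sg_window=3))  # minimal smoothing
    assert np.isfinite(out.xyz[10:17, 0]).all()
    assert all(FLAG_INTERPOLATED in out.flags[i, 0] for i in range(10, 17))
    assert np.isnan(out.xyz[30:38, 0]).all()
    # linear motion: interpolation is exact
    ref = _table(60)
    np.testing.assert_allclose(out.xyz[10:17, 0], ref.xyz[10:17, 0], atol=1e-9)


def test_boundary_gap_not_interpolated():
    tab = _table(20)
    tab.xyz[:3, 0] = np.nan
    tab.xyz[18:, 1] = np.nan
    out = close_gaps_and_smooth(tab, QcConfig())
    assert np.isnan(out.xyz[:3, 0]).all()
    assert np.isnan(out.xyz[18:, 1]).all()


def test_savgol_preserves_quadratic_signals():
    """An order-2 filter reproduces degree <= 2 polynomials exactly."""
    n = 100
    t = np.arange(n, dtype=float)
    xyz = np.zeros((n, 2, 3, 3))
    xyz[:, :, :, 0] = (0.001 * t**2 + 0.05 * t + 1.0)[:, None, None]
    xyz[:, :, :, 1] = 2.0
    xyz[:, :, :, 2] = (0.02 * t)[:, None, None]
    tab = dt.TrackTable(t.astype(int), ("1", "2"), xyz.copy())
    out = close_gaps_and_smooth(tab, QcConfig())
    np.testing.assert_allclose(out.xyz, xyz, atol=1e-9)


def test_savgol_impulse_support_is_window():
    """A unit impulse spreads over exactly sg_window frames."""
    n = 101
    xyz = np.zeros((n, 2, 3, 3))
    xyz[50, 0, 0, 0] = 1.0
    tab = dt.TrackTable(np.arange(n), ("1", "2"), xyz)
    cfg = QcConfig()
    out = close_gaps_and_smooth(tab, cfg)
    resp = out.xyz[:, 0, 0, 0]
    support = np.nonzero(np.abs(resp) > 1e-12)[0]
    assert support.size > 0
    assert support.max() - support.min() + 1 == cfg.sg_window


def test_short_segments_left_unsmoothed():
    tab = _table(20)
    tab.xyz[5:16, 0] = np.nan  # leaves a 5-frame head segment
    cfg = QcConfig()
    out = close_gaps_and_smooth(tab, cfg)
    np.testing.assert_array_equal(out.xyz[:5, 0], tab.xyz[:5, 0])


def test_coverage_counts_match_dropout_schedule():
    """Coverage bookkeeping equals a known corruption schedule."""
    tab = _table(50)
    tab.xyz[5:10, 0] = np.nan  # one fish absent: neither full nor empty
    tab.xyz[20:22] = np.nan  # both fish absent: empty
    cov = coverage_summary(tab)
    assert cov.n_frames_total == 50
    assert cov.n_frames_full == 50 - 5 - 2
    assert cov.n_frames_empty == 2


def test_full_and_empty_counts_on_clean_table():
    cov = coverage_summary(_table(25))
    assert cov.n_frames_full == 25 and cov.n_frames_empty == 0


def test_interpolation_respects_anatomy_at_flanks():
    """Linear interpolation between anatomically valid flanks cannot
    overshoot the flank segment lengths."""
    tab = _table(30)
    tab.xyz[12:15, 0] = np.nan
    out = close_gaps_and_smooth(tab, QcConfig(sg_window=3))
    hp = np.linalg.norm(out.xyz[:, 0, 0] - out.xyz[:, 0, 1], axis=-1)
    assert np.nanmax(hp) <= 1.4 + 1e-9


def test_qcconfig_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        QcConfig(sg_window=8)
    with pytest.raises(ValueError):
        QcConfig(head_pec_max_cm=-1.0)
    cfg = QcConfig(max_gap_frames=5)
    path = tmp_path / "qc.yaml"
    cfg.to_yaml(path)
    assert QcConfig.from_yaml(path) == cfg
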