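"""Quality control: anatomical filters, jump removal, gap closing, smoothing.

The pipeline order is fixed — registration/fusion thresholds are applied
during reconstruction; then, on the 3D tracks:

1. :func:`filter_anatomy` — null body points forming anatomically impossible
   segments (head-pec > 1.4 cm, pec-tail > 2.5 cm);
2. :func:`detect_jumps` — null teleport artifacts: simultaneous jumps of
   both fish (identity swap), whole-fish jumps and single-body-point jumps;
3. :func:`close_gaps_and_smooth` — fill gaps of up to 7 frames by linear
   interpolation, then Savitzky-Golay smoothing (order 2, window 9) on
   contiguous valid segments.

Jump detection must precede smoothing: smoothing spreads a teleport over
the filter window and would hide the velocity spike it is detected by.
:func:`apply_qc` runs the three stages in order and records per-stage
attrition in ``table.meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .fusion import (
    FLAG_FISH_JUMP,
    FLAG_HEAD_PEC_LEN,
    FLAG_ID_SWAP,
    FLAG_INTERPOLATED,
    FLAG_PEC_TAIL_LEN,
    FLAG_POINT_JUMP,
)
from .io import TrackTable


@dataclass
class QcConfig:
    """All tracking/QC thresholds, defaulting to the published pipeline.

    ``jump_speed_max_cm`` (cm per frame at ``fs_hz``) has no published
    value; the default 1.4 cm/frame (~5 body lengths per 9-frame smoothing
    window, i.e. ~200 cm/s) far exceeds burst-swim speeds while catching
    teleport artifacts.
    """

    reg_cost_max_px: float = 10.0
    fuse_cost_max_px: float = 15.0
    head_pec_max_cm: float = 1.4
    pec_tail_max_cm: float = 2.5
    max_gap_frames: int = 7
    sg_order: int = 2
    sg_window: int = 9
    jump_speed_max_cm: float = 1.4
    fs_hz: float = 140.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        for f in (
            "reg_cost_max_px",
            "fuse_cost_max_px",
            "head_pec_max_cm",
            "pec_tail_max_cm",
            "jump_speed_max_cm",
            "fs_hz",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "QcConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class CoverageSummary:
    """Frame bookkeeping after QC (cf. empty/full frame definitions)."""

    n_frames_total: int
    n_frames_full: int  # all three points present in 3D, both fish
    n_frames_empty: int  # no present body point for either fish
    flag_counts: dict = field(default_factory=dict)

    @property
    def full_fraction(self) -> float:
        return self.n_frames_full / self.n_frames_total if self.n_frames_total else 0.0

    @property
    def empty_fraction(self) -> float:
        return self.n_frames_empty / self.n_frames_total if self.n_frames_total else 0.0


def filter_anatomy(tracks: TrackTable, cfg: QcConfig) -> TrackTable:
    """Null body points of anatomically over-long segments (idempotent).

    Both endpoints of a violating segment are removed: when head-pec span
    exceeds the threshold there is no way to tell which of the two
    detections is the spurious one.
    """
    out = tracks.copy()
    xyz = out.xyz
    d_hp = np.linalg.norm(xyz[:, :, 0] - xyz[:, :, 1], axis=-1)  # (n, 2)
    d_pt = np.linalg.norm(xyz[:, :, 1] - xyz[:, :, 2], axis=-1)
    bad_hp = d_hp > cfg.head_pec_max_cm
    bad_pt = d_pt > cfg.pec_tail_max_cm
    for i, j in zip(*np.nonzero(bad_hp)):
        out.flags[i, j].add(FLAG_HEAD_PEC_LEN)
    for i, j in zip(*np.nonzero(bad_pt)):
        out.flags[i, j].add(FLAG_PEC_TAIL_LEN)
    xyz[bad_hp, 0] = np.nan
    xyz[bad_hp, 1] = np.nan
    xyz[bad_pt, 1] = np.nan
    xyz[bad_pt, 2] = np.nan
    return out


def _point_speeds(tracks: TrackTable) -> np.ndarray:
    """Per-point displacement speed (cm/frame), assigned to the later frame.

    Speed between consecutive *valid* samples of each body point, divided by
    the frame gap; NaN where undefined.  Shape (n_frames, 2, 3).
    """
    n = tracks.n_frames
    speeds = np.full((n, 2, 3), np.nan)
    frames = tracks.frames.astype(float)
    for j in range(2):
        for p in range(3):
            pos = tracks.xyz[:, j, p, :]
            valid = np.isfinite(pos).all(axis=1)
            idx = np.nonzero(valid)[0]
            if idx.size < 2:
                continue
            disp = np.linalg.norm(np.diff(pos[idx], axis=0), axis=1)
            gaps = np.diff(frames[idx])
            speeds[idx[1:], j, p] = disp / gaps
    return speeds


def _fish_speeds(tracks: TrackTable) -> np.ndarray:
    """Whole-fish speed (cm/frame): centroid displacement over the body
    points present in both of two consecutive frames with any detection.

    Robust to which points happen to be present; NaN where undefined.
    Shape (n_frames, 2).
    """
    n = tracks.n_frames
    out = np.full((n, 2), np.nan)
    frames = tracks.frames.astype(float)
    present = np.isfinite(tracks.xyz).all(axis=3)  # (n, 2, 3)
    for j in range(2):
        idx = np.nonzero(present[:, j].any(axis=1))[0]
        for a, b in zip(idx[:-1], idx[1:]):
            shared = present[a, j] & present[b, j]
            if not shared.any():
                continue
            disp = np.linalg.norm(
                tracks.xyz[b, j, shared].mean(axis=0)
                - tracks.xyz[a, j, shared].mean(axis=0)
            )
            out[b, j] = disp / (frames[b] - frames[a])
    return out


def detect_jumps(tracks: TrackTable, cfg: QcConfig) -> TrackTable:
    """Classify and null velocity-jump artifacts.

    A fish *jumps* at a frame when its whole-body speed (shared-point
    centroid displacement per frame) exceeds ``jump_speed_max_cm``: both
    fish jumping simultaneously is an identity swap, one fish jumping alone
    a single-fish jump; either way the affected skeletons are nulled.  A
    single body point whose own speed exceeds the bound while its fish does
    not jump (typical of head/tail misidentification during close contact)
    is nulled alone.
    """
    out = tracks.copy()
    speeds = _point_speeds(tracks)
    exceed = speeds > cfg.jump_speed_max_cm  # NaN compares False
    fish_jump = _fish_speeds(tracks) > cfg.jump_speed_max_cm
    id_swap = fish_jump[:, 0] & fish_jump[:, 1]
    for i in np.nonzero(id_swap)[0]:
        for j in range(2):
            out.flags[i, j].add(FLAG_ID_SWAP)
            out.xyz[i, j] = np.nan
    solo = fish_jump & ~id_swap[:, None]
    for i, j in zip(*np.nonzero(solo)):
        out.flags[i, j].add(FLAG_FISH_JUMP)
        out.xyz[i, j] = np.nan
    point_jump = exceed & ~fish_jump[:, :, None]
    for i, j, p in zip(*np.nonzero(point_jump)):
        out.flags[i, j].add(FLAG_POINT_JUMP)
        out.xyz[i, j, p] = np.nan
    return out


def close_gaps_and_smooth(tracks: TrackTable, cfg: QcConfig) -> TrackTable:
    """Linear interpolation of short gaps, then Savitzky-Golay smoothing.

    Gaps are runs of missing values per scalar coordinate; runs of length
    <= ``max_gap_frames`` with valid samples on both flanks are filled and
    flagged INTERPOLATED; boundary gaps are left missing.  Smoothing (order
    ``sg_order``, window ``sg_window``, edge handling by polynomial fit) is
    applied per coordinate on each contiguous valid segment at least one
    window long; shorter segments pass through unchanged.
    """
    out = tracks.copy()
    frames = tracks.frames.astype(float)
    n = tracks.n_frames
    for j in range(2):
        for p in range(3):
            for c in range(3):
                series = out.xyz[:, j, p, c]
                missing = ~np.isfinite(series)
                if missing.any() and not missing.all():
                    # enumerate missing runs
                    edges = np.diff(missing.astype(np.int8))
                    starts = list(np.nonzero(edges == 1)[0] + 1)
                    ends = list(np.nonzero(edges == -1)[0] + 1)
                    if missing[0]:
                        starts.insert(0, 0)
                    if missing[-1]:
                        ends.append(n)
                    for s, e in zip(starts, ends):
                        gap_frames = frames[e - 1] - frames[s] + 1 if e > s else 0
                        if s == 0 or e == n or gap_frames > cfg.max_gap_frames:
                            continue
                        series[s:e] = np.interp(
                            frames[s:e], [frames[s - 1], frames[e]], [series[s - 1], series[e]]
                        )
                        for i in range(s, e):
                            out.flags[i, j].add(FLAG_INTERPOLATED)
                # smooth contiguous valid segments
                valid = np.isfinite(series)
                idx = np.nonzero(valid)[0]
                if idx.size == 0:
                    continue
                breaks = np.nonzero(np.diff(idx) > 1)[0]
                seg_starts = np.concatenate(([0], breaks + 1))
                seg_ends = np.concatenate((breaks + 1, [idx.size]))
                for a, b in zip(seg_starts, seg_ends):
                    seg = idx[a:b]
                    if seg.size >= cfg.sg_window:
                        series[seg] = savgol_filter(
                            series[seg], cfg.sg_window, cfg.sg_order, mode="interp"
                        )
    return out


def apply_qc(tracks: TrackTable, cfg: QcConfig | None = None) -> TrackTable:
    """Run the fixed-order QC chain and record per-stage attrition in meta."""
    cfg = cfg or QcConfig()

    def n_points(t: TrackTable) -> int:
        return int(np.isfinite(t.xyz).all(axis=3).sum())

    stages = {}
    before = n_points(tracks)
    t = filter_anatomy(tracks, cfg)
    stages["anatomy_removed_points"] = before - n_points(t)
    before = n_points(t)
    t = detect_jumps(t, cfg)
    stages["jump_removed_points"] = before - n_points(t)
    before = n_points(t)
    t = close_gaps_and_smooth(t, cfg)
    stages["interpolated_points"] = n_points(t) - before
    t.meta["qc_config"] = cfg.to_dict()
    t.meta["qc_attrition"] = stages
    return t


def coverage_summary(tracks: TrackTable) -> CoverageSummary:
    """Count fully-reconstructed and empty frames and per-flag attrition."""
    present = np.isfinite(tracks.xyz).all(axis=3)  # (n, 2, 3)
    full = present.all(axis=(1, 2))
    empty = ~present.any(axis=(1, 2))
    counts: dict[str, int] = {}
    for i in range(tracks.n_frames):
        for j in range(2):
            for f in tracks.flags[i, j]:
                counts[f] = counts.get(f, 0) + 1
    return CoverageSummary(
        n_frames_total=tracks.n_frames,
        n_frames_full=int(full.sum()),
        n_frames_empty=int(empty.sum()),
        flag_counts=counts,
    )
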