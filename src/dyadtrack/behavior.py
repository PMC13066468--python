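"""Dyadic gaze analysis: gaze angles, windowed asymmetry, distances.

A fish's *gaze angle* toward its partner is the angle between its heading
vector (pec -> head) and the vector from its head to the partner's head,
in [0, 180] degrees.  A fish is "oriented toward" the partner when this
angle is within the cone half-width (default 20 degrees).  The gaze
asymmetry over an analysis window (default 2 minutes) is

    A_gaze = |N_1to2 - N_2to1| / N_total

with N_1to2 / N_2to1 the counts of frames in which fish 1 / fish 2 is
oriented toward the other and N_total the frames in the window where both
gaze angles are computable.  A_gaze is near 0 during mutual engagement and
rises toward 1 once one fish (the dominant) does all the looking.

Angles are computed in full 3D by default; ``mode="xy"`` projects to the
horizontal plane first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion import Skeleton3D
from .io import TrackTable

DEFAULT_CONE_DEG = 20.0
DEFAULT_WINDOW_S = 120.0


def _angles_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    out = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    out[(nu == 0) | (nv == 0)] = np.nan
    return out


def gaze_angles(tracks: TrackTable, mode: str = "3d") -> np.ndarray:
    """(n_frames, 2) gaze angle of each fish toward the other, degrees."""
    if mode not in ("3d", "xy"):
        raise ValueError("mode must be '3d' or 'xy'")
    head = tracks.point("head")  # (n, 2, 3)
    pec = tracks.point("pec")
    heading = head - pec
    to_other = head[:, ::-1, :] - head  # partner head - own head
    if mode == "xy":
        heading = heading.copy()
        to_other = to_other.copy()
        heading[..., 2] = 0.0
        to_other[..., 2] = 0.0
    return _angles_between(heading, to_other)


def gaze_angle(subject: Skeleton3D, target: Skeleton3D, mode: str = "3d") -> float:
    """Scalar gaze angle of one skeleton toward another (NaN if missing)."""
    heading = subject.head - subject.pec
    to_other = target.head - subject.head
    if mode == "xy":
        heading, to_other = heading.copy(), to_other.copy()
        heading[2] = 0.0
        to_other[2] = 0.0
    if not (np.isfinite(heading).all() and np.isfinite(to_other).all()):
        return float("nan")
    return float(_angles_between(heading[None], to_other[None])[0])


def head_to_head_distance(tracks: TrackTable) -> np.ndarray:
    """Per-frame 3D distance between the two heads, cm (NaN when missing)."""
    head = tracks.point("head")
    return np.linalg.norm(head[:, 0] - head[:, 1], axis=-1)


@dataclass
class GazeWindowStats:
    """Orientation counts and gaze asymmetry for one analysis window."""

    window_start_frame: int
    window_len_frames: int
    N_1to2: int
    N_2to1: int
    N_total: int

    @property
    def A_gaze(self) -> float:
        return asymmetry_from_counts(self.N_1to2, self.N_2to1, self.N_total)


def asymmetry_from_counts(n_1to2: int, n_2to1: int, n_total: int) -> float:
    """|N_1to2 - N_2to1| / N_total; NaN for an empty window."""
    if n_total <= 0:
        return float("nan")
    return abs(n_1to2 - n_2to1) / n_total


def gaze_asymmetry(
    tracks: TrackTable,
    window_start_frame: int,
    window_len_frames: int,
    cone_deg: float = DEFAULT_CONE_DEG,
    mode: str = "3d",
) -> GazeWindowStats:
    """Gaze asymmetry over one window of the track (frame-index units)."""
    lo = np.searchsorted(tracks.frames, window_start_frame)
    hi = np.searchsorted(tracks.frames, window_start_frame + window_len_frames)
    ang = gaze_angles(tracks, mode=mode)[lo:hi]
    both = np.isfinite(ang).all(axis=1)
    toward = (ang <= cone_deg) & both[:, None]
    return GazeWindowStats(
        window_start_frame=int(window_start_frame),
        window_len_frames=int(window_len_frames),
        N_1to2=int(toward[:, 0].sum()),
        N_2to1=int(toward[:, 1].sum()),
        N_total=int(both.sum()),
    )


def gaze_asymmetry_windows(
    tracks: TrackTable,
    fs_hz: float = 140.0,
    window_s: float = DEFAULT_WINDOW_S,
    stride_s: float | None = None,
    cone_deg: float = DEFAULT_CONE_DEG,
    mode: str = "3d",
) -> pd.DataFrame:
    """Windowed asymmetry series (non-overlapping windows by default)."""
    wlen = int(round(window_s * fs_hz))
    stride = wlen if stride_s is None else int(round(stride_s * fs_hz))
    first, last = int(tracks.frames[0]), int(tracks.frames[-1])
    rows = []
    for start in range(first, last - wlen + 2, stride):
        st = gaze_asymmetry(tracks, start, wlen, cone_deg=cone_deg, mode=mode)
        rows.append(
            {
                "window_start_frame": st.window_start_frame,
                "window_len_frames": st.window_len_frames,
                "time_s": (st.window_start_frame - first) / fs_hz,
                "N_1to2": st.N_1to2,
                "N_2to1": st.N_2to1,
                "N_total": st.N_total,
                "A_gaze": st.A_gaze,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GazeHistogram2D:
    """Joint normalized histogram of the two gaze angles."""

    edges: np.ndarray  # (n_bins + 1,) shared by both axes, degrees
    density: np.ndarray  # (n_bins, n_bins); axis 0 = theta_1to2, axis 1 = theta_2to1
    n_frames: int

    def transpose(self) -> "GazeHistogram2D":
        return GazeHistogram2D(self.edges, self.density.T, self.n_frames)


def gaze_histogram(
    tracks: TrackTable,
    frame_mask: np.ndarray | None = None,
    n_bins: int = 36,
    mode: str = "3d",
) -> GazeHistogram2D:
    """2D histogram of (theta_1to2, theta_2to1) over selected frames.

    Counts are normalized to sum to 1 over frames where both angles are
    computable; ``frame_mask`` selects a subset of frames (e.g. early/late
    recording phases).
    """
    ang = gaze_angles(tracks, mode=mode)
    sel = np.isfinite(ang).all(axis=1)
    if frame_mask is not None:
        sel &= np.asarray(frame_mask, dtype=bool)
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _, _ = np.histogram2d(ang[sel, 0], ang[sel, 1], bins=(edges, edges))
    n = int(sel.sum())
    density = counts / n if n else counts
    return GazeHistogram2D(edges=edges, density=density, n_frames=n)


def smooth_series(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average for display of asymmetry/distance curves."""
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    half = window // 2
    for i in range(v.size):
        seg = v[max(0, i - half) : i + half + 1]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = seg.mean()
    return out
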