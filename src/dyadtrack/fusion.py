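"""Detector fusion: whole-video identities and 3D reconstruction.

The registration step yields per-frame identity slots that are consistent
*across views* but not across time.  Global identity comes from the
top-view centroid tracker, which labels each fish for the whole video: a
registered skeleton is given the identity of the centroid nearest to its
top-view pec point, provided the match distance stays within the fusion
threshold (15 px).  Reconstruction then lifts each body point seen in all
three views to world coordinates through the calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationModel, map_to_world, map_views_pairwise, VIEWS
from .registration import FrameDetections, IdentityAssignment, _slot_points

#: Default cut on the pec-to-centroid match distance, px.
DEFAULT_FUSE_COST_MAX_PX = 15.0

# QC flag vocabulary shared by fusion, qc and io.
FLAG_REG_COST = "REG_COST"
FLAG_FUSE_COST = "FUSE_COST"
FLAG_HEAD_PEC_LEN = "HEAD_PEC_LEN"
FLAG_PEC_TAIL_LEN = "PEC_TAIL_LEN"
FLAG_ID_SWAP = "ID_SWAP"
FLAG_FISH_JUMP = "FISH_JUMP"
FLAG_POINT_JUMP = "POINT_JUMP"
FLAG_INTERPOLATED = "INTERPOLATED"
ALL_FLAGS = (
    FLAG_REG_COST,
    FLAG_FUSE_COST,
    FLAG_HEAD_PEC_LEN,
    FLAG_PEC_TAIL_LEN,
    FLAG_ID_SWAP,
    FLAG_FISH_JUMP,
    FLAG_POINT_JUMP,
    FLAG_INTERPOLATED,
)


@dataclass
class Skeleton3D:
    """One fish in world coordinates: (3, 3) head/pec/tail array in cm."""

    points: np.ndarray
    fish_id: str | None = None
    frame_index: int = -1
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(3, 3)

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def pec(self) -> np.ndarray:
        return self.points[1]

    @property
    def tail(self) -> np.ndarray:
        return self.points[2]


@dataclass
class FusionResult:
    """Outcome of matching identity slots to top-view centroid labels."""

    identities: dict[int, str | None]  # slot -> centroid label (None = unmatched)
    distances: dict[int, float]  # slot -> distance to nearest centroid, px
    rejected: dict[int, str] = field(default_factory=dict)  # over-threshold matches


def fuse_identity(
    frame: FrameDetections,
    assignment: IdentityAssignment,
    threshold_px: float = DEFAULT_FUSE_COST_MAX_PX,
) -> FusionResult:
    """Greedy pec-to-centroid matching, ascending by pixel distance.

    Each centroid claims at most one skeleton; pairs whose distance exceeds
    ``threshold_px`` are not matched but the nearest label is reported in
    ``rejected`` so the caller can record the removal against an identity.
    """
    P = _slot_points(frame, assignment.slots)
    pecs = {s: P["XY"][s][1] for s in (0, 1) if np.isfinite(P["XY"][s][1]).all()}
    cents = [(lab, np.asarray(p, dtype=float)) for lab, p in frame.top_view_centroids]
    identities: dict[int, str | None] = {0: None, 1: None}
    distances: dict[int, float] = {}
    rejected: dict[int, str] = {}
    if not cents or not pecs:
        return FusionResult(identities, distances, rejected)
    pairs = sorted(
        (
            (float(np.linalg.norm(pec - p)), slot, lab)
            for slot, pec in pecs.items()
            for lab, p in cents
        ),
        key=lambda t: t[0],
    )
    used_slots: set[int] = set()
    used_labels: set[str] = set()
    for d, slot, lab in pairs:
        if slot in used_slots or lab in used_labels:
            continue
        if d <= threshold_px:
            identities[slot] = lab
            used_labels.add(lab)
        else:
            rejected.setdefault(slot, lab)
        distances.setdefault(slot, d)
        used_slots.add(slot)
    return FusionResult(identities, distances, rejected)


def reconstruct_skeleton3d(
    frame: FrameDetections,
    assignment: IdentityAssignment,
    model: CalibrationModel,
    impute_missing_view: bool = False,
) -> tuple[Skeleton3D, Skeleton3D]:
    """Lift the two assigned skeletons to 3D (cm) through ``map_to_world``.

    A body point must be present in all three views; otherwise it is missing
    in 3D.  With ``impute_missing_view=True``, a point missing in exactly one
    view is first predicted from the other two via the view maps (off by
    default: reconstruction sticks to observed pixels).
    """
    P = _slot_points(frame, assignment.slots)
    out = []
    for slot in (0, 1):
        pts = np.stack([P[v][slot] for v in VIEWS])  # (3 views, 3 points, 2)
        if impute_missing_view:
            pts = pts.copy()
            for bp in range(3):
                present = [vi for vi in range(3) if np.isfinite(pts[vi, bp]).all()]
                if len(present) == 2:
                    missing = ({0, 1, 2} - set(present)).pop()
                    a, b = (VIEWS[present[0]], VIEWS[present[1]])
                    pts[missing, bp] = map_views_pairwise(
                        model, a, b, pts[present[0], bp], pts[present[1], bp]
                    )
        triplets = pts.transpose(1, 0, 2)  # (3 points, 3 views, 2)
        world = map_to_world(model, triplets)
        out.append(Skeleton3D(points=world, frame_index=frame.frame_index))
    return out[0], out[1]
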