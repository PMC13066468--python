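"""Cross-camera identity registration by exhaustive permutation search.

Per frame, each camera view reports up to two 3-point skeletons whose order
is arbitrary.  The registration step decides which detection in each view
belongs to which of the two identity *slots* (A = 0, B = 1) by enumerating
every candidate pairing and scoring it with a reprojection cost: with the
top view (XY) as the fixed reference, each side view serves in turn as a
source camera; a skeleton is projected from (XY, source) into the remaining
side view and from (XY, that prediction) back into the source view, and the
cost is the mean pixel distance between the reprojected and the detected
body points, averaged over present points, the two fish and the two source
cameras.  A consistent pairing reprojects onto itself; a swapped one does
not.  The lowest-cost candidate wins; frames whose best cost exceeds the
registration threshold (10 px) are marked discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .calibration import VIEWS, CalibrationModel, map_views_pairwise

#: Body point order used everywhere: head tip, pectoral-fin center, tail base.
BODY_POINTS: tuple[str, str, str] = ("head", "pec", "tail")

#: Default cut on the best cross-camera registration cost, px.
DEFAULT_REG_COST_MAX_PX = 10.0

_SIDES = ("YZ", "XZ")
_NO_SKELETON = np.full((3, 2), np.nan)


@dataclass
class Skeleton2D:
    """One fish in one view: head/pec/tail pixel coordinates, NaN = missing."""

    points: np.ndarray  # (3, 2)
    view: str
    detection_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(3, 2)
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if not np.isfinite(self.points).any():
            raise ValueError("a Skeleton2D must have at least one present point")

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
class FrameDetections:
    """All raw per-frame input: 0-2 skeletons per view + top-view centroids."""

    frame_index: int
    detections: Mapping[str, Sequence[Skeleton2D]]
    top_view_centroids: Sequence[tuple[str, np.ndarray]] = ()

    def __post_init__(self) -> None:
        self.detections = {v: list(self.detections.get(v, ())) for v in VIEWS}
        for v, dets in self.detections.items():
            if len(dets) > 2:
                raise ValueError(f"view {v}: at most two skeletons per frame")
        labels = [lab for lab, _ in self.top_view_centroids]
        if len(labels) != len(set(labels)):
            raise ValueError("centroid identity labels must be distinct")


@dataclass
class IdentityAssignment:
    """Winning per-view placement of detections into identity slots A/B.

    ``slots[view]`` is a pair giving, for slot A and slot B, the detection
    index assigned in that view (or None).
    """

    slots: dict[str, tuple[int | None, int | None]]
    cost: float
    n_candidates_evaluated: int
    discarded: bool = False
    empty: bool = False
    frame_index: int = -1
    all_costs: list[float] = field(default_factory=list, repr=False)


def _slot_points(
    frame: FrameDetections, slots: Mapping[str, tuple[int | None, int | None]]
) -> dict[str, list[np.ndarray]]:
    """(3, 2) point array per view per slot; all-NaN where unassigned."""
    out: dict[str, list[np.ndarray]] = {}
    for v in VIEWS:
        dets = frame.detections[v]
        pair = slots.get(v, (None, None))
        out[v] = [
            dets[i].points if i is not None and i < len(dets) else _NO_SKELETON
            for i in pair
        ]
    return out


def reprojection_cost(
    frame: FrameDetections,
    slots: Mapping[str, tuple[int | None, int | None]],
    model: CalibrationModel,
) -> float:
    """Average reprojection distance (px) of a candidate pairing.

    Averaged over present body points, then fish, then the scorable source
    cameras; NaN when no body point can be scored at all.
    """
    P = _slot_points(frame, slots)
    per_source = []
    for si, source in enumerate(_SIDES):
        third = _SIDES[1 - si]
        per_fish = []
        for slot in (0, 1):
            p_ref, p_src = P["XY"][slot], P[source][slot]
            usable = np.isfinite(p_ref).all(axis=1) & np.isfinite(p_src).all(axis=1)
            if not usable.any():
                continue
            pred_third = map_views_pairwise(model, "XY", source, p_ref, p_src)
            reproj = map_views_pairwise(model, "XY", third, p_ref, pred_third)
            d = np.linalg.norm(reproj - p_src, axis=1)
            d = d[np.isfinite(d)]
            if d.size:
                per_fish.append(float(d.mean()))
        if per_fish:
            per_source.append(float(np.mean(per_fish)))
    return float(np.mean(per_source)) if per_source else float("nan")


def _placements(n_dets: int, permute: bool) -> list[tuple[int | None, int | None]]:
    if n_dets == 0:
        return [(None, None)]
    if n_dets == 1:
        return [(0, None), (None, 0)] if permute else [(0, None)]
    return [(0, 1), (1, 0)] if permute else [(0, 1)]


def enumerate_candidates(
    frame: FrameDetections,
) -> list[dict[str, tuple[int | None, int | None]]]:
    """All candidate slot assignments: XY order is fixed as the reference,
    the two side views are permuted independently (2 x 2 = 4 for a full
    two-fish frame)."""
    opts = {
        v: _placements(len(frame.detections[v]), permute=(v != "XY")) for v in VIEWS
    }
    return [
        {"XY": xy, "YZ": yz, "XZ": xz}
        for xy, yz, xz in product(opts["XY"], opts["YZ"], opts["XZ"])
    ]


def register_frame(
    frame: FrameDetections,
    model: CalibrationModel,
    cost_threshold_px: float = DEFAULT_REG_COST_MAX_PX,
    prev: IdentityAssignment | None = None,
) -> IdentityAssignment:
    """Exhaustive search over candidate pairings; returns the cost minimizer.

    Ties (within 1e-9 px) are broken toward the previous frame's accepted
    assignment when one is given, else toward the lexicographically smallest
    placement.  The winner is flagged ``discarded`` when its cost exceeds
    ``cost_threshold_px``, and the assignment is ``empty`` when no candidate
    can be scored at all.
    """
    candidates = enumerate_candidates(frame)
    costs = [reprojection_cost(frame, c, model) for c in candidates]
    finite = [(c, cand) for c, cand in zip(costs, candidates) if np.isfinite(c)]
    if not finite:
        return IdentityAssignment(
            slots={v: (None, None) for v in VIEWS},
            cost=float("nan"),
            n_candidates_evaluated=len(candidates),
            empty=True,
            frame_index=frame.frame_index,
            all_costs=costs,
        )
    best_cost = min(c for c, _ in finite)
    tied = [cand for c, cand in finite if c <= best_cost + 1e-9]

    def _key(cand: dict) -> tuple:
        matches_prev = prev is not None and not prev.empty and all(
            cand[v] == prev.slots[v] for v in VIEWS
        )
        lex = tuple(tuple(-1 if i is None else i for i in cand[v]) for v in VIEWS)
        return (not matches_prev, lex)

    winner = min(tied, key=_key)
    return IdentityAssignment(
        slots=winner,
        cost=best_cost,
        n_candidates_evaluated=len(candidates),
        discarded=bool(best_cost > cost_threshold_px),
        frame_index=frame.frame_index,
        all_costs=costs,
    )
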