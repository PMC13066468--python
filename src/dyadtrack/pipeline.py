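"""End-to-end tracking: registration -> fusion -> 3D reconstruction -> QC."""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationModel
from .fusion import (
    FLAG_FUSE_COST,
    FLAG_REG_COST,
    fuse_identity,
    reconstruct_skeleton3d,
)
from .io import TrackTable
from .qc import QcConfig, apply_qc
from .registration import FrameDetections, register_frame


def reconstruct_tracks(
    frames: list[FrameDetections],
    model: CalibrationModel,
    config: QcConfig | None = None,
    fish_ids: tuple[str, str] | None = None,
    impute_missing_view: bool = False,
    run_qc: bool = True,
) -> TrackTable:
    """Run the whole pipeline over a frame stream and return 3D tracks.

    Per frame: exhaustive-search cross-camera registration (frames whose
    best cost exceeds ``reg_cost_max_px`` are kept but nulled and flagged
    REG_COST), top-view centroid fusion for whole-video identities (nearest
    pec/centroid match, cut at ``fuse_cost_max_px``; over-threshold matches
    are nulled and flagged FUSE_COST), then 3D reconstruction.  With
    ``run_qc`` the anatomy/jump/gap-and-smooth chain follows.
    """
    cfg = config or QcConfig()
    if fish_ids is None:
        seen: dict[str, None] = {}
        for f in frames:
            for lab, _ in f.top_view_centroids:
                seen.setdefault(str(lab), None)
        ids = list(seen)
        if len(ids) > 2:
            raise ValueError(f"more than two centroid identities: {ids}")
        while len(ids) < 2:
            ids.append(f"unlabeled_{len(ids)}")
        fish_ids = (ids[0], ids[1])
    col = {fid: j for j, fid in enumerate(fish_ids)}

    frame_idx = np.array([f.frame_index for f in frames], dtype=np.int64)
    table = TrackTable.empty(frame_idx, fish_ids)
    attrition = {"registered": 0, "reg_discarded": 0, "reg_empty": 0, "fuse_unmatched": 0, "fuse_rejected": 0}
    prev = None
    for i, frame in enumerate(frames):
        assignment = register_frame(
            frame, model, cost_threshold_px=cfg.reg_cost_max_px, prev=prev
        )
        if assignment.empty:
            attrition["reg_empty"] += 1
            continue
        prev = assignment if not assignment.discarded else prev
        fusion = fuse_identity(frame, assignment, threshold_px=cfg.fuse_cost_max_px)
        if assignment.discarded:
            attrition["reg_discarded"] += 1
        else:
            attrition["registered"] += 1
        sk = (
            None
            if assignment.discarded
            else reconstruct_skeleton3d(
                frame, assignment, model, impute_missing_view=impute_missing_view
            )
        )
        for slot in (0, 1):
            fid = fusion.identities[slot]
            if fid is None:
                rej = fusion.rejected.get(slot)
                if rej is not None and rej in col:
                    table.flags[i, col[rej]].add(FLAG_FUSE_COST)
                    attrition["fuse_rejected"] += 1
                else:
                    attrition["fuse_unmatched"] += 1
                continue
            j = col[fid]
            if assignment.discarded:
                table.flags[i, j].add(FLAG_REG_COST)
            else:
                table.xyz[i, j] = sk[slot].points
    table.meta["attrition"] = attrition
    table.meta["fish_ids"] = list(fish_ids)
    if run_qc:
        table = apply_qc(table, cfg)
        table.meta["attrition"] = attrition
    return table
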