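"""File formats: track tables, metadata, beads, detections, model JSON.

All on-disk formats are plain text (CSV / JSON / YAML).  The native track
schema is long-form CSV with two rows per frame (one per fish)::

    frame, fish_id, head_x, head_y, head_z, pec_x, ..., tail_z, flags

Coordinates are cm, missing values are empty cells and QC flags are a
``|``-joined set.  ``read_tracks_csv`` accepts a column-mapping dict so
externally produced track files with different headers can be adapted
without code changes; unknown extra columns are preserved opaquely and
written back on output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import VIEWS, CalibrationModel, PolyMap
from .registration import BODY_POINTS, FrameDetections, Skeleton2D

COORDS = ("x", "y", "z")
POINT_COLUMNS = tuple(f"{p}_{c}" for p in BODY_POINTS for c in COORDS)
TRACK_COLUMNS = ("frame", "fish_id") + POINT_COLUMNS + ("flags",)

CAGE_TYPES = ("circular", "square")
GENOTYPES = ("WT", "mecp2", "fgfr1a")


class TrackTable:
    """Per-fish, per-frame 3D skeleton time series with QC flags.

    Data layout: ``xyz`` is ``(n_frames, 2, 3, 3)`` — frame x fish x body
    point (head, pec, tail) x coordinate — NaN meaning missing; ``flags`` is
    an ``(n_frames, 2)`` object array of flag-string sets.
    """

    def __init__(
        self,
        frames: np.ndarray,
        fish_ids: tuple[str, str],
        xyz: np.ndarray,
        flags: np.ndarray | None = None,
        meta: dict | None = None,
        extras: pd.DataFrame | None = None,
    ):
        self.frames = np.asarray(frames, dtype=np.int64)
        if self.frames.ndim != 1:
            raise ValueError("frames must be 1-D")
        if self.frames.size > 1 and not (np.diff(self.frames) > 0).all():
            bad = int(np.argmax(np.diff(self.frames) <= 0)) + 1
            raise ValueError(f"frame indices must be strictly increasing (index {bad})")
        if len(fish_ids) != 2 or len(set(fish_ids)) != 2:
            raise ValueError("exactly two distinct fish ids are required")
        self.fish_ids = (str(fish_ids[0]), str(fish_ids[1]))
        self.xyz = np.asarray(xyz, dtype=float)
        if self.xyz.shape != (self.frames.size, 2, 3, 3):
            raise ValueError(
                f"xyz must be (n_frames, 2, 3, 3); got {self.xyz.shape}"
            )
        if flags is None:
            flags = np.empty((self.frames.size, 2), dtype=object)
            for i in range(self.frames.size):
                for j in range(2):
                    flags[i, j] = set()
        self.flags = flags
        self.meta = dict(meta or {})
        self.extras = extras

    # ---------------------------------------------------------------- basics
    @property
    def n_frames(self) -> int:
        return self.frames.size

    def copy(self) -> "TrackTable":
        flags = np.empty_like(self.flags)
        for idx in np.ndindex(self.flags.shape):
            flags[idx] = set(self.flags[idx])
        return TrackTable(
            self.frames.copy(),
            self.fish_ids,
            self.xyz.copy(),
            flags,
            dict(self.meta),
            None if self.extras is None else self.extras.copy(),
        )

    @classmethod
    def empty(cls, frames: np.ndarray, fish_ids=("1", "2")) -> "TrackTable":
        frames = np.asarray(frames, dtype=np.int64)
        return cls(frames, tuple(fish_ids), np.full((frames.size, 2, 3, 3), np.nan))

    def point(self, name: str) -> np.ndarray:
        """(n_frames, 2, 3) coordinates of one named body point."""
        return self.xyz[:, :, BODY_POINTS.index(name), :]

    # ----------------------------------------------------------- dataframes
    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_frames
        rows = {
            "frame": np.repeat(self.frames, 2),
            "fish_id": np.tile(np.asarray(self.fish_ids, dtype=object), n),
        }
        flat = self.xyz.reshape(n * 2, 9)
        for k, col in enumerate(POINT_COLUMNS):
            rows[col] = flat[:, k]
        rows["flags"] = [
            "|".join(sorted(self.flags[i, j])) for i in range(n) for j in range(2)
        ]
        df = pd.DataFrame(rows)
        if self.extras is not None:
            df = pd.concat([df, self.extras.reset_index(drop=True)], axis=1)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, column_map: dict | None = None
    ) -> "TrackTable":
        if column_map:
            df = df.rename(columns=column_map)
        missing = [c for c in TRACK_COLUMNS if c not in df.columns and c != "flags"]
        if missing:
            raise ValueError(f"track table is missing columns {missing}")
        fish_ids = tuple(dict.fromkeys(df["fish_id"].astype(str)))
        if len(fish_ids) != 2:
            raise ValueError(f"expected exactly two fish ids, found {fish_ids}")
        frames = np.asarray(sorted(dict.fromkeys(df["frame"].astype(int))))
        n = frames.size
        order = {f: i for i, f in enumerate(frames)}
        xyz = np.full((n, 2, 3, 3), np.nan)
        flags = np.empty((n, 2), dtype=object)
        for i in range(n):
            for j in range(2):
                flags[i, j] = set()
        fish_pos = {fid: j for j, fid in enumerate(fish_ids)}
        fi = df["frame"].astype(int).map(order).to_numpy()
        fj = df["fish_id"].astype(str).map(fish_pos).to_numpy()
        vals = df[list(POINT_COLUMNS)].to_numpy(dtype=float)
        xyz[fi, fj] = vals.reshape(-1, 3, 3)
        if "flags" in df.columns:
            for r, s in enumerate(df["flags"].fillna("")):
                if s:
                    flags[fi[r], fj[r]] |= set(str(s).split("|"))
        extra_cols = [c for c in df.columns if c not in TRACK_COLUMNS]
        extras = df[extra_cols].copy() if extra_cols else None
        return cls(frames, fish_ids, xyz, flags, extras=extras)


def write_tracks_csv(table: TrackTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_tracks_csv(path, column_map: dict | None = None) -> TrackTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    # Name the offending row (1-based data row) for non-monotone frames.
    fr = df["frame"].to_numpy()
    per_frame = fr[::2] if (len(fr) >= 2 and fr[0] == fr[1]) else fr
    dec = np.nonzero(np.diff(per_frame) < 0)[0]
    if dec.size:
        row = int(dec[0]) + 1
        raise ValueError(f"frame column decreases at data row {row}")
    return TrackTable.from_dataframe(df)


# ------------------------------------------------------------------ metadata
@dataclass
class ExperimentMeta:
    """One dataset recording: id, date, sex, cage shape and genotype."""

    experiment_id: str
    date: str
    sex: str
    cage_type: str
    genotype: str

    def __post_init__(self) -> None:
        for f in ("experiment_id", "date", "sex", "cage_type", "genotype"):
            if not str(getattr(self, f)).strip():
                raise ValueError(f"metadata field {f!r} must be non-empty")
        if self.cage_type not in CAGE_TYPES:
            raise ValueError(
                f"cage_type must be one of {CAGE_TYPES}, got {self.cage_type!r}"
            )
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}"
            )


def read_metadata_csv(path) -> list[ExperimentMeta]:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    df.columns = [c.strip().lower() for c in df.columns]
    return [
        ExperimentMeta(
            experiment_id=row["experiment_id"],
            date=row["date"],
            sex=row["sex"],
            cage_type=row["cage_type"],
            genotype=row["genotype"],
        )
        for _, row in df.iterrows()
    ]


def write_metadata_csv(records: list[ExperimentMeta], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


# ------------------------------------------------------------------ beads
def write_beads_csv(beads, path) -> None:
    from .calibration import BeadSet  # local import to keep module load light

    assert isinstance(beads, BeadSet)
    cols = {"bead_id": np.arange(beads.n_beads)}
    for ax, name in zip(range(3), ("X", "Y", "Z")):
        cols[name] = beads.world[:, ax]
    for v in VIEWS:
        cols[f"{v.lower()}_u"] = beads.images[v][:, 0]
        cols[f"{v.lower()}_v"] = beads.images[v][:, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_beads_csv(path):
    from .calibration import BeadSet

    df = pd.read_csv(path, float_precision="round_trip")
    world = df[["X", "Y", "Z"]].to_numpy(dtype=float)
    images = {
        v: df[[f"{v.lower()}_u", f"{v.lower()}_v"]].to_numpy(dtype=float)
        for v in VIEWS
    }
    return BeadSet(world=world, images=images)


# --------------------------------------------------------------- detections
def detections_to_dataframe(frames: list[FrameDetections]) -> pd.DataFrame:
    rows = []
    for f in frames:
        for v in VIEWS:
            for det in f.detections[v]:
                row = {"frame": f.frame_index, "view": v, "detection_index": det.detection_index}
                for k, p in enumerate(BODY_POINTS):
                    row[f"{p}_u"], row[f"{p}_v"] = det.points[k]
                rows.append(row)
    cols = ["frame", "view", "detection_index"] + [
        f"{p}_{ax}" for p in BODY_POINTS for ax in ("u", "v")
    ]
    return pd.DataFrame(rows, columns=cols)


def centroids_to_dataframe(frames: list[FrameDetections]) -> pd.DataFrame:
    rows = [
        {"frame": f.frame_index, "identity": lab, "u": p[0], "v": p[1]}
        for f in frames
        for lab, p in f.top_view_centroids
    ]
    return pd.DataFrame(rows, columns=["frame", "identity", "u", "v"])


def read_detections_csv(det_path, centroid_path=None) -> list[FrameDetections]:
    """Rebuild per-frame detection bundles from the tabular schemas."""
    df = pd.read_csv(det_path, float_precision="round_trip")
    cents: dict[int, list] = {}
    if centroid_path is not None:
        cdf = pd.read_csv(centroid_path, dtype={"identity": str}, float_precision="round_trip")
        for _, r in cdf.iterrows():
            cents.setdefault(int(r["frame"]), []).append(
                (str(r["identity"]), np.array([r["u"], r["v"]], dtype=float))
            )
    frames: dict[int, dict[str, list]] = {}
    for _, r in df.iterrows():
        fr = int(r["frame"])
        pts = np.array(
            [[r[f"{p}_u"], r[f"{p}_v"]] for p in BODY_POINTS], dtype=float
        )
        det = Skeleton2D(points=pts, view=str(r["view"]), detection_index=int(r["detection_index"]))
        frames.setdefault(fr, {v: [] for v in VIEWS})[str(r["view"])].append(det)
    all_frames = sorted(set(frames) | set(cents))
    return [
        FrameDetections(
            frame_index=fr,
            detections=frames.get(fr, {v: [] for v in VIEWS}),
            top_view_centroids=cents.get(fr, []),
        )
        for fr in all_frames
    ]


# ------------------------------------------------------------- model (JSON)
def save_calibration(model: CalibrationModel, path) -> None:
    def dump(m: PolyMap) -> dict:
        return {
            "input_dim": m.input_dim,
            "output_dim": m.output_dim,
            "degree": m.degree,
            "coeffs": m.coeffs.tolist(),
            "offset": m.offset.tolist(),
            "scale": m.scale.tolist(),
            "rms_residual": m.rms_residual,
        }

    doc = {
        "to_world": dump(model.to_world),
        "to_views": dump(model.to_views),
        "view_maps": {v: dump(m) for v, m in model.view_maps.items()},
        "fitted_on": model.fitted_on,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_calibration(path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())

    def load(d: dict) -> PolyMap:
        return PolyMap(
            input_dim=d["input_dim"],
            output_dim=d["output_dim"],
            degree=d["degree"],
            coeffs=np.asarray(d["coeffs"], dtype=float),
            offset=np.asarray(d["offset"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            rms_residual=d["rms_residual"],
        )

    return CalibrationModel(
        to_world=load(doc["to_world"]),
        to_views=load(doc["to_views"]),
        view_maps={v: load(d) for v, d in doc["view_maps"].items()},
        fitted_on=doc.get("fitted_on", {}),
    )
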