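"""Ground-truthed synthetic data for every pipeline stage.

This module stands in for the hardware stack (cameras, pose detector,
centroid tracker): it simulates smooth 3D dyad kinematics inside the cage,
projects them through synthetic polynomial cameras, corrupts the resulting
2D detections the way real detectors do (pixel noise, dropouts, head/tail
confusions, identity-label swaps) and emits the same tables the pipeline
reads — together with an injection log that records every corruption, so
each downstream filter can be verified against ground truth.

Everything is deterministic per seed: the same :class:`SimConfig` always
produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .calibration import VIEWS, VIEW_AXES, BeadSet, PolyMap, monomial_powers
from .registration import FrameDetections, IdentityAssignment, Skeleton2D

_GOLDEN = 0.6180339887498949


@dataclass
class SimConfig:
    """Study conditions for the synthetic dyad.

    Geometry mirrors the recording rig: a 25 cm cubic cage inside a
    40 x 40 x 44 cm tank, 140 Hz sampling, ~2.5 cm adult fish imaged at
    ~36 px/cm (body length ~ 90 px), 1280 x 1024 sensors.  Corruption rates
    default to zero; each one is independently switchable.
    """

    seed: int = 0
    n_frames: int = 1000
    fs_hz: float = 140.0
    cage_cm: tuple = (25.0, 25.0, 25.0)
    tank_cm: tuple = (40.0, 40.0, 44.0)
    body_length_cm: float = 2.5
    head_pec_cm: float = 0.8
    pec_tail_cm: float = 1.7
    pixel_scale: float = 36.0  # px per cm (body length ~ 90 px)
    image_size: tuple = (1280, 1024)
    noise_sigma_px: float = 0.0
    dropout_rate: float = 0.0
    part_confusion_rate: float = 0.0
    swap_rate: float = 0.0
    pursuit_mode: bool = False
    pursuit_switch_frame: int | None = None
    pursuit_gain: float = 0.6
    cruise_speed_cm: float = 0.05  # cm per frame (~7 cm/s at 140 Hz)
    turn_sigma: float = 0.1
    turn_max_rad: float = 0.25  # per-frame turn-rate cap (bodies rotate smoothly)
    min_separation_cm: float = 2.0
    camera_distortion_px: float = 0.1  # mild quadratic distortion at volume edge
    camera_mismatch_px: float = 0.0  # extra cubic terms (model-mismatch mode)
    n_bead_orientations: int = 4

    def __post_init__(self) -> None:
        for f in ("dropout_rate", "part_confusion_rate", "swap_rate"):
            r = getattr(self, f)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {r}")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("cage_cm", "tank_cm", "image_size"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


# ------------------------------------------------------------------ cameras
def make_cameras(cfg: SimConfig) -> dict[str, PolyMap]:
    """Synthetic camera projections, one per view, as explicit PolyMaps.

    Each camera is an exact polynomial: an orthographic projection of the two
    world axes the view images (``pixel_scale`` px/cm, pixel origin top-left,
    v axis pointing down) plus mild quadratic distortion
    (``camera_distortion_px``) and, when ``camera_mismatch_px`` > 0, cubic
    terms that no degree-2 calibration can absorb.
    """
    degree = 3 if cfg.camera_mismatch_px > 0 else 2
    powers = monomial_powers(3, degree)
    rng = np.random.default_rng([int(cfg.seed), 101])
    s = cfg.pixel_scale
    cx, cy = cfg.image_size[0] / 2.0, cfg.image_size[1] / 2.0
    z_mid = cfg.cage_cm[2] / 2.0
    L = max(cfg.tank_cm) / 2.0
    cameras: dict[str, PolyMap] = {}
    for v in VIEWS:
        a0, a1 = VIEW_AXES[v]
        m = powers.shape[0]
        coeffs = np.zeros((m, 2))
        # constant term is row 0, pure linear terms rows 1..3
        center1 = 0.0 if v == "XY" else z_mid  # side views image z, centered mid-cage
        coeffs[0] = (cx, cy + s * center1)
        coeffs[1 + a0, 0] = s
        coeffs[1 + a1, 1] = -s
        deg_of_row = powers.sum(axis=1)
        quad = deg_of_row == 2
        # normalized so the summed edge-of-volume effect <= camera_distortion_px
        coeffs[quad] += (
            cfg.camera_distortion_px
            * rng.uniform(-1.0, 1.0, (int(quad.sum()), 2))
            / (quad.sum() * L**2)
        )
        cubic = deg_of_row == 3
        if cubic.any():
            coeffs[cubic] += (
                cfg.camera_mismatch_px
                * rng.uniform(-1.0, 1.0, (int(cubic.sum()), 2))
                / (cubic.sum() * L**3)
            )
        cameras[v] = PolyMap(
            input_dim=3, output_dim=2, degree=degree, coeffs=coeffs, rms_residual=0.0
        )
    return cameras


def project_points(cameras: dict[str, PolyMap], points: np.ndarray) -> np.ndarray:
    """Project (n, 3) world points into all views -> (n, 3 views, 2) px."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.stack([cameras[v](pts) for v in VIEWS], axis=1)


# -------------------------------------------------------------- bead fixture
def make_bead_fixture(
    cfg: SimConfig,
    cameras: dict[str, PolyMap] | None = None,
    n_orientations: int | None = None,
) -> BeadSet:
    """The 49-bead calibration fixture photographed in several orientations.

    Beads sit on a 7 x 7 horizontal grid (3.5 cm pitch) at staggered,
    non-coplanar heights spanning the cage; each orientation rotates the
    board about the vertical axis and all orientations are pooled into one
    correspondence set with projections under the synthetic cameras.
    """
    cameras = cameras or make_cameras(cfg)
    n_orientations = n_orientations or cfg.n_bead_orientations
    g = np.linspace(-10.5, 10.5, 7)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    idx = np.arange(49, dtype=float)
    zz = 2.0 + 20.0 * ((_GOLDEN * (idx + 1.0)) % 1.0)
    base = np.column_stack([xx.ravel(), yy.ravel(), zz])
    worlds = []
    for k in range(max(1, n_orientations)):
        ang = np.deg2rad(35.0 * k)
        c, s = np.cos(ang), np.sin(ang)
        rot = base.copy()
        rot[:, 0] = c * base[:, 0] - s * base[:, 1]
        rot[:, 1] = s * base[:, 0] + c * base[:, 1]
        worlds.append(rot)
    world = np.concatenate(worlds, axis=0)
    proj = project_points(cameras, world)  # (n, 3, 2)
    images = {v: proj[:, i, :] for i, v in enumerate(VIEWS)}
    return BeadSet(world=world, images=images)


# ---------------------------------------------------------------- kinematics
def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n == 0, 1.0, n)


def _rotate_towards(a: np.ndarray, b: np.ndarray, max_rad: float) -> np.ndarray:
    """Rotate each unit row of ``a`` toward ``b`` by at most ``max_rad``.

    Spherical interpolation; keeps heading changes (and therefore head/tail
    marker displacements) continuous even when a wall bounce reverses the
    desired direction.
    """
    out = np.empty_like(a)
    for k in range(a.shape[0]):
        c = float(np.clip(np.dot(a[k], b[k]), -1.0, 1.0))
        ang = np.arccos(c)
        if ang <= max_rad:
            out[k] = b[k]
        elif ang > np.pi - 1e-6:
            # antiparallel: veer off through an arbitrary perpendicular
            perp = np.cross(a[k], [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(a[k], [1.0, 0.0, 0.0])
            out[k] = np.cos(max_rad) * a[k] + np.sin(max_rad) * perp / np.linalg.norm(perp)
        else:
            t = max_rad / ang
            s = np.sin(ang)
            out[k] = (np.sin((1 - t) * ang) * a[k] + np.sin(t * ang) * b[k]) / s
    return _normalize(out)


def simulate_dyad(cfg: SimConfig) -> np.ndarray:
    """Ground-truth 3D skeletons, shape (n_frames, 2 fish, 3 points, 3).

    A smoothed correlated random walk with reflective cage boundaries:
    heading directions diffuse on the sphere (vertical component damped),
    speed jitters around cruise, and the tail direction lags the heading so
    the skeleton bends naturally while keeping rigid segment lengths.  Soft
    repulsion keeps the pair at least ``min_separation_cm`` apart.  In
    pursuit mode fish 1 steers toward fish 2's head after the switch frame,
    producing the one-sided gaze statistics of an established dominance.
    """
    rng = np.random.default_rng([int(cfg.seed), 7])
    n = cfg.n_frames
    margin = cfg.head_pec_cm + cfg.pec_tail_cm + 0.3
    half = np.asarray(cfg.cage_cm, dtype=float) / 2.0
    lo = np.array([-half[0], -half[1], 0.0]) + margin
    hi = np.array([half[0], half[1], cfg.cage_cm[2]]) - margin
    switch = (
        cfg.pursuit_switch_frame
        if cfg.pursuit_switch_frame is not None
        else n // 2
    )
    pos = np.array([[-4.0, -2.0, 10.0], [4.0, 2.0, 14.0]])
    h = _normalize(rng.normal(size=(2, 3)) * np.array([1.0, 1.0, 0.3]))
    tail_dir = h.copy()
    out = np.empty((n, 2, 3, 3))
    for t in range(n):
        noise = rng.normal(0.0, cfg.turn_sigma, (2, 3))
        noise[:, 2] *= 0.3
        h_des = _normalize(h + noise)
        if cfg.pursuit_mode and t >= switch:
            head0 = pos[0] + cfg.head_pec_cm * h[0]
            head1 = pos[1] + cfg.head_pec_cm * h[1]
            target = _normalize(head1 - head0)
            h_des[0] = _normalize(
                (1.0 - cfg.pursuit_gain) * h_des[0] + cfg.pursuit_gain * target
            )
        h = _rotate_towards(h, h_des, cfg.turn_max_rad)
        speed = cfg.cruise_speed_cm * np.clip(
            1.0 + 0.3 * rng.standard_normal(2), 0.2, 2.0
        )
        pos = pos + h * speed[:, None]
        below, above = pos < lo, pos > hi
        pos = np.where(below, 2 * lo - pos, pos)
        pos = np.where(above, 2 * hi - pos, pos)
        h_des = np.where(below, np.abs(h), h)
        h_des = np.where(above, -np.abs(h_des), h_des)
        h = _rotate_towards(h, _normalize(h_des), cfg.turn_max_rad)
        d = pos[0] - pos[1]
        dist = float(np.linalg.norm(d))
        if 0.0 < dist < cfg.min_separation_cm:
            push = 0.5 * (cfg.min_separation_cm - dist) * d / dist
            pos = np.clip(pos + np.array([push, -push]), lo, hi)
        tail_dir = _normalize(0.8 * tail_dir + 0.2 * h)
        out[t, :, 1] = pos
        out[t, :, 0] = pos + cfg.head_pec_cm * h
        out[t, :, 2] = pos - cfg.pec_tail_cm * tail_dir
    return out


# ------------------------------------------------------------------- scenes
@dataclass
class SyntheticScene:
    """A rendered recording: truth, corrupted detections and the oracle log.

    ``det_px`` stays in *truth-fish order*; ``perm[t, view, k]`` gives the
    truth fish shown as detection slot k in that view, emulating the
    arbitrary per-frame detection order of a real pose detector.
    ``centroid_label_idx[t, f]`` maps truth fish f to its centroid label
    (swap injections toggle this mapping).
    """

    config: SimConfig
    cameras: dict[str, PolyMap]
    truth: np.ndarray  # (n, 2, 3, 3) world cm
    det_px: np.ndarray  # (n, 3 views, 2 fish, 3 points, 2) px, NaN = dropped
    perm: np.ndarray  # (n, 3, 2) detection order
    centroid_px: np.ndarray  # (n, 2, 2) px, truth-fish order
    centroid_label_idx: np.ndarray  # (n, 2) int
    labels: tuple = ("1", "2")
    injection_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_frames(self) -> int:
        return self.truth.shape[0]

    def frame(self, t: int) -> FrameDetections:
        dets: dict[str, list[Skeleton2D]] = {}
        for vi, v in enumerate(VIEWS):
            lst = []
            for k in range(2):
                fish = int(self.perm[t, vi, k])
                pts = self.det_px[t, vi, fish]
                if np.isfinite(pts).any():
                    lst.append(
                        Skeleton2D(points=pts.copy(), view=v, detection_index=len(lst))
                    )
            dets[v] = lst
        cents = [
            (self.labels[int(self.centroid_label_idx[t, f])], self.centroid_px[t, f])
            for f in range(2)
        ]
        return FrameDetections(frame_index=t, detections=dets, top_view_centroids=cents)

    def frames(self) -> list[FrameDetections]:
        return [self.frame(t) for t in range(self.n_frames)]

    def detection_truth(self, t: int) -> dict[str, list[int]]:
        """Truth fish index behind each detection slot, per view."""
        out: dict[str, list[int]] = {}
        for vi, v in enumerate(VIEWS):
            ids = []
            for k in range(2):
                fish = int(self.perm[t, vi, k])
                if np.isfinite(self.det_px[t, vi, fish]).any():
                    ids.append(fish)
            out[v] = ids
        return out

    def assignment_correct(self, t: int, assignment: IdentityAssignment) -> bool:
        """Whether an assignment groups detections consistently by truth fish."""
        truth_ids = self.detection_truth(t)
        per_slot: list[set[int]] = [set(), set()]
        for v in VIEWS:
            for slot in (0, 1):
                i = assignment.slots[v][slot]
                if i is not None and i < len(truth_ids[v]):
                    per_slot[slot].add(truth_ids[v][i])
        if any(len(s) > 1 for s in per_slot):
            return False
        return not (per_slot[0] and per_slot[1] and per_slot[0] == per_slot[1])


def render_detections(
    truth: np.ndarray, cameras: dict[str, PolyMap], cfg: SimConfig
) -> SyntheticScene:
    """Project truth through the cameras and apply detector corruption.

    Corruption order: Gaussian pixel noise, head/tail confusion (per fish,
    view and frame), per-point dropout, then per-view detection-order
    shuffling; top-view centroids are noisy pec projections with persistent
    identity labels whose mapping toggles at injected swap frames.  Every
    injection is logged with its target.
    """
    rng = np.random.default_rng([int(cfg.seed), 13])
    n = truth.shape[0]
    flat = truth.reshape(-1, 3)
    det = np.stack(
        [cameras[v](flat).reshape(n, 2, 3, 2) for v in VIEWS], axis=1
    )  # (n, 3, 2, 3, 2)
    if cfg.noise_sigma_px > 0:
        det = det + rng.normal(0.0, cfg.noise_sigma_px, det.shape)
    log: list[dict] = []
    if cfg.part_confusion_rate > 0:
        conf = rng.random((n, 3, 2)) < cfg.part_confusion_rate
        for t, vi, f in zip(*np.nonzero(conf)):
            det[t, vi, f, [0, 2]] = det[t, vi, f, [2, 0]]
            log.append(
                {"frame": int(t), "kind": "part_confusion", "view": VIEWS[vi], "fish": int(f), "point": ""}
            )
    if cfg.dropout_rate > 0:
        drop = rng.random((n, 3, 2, 3)) < cfg.dropout_rate
        det[drop] = np.nan
        for t, vi, f, p in zip(*np.nonzero(drop)):
            log.append(
                {"frame": int(t), "kind": "dropout", "view": VIEWS[vi], "fish": int(f), "point": ["head", "pec", "tail"][p]}
            )
    perm = np.argsort(rng.random((n, 3, 2)), axis=2)
    cent = cameras["XY"](truth[:, :, 1, :].reshape(-1, 3)).reshape(n, 2, 2)
    if cfg.noise_sigma_px > 0:
        cent = cent + rng.normal(0.0, cfg.noise_sigma_px, cent.shape)
    label_idx = np.zeros((n, 2), dtype=np.int64)
    state = np.array([0, 1])
    toggles = rng.random(n) < cfg.swap_rate
    for t in range(n):
        if toggles[t]:
            state = state[::-1]
            log.append(
                {"frame": int(t), "kind": "id_swap", "view": "XY", "fish": -1, "point": ""}
            )
        label_idx[t] = state
    log_df = pd.DataFrame(log, columns=["frame", "kind", "view", "fish", "point"])
    return SyntheticScene(
        config=cfg,
        cameras=cameras,
        truth=truth,
        det_px=det,
        perm=perm,
        centroid_px=cent,
        centroid_label_idx=label_idx,
        injection_log=log_df,
    )


def make_scene(cfg: SimConfig) -> SyntheticScene:
    """Simulate the dyad and render it under the synthetic cameras."""
    cameras = make_cameras(cfg)
    return render_detections(simulate_dyad(cfg), cameras, cfg)
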