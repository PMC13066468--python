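"""Polynomial multi-view calibration.

Three orthogonal cameras observe a tank: ``XY`` from the top and ``YZ``/``XZ``
from the sides.  Instead of an explicit pinhole + refraction model, the
mapping between pixel and world coordinates is absorbed into five polynomial
regressions fitted to a bead fixture of known 3D geometry:

* ``to_world``   — degree-2 map from the six image coordinates (two per view)
  to the 3D world point (cm);
* ``to_views``   — degree-2 inverse map from the world point to all six image
  coordinates;
* three ``view_maps`` — degree-3 maps from the two *source* views' image
  coordinates (four scalars) to the pixel coordinates in the remaining
  *target* view, one map per possible target.

All maps use the full multivariate monomial basis of total degree <= d
(constant and cross terms included) and are fitted by unregularized ordinary
least squares, one output dimension at a time.  Missing inputs (NaN)
propagate to missing outputs; they are never raised as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb

import numpy as np

#: View labels in canonical order: top camera first, then the two side cameras.
VIEWS: tuple[str, str, str] = ("XY", "YZ", "XZ")

#: World-coordinate axes (indices into x, y, z) imaged by each view.
VIEW_AXES: dict[str, tuple[int, int]] = {"XY": (0, 1), "YZ": (1, 2), "XZ": (0, 2)}


class CalibrationError(ValueError):
    """Base class for calibration fitting failures."""


class UnderdeterminedFitError(CalibrationError):
    """Fewer observations than monomial coefficients for a requested map."""


class DegenerateGeometryError(CalibrationError):
    """Bead geometry leaves the least-squares design matrix rank deficient."""


def monomial_powers(n_vars: int, degree: int) -> np.ndarray:
    """Exponent matrix of all monomials of total degree <= ``degree``.

    Rows are ordered by total degree, then lexicographically by variable
    index, so the constant term is always row 0 and the pure linear terms
    rows 1..n_vars.  Shape ``(n_monomials, n_vars)``.
    """
    rows = []
    for d in range(degree + 1):
        for combo in combinations_with_replacement(range(n_vars), d):
            p = np.zeros(n_vars, dtype=np.int64)
            for i in combo:
                p[i] += 1
            rows.append(p)
    return np.asarray(rows, dtype=np.int64)


def n_monomials(n_vars: int, degree: int) -> int:
    return comb(n_vars + degree, degree)


def _design_matrix(X: np.ndarray, powers: np.ndarray) -> np.ndarray:
    # (n, m) monomial values; NaN inputs contaminate every monomial that
    # involves the missing variable (NaN**0 == 1, so the constant survives,
    # but any dot product with the row is NaN, which is what we want).
    return np.prod(np.power(X[:, None, :], powers[None, :, :]), axis=2)


@dataclass
class PolyMap:
    """A fitted multivariate polynomial map R^input_dim -> R^output_dim.

    Inputs are affinely standardized before monomial expansion
    (``x' = (x - offset) / scale``): the monomial basis in raw pixel/cm
    units is catastrophically ill-conditioned across degrees.  ``coeffs``
    lives in the standardized basis; :meth:`raw_coefficients` expands back
    to the raw basis exactly for comparison against a generating model.
    """

    input_dim: int
    output_dim: int
    degree: int
    coeffs: np.ndarray  # (n_monomials, output_dim), standardized basis
    rms_residual: float = float("nan")
    offset: np.ndarray = None
    scale: np.ndarray = None
    _powers: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.degree not in (2, 3):
            raise ValueError(f"degree must be 2 or 3, got {self.degree}")
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        m = n_monomials(self.input_dim, self.degree)
        if self.coeffs.shape != (m, self.output_dim):
            raise ValueError(
                f"coefficient matrix must be {(m, self.output_dim)}, "
                f"got {self.coeffs.shape}"
            )
        self.offset = (
            np.zeros(self.input_dim)
            if self.offset is None
            else np.asarray(self.offset, dtype=float)
        )
        self.scale = (
            np.ones(self.input_dim)
            if self.scale is None
            else np.asarray(self.scale, dtype=float)
        )
        if self._powers is None:
            self._powers = monomial_powers(self.input_dim, self.degree)

    @property
    def powers(self) -> np.ndarray:
        return self._powers

    def __call__(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the map; rows with any non-finite input give NaN rows."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X2 = np.atleast_2d(X)
        if X2.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} inputs, got {X2.shape[1]}")
        out = np.full((X2.shape[0], self.output_dim), np.nan)
        ok = np.isfinite(X2).all(axis=1)
        if ok.any():
            A = _design_matrix((X2[ok] - self.offset) / self.scale, self._powers)
            out[ok] = A @ self.coeffs
        return out[0] if single else out

    def raw_coefficients(self) -> np.ndarray:
        """Coefficients expanded into the raw (unstandardized) monomial basis.

        Exact binomial expansion of each standardized monomial
        ``prod_i ((x_i - mu_i) / s_i)^{p_i}``; same shape and row order as
        ``coeffs``.
        """
        index = {tuple(p): i for i, p in enumerate(self._powers)}
        raw = np.zeros_like(self.coeffs)
        for j, p in enumerate(self._powers):
            terms = {(0,) * self.input_dim: 1.0}
            for i, pi in enumerate(p):
                if pi == 0:
                    continue
                factor = {
                    k: comb(pi, k) * (-self.offset[i]) ** (pi - k) / self.scale[i] ** pi
                    for k in range(pi + 1)
                }
                new: dict[tuple, float] = {}
                for e, c in terms.items():
                    for k, fc in factor.items():
                        e2 = list(e)
                        e2[i] += k
                        key = tuple(e2)
                        new[key] = new.get(key, 0.0) + c * fc
                terms = new
            for e, c in terms.items():
                raw[index[e]] += c * self.coeffs[j]
        return raw

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        Y: np.ndarray,
        degree: int,
        name: str = "map",
        strict_rank: bool = True,
    ) -> "PolyMap":
        """Ordinary least squares on the full monomial basis.

        Rows with non-finite entries in either X or Y are dropped before
        fitting.  Raises :class:`UnderdeterminedFitError` if fewer usable
        rows than coefficients remain and, when ``strict_rank``,
        :class:`DegenerateGeometryError` if the design matrix is rank
        deficient.  ``strict_rank=False`` takes the minimum-norm solution
        instead: maps whose inputs are image coordinates of a common 3D
        scene are *inherently* rank deficient (the inputs live on the
        3-dimensional manifold of consistent projections), and only the
        map's action on that manifold is identifiable or ever used.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        ok = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
        X, Y = X[ok], Y[ok]
        powers = monomial_powers(X.shape[1], degree)
        m = powers.shape[0]
        if X.shape[0] < m:
            raise UnderdeterminedFitError(
                f"{name}: {X.shape[0]} observations cannot determine "
                f"{m} degree-{degree} coefficients in {X.shape[1]} variables"
            )
        offset = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        A = _design_matrix((X - offset) / scale, powers)
        # rcond: treat directions below ~1e-9 of the leading singular value
        # as the unidentifiable off-manifold null space (minimum-norm there).
        coeffs, _, rank, _ = np.linalg.lstsq(A, Y, rcond=1e-9)
        if strict_rank and rank < m:
            raise DegenerateGeometryError(
                f"{name}: design matrix rank {rank} < {m}; "
                "bead geometry is degenerate for this polynomial degree"
            )
        resid = A @ coeffs - Y
        rms = float(np.sqrt(np.mean(resid**2)))
        return cls(
            input_dim=X.shape[1],
            output_dim=Y.shape[1],
            degree=degree,
            coeffs=coeffs,
            rms_residual=rms,
            offset=offset,
            scale=scale,
            _powers=powers,
        )


@dataclass
class BeadSet:
    """Calibration bead correspondences: known 3D points and their pixels.

    ``world`` is (n, 3) in cm; ``images`` maps each view label to an (n, 2)
    pixel array aligned row-by-row with ``world``.  Multiple fixture
    orientations are simply pooled as extra rows.
    """

    world: np.ndarray
    images: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.world = np.atleast_2d(np.asarray(self.world, dtype=float))
        if self.world.shape[1] != 3:
            raise ValueError("world points must be (n, 3)")
        if set(self.images) != set(VIEWS):
            raise ValueError(f"images must cover exactly the views {VIEWS}")
        self.images = {v: np.atleast_2d(np.asarray(p, dtype=float)) for v, p in self.images.items()}
        n = self.n_beads
        for v, pts in self.images.items():
            if pts.shape != (n, 2):
                raise ValueError(f"view {v}: expected ({n}, 2) pixel array")
        centered = self.world - self.world.mean(axis=0)
        if n >= 4 and np.linalg.matrix_rank(centered, tol=1e-9) < 3:
            raise DegenerateGeometryError(
                "bead world points are coplanar; 3D calibration is degenerate"
            )

    @property
    def n_beads(self) -> int:
        return self.world.shape[0]

    def image_vector(self) -> np.ndarray:
        """(n, 6) concatenated pixel coordinates in canonical view order."""
        return np.concatenate([self.images[v] for v in VIEWS], axis=1)


@dataclass
class CalibrationModel:
    """The five fitted polynomial mappings plus fit diagnostics."""

    to_world: PolyMap
    to_views: PolyMap
    view_maps: dict[str, PolyMap]  # keyed by TARGET view label
    fitted_on: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.view_maps) != set(VIEWS):
            raise ValueError("one view map per target view is required")

    @property
    def residuals(self) -> dict[str, float]:
        out = {"to_world": self.to_world.rms_residual, "to_views": self.to_views.rms_residual}
        for v, m in self.view_maps.items():
            out[f"view_map_{v}"] = m.rms_residual
        return out


def fit_calibration(
    beads: BeadSet, world_degree: int = 2, view_degree: int = 3
) -> CalibrationModel:
    """Fit all five maps by OLS over the pooled bead correspondences."""
    img = beads.image_vector()  # (n, 6)
    w = beads.world
    # Image-coordinate inputs are confined to the 3D manifold of consistent
    # projections, so those designs are rank deficient by construction;
    # minimum-norm OLS is used there.  to_views has free 3D inputs and keeps
    # the strict rank check (it is also the identifiable map).
    to_world = PolyMap.fit(img, w, world_degree, "to_world", strict_rank=False)
    to_views = PolyMap.fit(w, img, world_degree, "to_views")
    view_maps: dict[str, PolyMap] = {}
    for target in VIEWS:
        sources = [v for v in VIEWS if v != target]
        X = np.concatenate([beads.images[v] for v in sources], axis=1)
        view_maps[target] = PolyMap.fit(
            X, beads.images[target], view_degree, f"view_map_{target}", strict_rank=False
        )
    return CalibrationModel(
        to_world=to_world,
        to_views=to_views,
        view_maps=view_maps,
        fitted_on={"n_beads": beads.n_beads},
    )


def map_to_world(model: CalibrationModel, triplet: np.ndarray) -> np.ndarray:
    """Map three 2D view points (XY, YZ, XZ order) to one 3D point in cm.

    ``triplet`` is (3, 2) or (n, 3, 2).  Any missing (NaN) coordinate makes
    the whole output point missing.
    """
    t = np.asarray(triplet, dtype=float)
    single = t.ndim == 2
    t = t.reshape(-1, 3, 2)
    out = model.to_world(t.reshape(-1, 6))
    return out[0] if single else out


def map_to_views(model: CalibrationModel, point3d: np.ndarray) -> np.ndarray:
    """Map 3D world points to the three 2D view points ((n, 3, 2) or (3, 2))."""
    p = np.asarray(point3d, dtype=float)
    single = p.ndim == 1
    out = model.to_views(np.atleast_2d(p)).reshape(-1, 3, 2)
    return out[0] if single else out


def map_views_pairwise(
    model: CalibrationModel,
    source_a: str,
    source_b: str,
    points_a: np.ndarray,
    points_b: np.ndarray,
) -> np.ndarray:
    """Predict pixel coordinates in the remaining view from two source views.

    Sources are reordered canonically, so argument order does not matter.
    Accepts (2,) points or (n, 2) arrays; missing inputs give missing outputs.
    """
    if source_a == source_b:
        raise ValueError(f"source views must differ, got {source_a!r} twice")
    for v in (source_a, source_b):
        if v not in VIEWS:
            raise ValueError(f"unknown view {v!r}")
    target = next(v for v in VIEWS if v not in (source_a, source_b))
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    pts = {source_a: pa, source_b: pb}
    ordered = [v for v in VIEWS if v != target]
    X = np.concatenate([pts[ordered[0]], pts[ordered[1]]], axis=1)
    out = model.view_maps[target](X)
    single = np.asarray(points_a).ndim == 1
    return out[0] if single else out
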