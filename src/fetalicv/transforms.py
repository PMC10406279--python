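"""Geometric transforms: linear, B-spline free-form, chains, inversion.

All transforms map *fixed*-space world points (mm) to *moving*-space world
points (pull-back convention): resampling a moving image onto a fixed grid
evaluates the moving image at ``t(x)`` for each fixed voxel center ``x``.
The "inverse transformation from the brain model to the subject's scan" used
for ICV label propagation is therefore the chain that carries subject-grid
points into model space, where the model's ICV mask is sampled.

Linear transforms act as ``y = M (x - c) + c + o`` with matrix ``M``, rotation
/scaling center ``c`` and offset ``o``.  B-spline free-form deformations add a
displacement field parameterized by control-point coefficients interpolated
with the cubic B-spline basis.  Chains apply their members in list order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import BinaryMask, Geometry, Volume

__all__ = [
    "LinearTransform",
    "BSplineTransform",
    "DisplacementFieldTransform",
    "TransformChain",
    "apply_transform",
    "compose",
    "invert",
    "warp_mask",
    "save_transform",
    "load_transform",
]

_LINEAR_KINDS = ("translation", "rigid", "similarity", "affine")


# ---------------------------------------------------------------------------
# Transform classes


@dataclass
class LinearTransform:
    """Affine-family map ``y = M (x - c) + c + o`` (mm)."""

    kind: str
    matrix: np.ndarray
    offset: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in _LINEAR_KINDS:
            raise ValueError(f"unknown linear kind {self.kind!r}")
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("singular linear transform (|det| <= 1e-12)")
        if self.kind == "translation" and not np.allclose(self.matrix, np.eye(3)):
            raise ValueError("translation transform requires identity matrix")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity(center: np.ndarray | None = None) -> "LinearTransform":
        c = np.zeros(3) if center is None else center
        return LinearTransform("translation", np.eye(3), np.zeros(3), c)

    @staticmethod
    def translation(t: np.ndarray) -> "LinearTransform":
        return LinearTransform("translation", np.eye(3), np.asarray(t, float),
                               np.zeros(3))

    @staticmethod
    def from_params(kind: str, angles_rad: np.ndarray, translation: np.ndarray,
                    scale: float, center: np.ndarray) -> "LinearTransform":
        """Build rigid/similarity transforms from Euler angles (x,y,z order)."""
        R = _euler_matrix(np.asarray(angles_rad, float))
        return LinearTransform(kind, scale * R, np.asarray(translation, float),
                               np.asarray(center, float))

    # -- action ------------------------------------------------------------
    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (3, N) world points."""
        c = self.center[:, None]
        return self.matrix @ (pts - c) + c + self.offset[:, None]

    def inverted(self) -> "LinearTransform":
        Minv = np.linalg.inv(self.matrix)
        kind = self.kind if self.kind in ("translation", "rigid", "similarity",
                                          "affine") else "affine"
        return LinearTransform(kind, Minv, -Minv @ self.offset, self.center)

    def to_dict(self) -> dict:
        return {"type": "linear", "kind": self.kind,
                "matrix": self.matrix.tolist(), "offset": self.offset.tolist(),
                "center": self.center.tolist()}


def _euler_matrix(angles: np.ndarray) -> np.ndarray:
    """Rotation matrix Rz @ Ry @ Rx for Euler angles (rad) about x, y, z."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _bspline_weights(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values B3(u + 1), B3(u), B3(u - 1), B3(u - 2).

    ``u`` is the fractional part of the continuous control-grid index; the
    four weights multiply coefficients at floor(idx)-1 .. floor(idx)+2.
    Matches scipy's ``map_coordinates(order=3, prefilter=False)`` convention.
    """
    w = np.empty((4,) + u.shape)
    w[0] = (1 - u) ** 3 / 6.0
    w[1] = (3 * u**3 - 6 * u**2 + 4) / 6.0
    w[2] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    w[3] = u**3 / 6.0
    return w


@dataclass
class BSplineTransform:
    """Free-form deformation ``y = x + d(x)`` on a cubic B-spline control grid.

    ``coefficients`` has shape (3, nx, ny, nz): per-axis mm displacements of
    the control points (B-spline coefficients, the optimization parameters).
    The grid must cover ``domain`` with at least two control points of margin
    on each side so that interior evaluation never touches the grid edge.
    """

    grid_origin: np.ndarray
    grid_spacing: np.ndarray
    coefficients: np.ndarray
    domain: Geometry

    def __post_init__(self) -> None:
        self.grid_origin = np.asarray(self.grid_origin, float).reshape(3)
        self.grid_spacing = np.asarray(self.grid_spacing, float).reshape(3)
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[0] != 3:
            raise ValueError("coefficients must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite B-spline coefficients")
        lo = self.domain.origin
        hi = self.domain.origin + self.domain.spacing * (
            np.asarray(self.domain.shape) - 1)
        n = np.asarray(self.coefficients.shape[1:])
        glo = self.grid_origin
        ghi = self.grid_origin + self.grid_spacing * (n - 1)
        if np.any(glo > lo - self.grid_spacing) or np.any(ghi < hi + self.grid_spacing):
            raise ValueError("control grid must cover the domain with >=1 "
                             "control-point margin per side")

    @staticmethod
    def for_domain(domain: Geometry, grid_spacing_mm: np.ndarray,
                   margin: int = 2) -> "BSplineTransform":
        """Zero-displacement FFD whose grid covers ``domain`` with margin."""
        gs = np.asarray(grid_spacing_mm, float) * np.ones(3)
        extent = np.asarray(domain.shape) * domain.spacing
        n_inner = np.ceil(extent / gs).astype(int) + 1
        n = n_inner + 2 * margin
        origin = domain.origin - margin * gs
        coeff = np.zeros((3, *n))
        return BSplineTransform(origin, gs, coeff, domain)

    def grid_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous control-grid index of (3, N) world points."""
        return (pts - self.grid_origin[:, None]) / self.grid_spacing[:, None]

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        """(3, N) mm displacement at world points, cubic B-spline interp."""
        u = self.grid_index(pts)
        d = np.empty_like(u)
        for a in range(3):
            d[a] = map_coordinates(self.coefficients[a], u, order=3,
                                   mode="nearest", prefilter=False)
        return d

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement(pts)

    def basis_matrix(self, pts: np.ndarray):
        """Sparse (N, n_ctrl) cubic-basis matrix at world points.

        Rows reproduce :meth:`displacement` for interior points:
        ``W @ coefficients[a].ravel() == displacement[a]``.  Used for the
        analytic gradient of B-spline registration.
        """
        from scipy import sparse

        u = self.grid_index(pts)  # (3, N)
        base = np.floor(u).astype(int)
        frac = u - base
        nshape = np.asarray(self.coefficients.shape[1:])
        # clamp so the 4-point support stays inside the grid (margin >= 1)
        base = np.clip(base, 1, nshape[:, None] - 3)
        w = [_bspline_weights(frac[a]) for a in range(3)]  # 3 x (4, N)
        npts = pts.shape[1]
        rows = np.repeat(np.arange(npts), 64)
        cols = np.empty((npts, 4, 4, 4), dtype=np.int64)
        vals = np.empty((npts, 4, 4, 4))
        offs = np.arange(-1, 3)
        ix = base[0][:, None] + offs
        iy = base[1][:, None] + offs
        iz = base[2][:, None] + offs
        cols[:] = ((ix[:, :, None, None] * nshape[1] + iy[:, None, :, None])
                   * nshape[2] + iz[:, None, None, :])
        vals[:] = (w[0].T[:, :, None, None] * w[1].T[:, None, :, None]
                   * w[2].T[:, None, None, :])
        W = sparse.csr_matrix((vals.ravel(), (rows, cols.ravel())),
                              shape=(npts, int(np.prod(nshape))))
        return W

    def to_dict(self) -> dict:
        return {"type": "bspline", "grid_origin": self.grid_origin.tolist(),
                "grid_spacing": self.grid_spacing.tolist(),
                "coefficients": self.coefficients.tolist(),
                "domain": {"shape": list(self.domain.shape),
                           "spacing": self.domain.spacing.tolist(),
                           "origin": self.domain.origin.tolist()}}


@dataclass
class DisplacementFieldTransform:
    """Dense displacement field ``y = x + d(x)``, trilinear interpolation.

    Produced by numeric inversion of B-spline transforms.  Outside its grid
    the displacement is clamped to the nearest edge value.
    """

    geometry: Geometry
    field: np.ndarray  # (3, *geometry.shape), mm

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, float)
        if self.field.shape != (3, *self.geometry.shape):
            raise ValueError("field shape must be (3, *geometry.shape)")

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        idx = (pts - self.geometry.origin[:, None]) / self.geometry.spacing[:, None]
        d = np.empty_like(idx)
        for a in range(3):
            d[a] = map_coordinates(self.field[a], idx, order=1, mode="nearest")
        return d

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement(pts)

    def to_dict(self) -> dict:
        return {"type": "displacement_field",
                "geometry": {"shape": list(self.geometry.shape),
                             "spacing": self.geometry.spacing.tolist(),
                             "origin": self.geometry.origin.tolist()},
                "field": self.field.tolist()}


Transform = LinearTransform | BSplineTransform | DisplacementFieldTransform


@dataclass
class TransformChain:
    """Ordered transforms applied in list order (fixed point -> moving point)."""

    transforms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.transforms = list(self.transforms)

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        if not self.transforms:
            raise ValueError("empty transform chain")
        out = pts
        for t in self.transforms:
            out = t.apply_points(out)
        return out

    def prepended(self, t: Transform) -> "TransformChain":
        """Chain with ``t`` applied before the existing members.

        Stage accumulation: after stage k found T_k on the common grid, the
        warped moving image is ``moving(T_1(...T_k(x)))``; the newest stage
        transform acts first on fixed points and so goes at the front.
        """
        return TransformChain([t, *self.transforms])

    def to_dict(self) -> dict:
        return {"type": "chain", "transforms": [t.to_dict() for t in self.transforms]}


# ---------------------------------------------------------------------------
# Operations


def _as_chain(t) -> TransformChain:
    return t if isinstance(t, TransformChain) else TransformChain([t])


def apply_transform(v: Volume, t, interpolation: str = "linear",
                    target_geometry: Geometry | None = None,
                    cval: float | None = None) -> Volume:
    """Resample ``v`` onto a fixed grid through transform ``t``.

    Output voxel at world position ``x`` takes the input value at ``t(x)``.
    Out-of-domain samples default to the input's nonzero-mean background, the
    same gray level the sweep-boundary preprocessing fills padding with.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    chain = _as_chain(t)
    target = target_geometry or v.geometry()
    pts = target.voxel_centers_world()
    mapped = chain.apply_points(pts)
    idx = (mapped - v.origin[:, None]) / v.spacing[:, None]
    if cval is None:
        nz = v.data[v.data != 0]
        cval = float(nz.mean()) if nz.size else 0.0
    order = 1 if interpolation == "linear" else 0
    out = map_coordinates(v.data.astype(float), idx, order=order,
                          mode="constant", cval=cval)
    return Volume(out.reshape(target.shape), target.spacing, target.origin,
                  orientation_label=v.orientation_label)


def _compose_pair(t1: LinearTransform, t2: LinearTransform) -> LinearTransform:
    """Single linear transform equal to applying t1 then t2."""
    M = t2.matrix @ t1.matrix
    c = t1.center
    o = t2.matrix @ (c + t1.offset - t2.center) + t2.center + t2.offset - c
    if t1.kind == "translation" and t2.kind == "translation":
        kind = "translation"
    elif {t1.kind, t2.kind} <= {"translation", "rigid"}:
        kind = "rigid"
    elif {t1.kind, t2.kind} <= {"translation", "rigid", "similarity"}:
        kind = "similarity"
    else:
        kind = "affine"
    return LinearTransform(kind, M, o, c)


def compose(chain: TransformChain) -> TransformChain:
    """Collapse runs of adjacent linear members into single linear transforms."""
    if not len(chain):
        raise ValueError("empty transform chain")
    out: list = []
    for t in chain:
        if isinstance(t, LinearTransform) and out and isinstance(out[-1], LinearTransform):
            out[-1] = _compose_pair(out[-1], t)
        else:
            out.append(t)
    return TransformChain(out)


def _invert_nonlinear(t: BSplineTransform | DisplacementFieldTransform,
                      tolerance_mm: float, max_iter: int = 100
                      ) -> DisplacementFieldTransform:
    """Numeric inverse as a dense displacement field by fixed-point iteration.

    Solves ``e(y) = -d(y + e(y))`` on the transform's domain grid; converges
    for the moderate, smooth deformations the registration pipelines produce.
    """
    geom = t.domain if isinstance(t, BSplineTransform) else t.geometry
    pts = geom.voxel_centers_world()
    e = np.zeros_like(pts)
    for _ in range(max_iter):
        e_new = -t.displacement(pts + e)
        delta = float(np.max(np.abs(e_new - e)))
        e = e_new
        if delta < 0.25 * tolerance_mm:
            break
    inv = DisplacementFieldTransform(geom, e.reshape(3, *geom.shape))
    # verify round trip on voxel centers
    resid = t.apply_points(inv.apply_points(pts)) - pts
    worst = float(np.max(np.abs(resid)))
    if worst > tolerance_mm:
        raise RuntimeError(
            f"displacement-field inversion did not converge: worst residual "
            f"{worst:.4g} mm exceeds tolerance {tolerance_mm:.4g} mm")
    return inv


def invert(t, tolerance: float | None = None):
    """Invert a transform or chain.

    Linear members are inverted in closed form; B-spline members numerically,
    as a dense displacement field, such that ``|t(invert(t)(x)) - x|`` is at
    most ``tolerance`` (mm) at every voxel center of the member's domain.
    Default tolerance: 0.05 of the smallest domain voxel size.
    """
    if isinstance(t, TransformChain):
        return TransformChain([invert(m, tolerance) for m in reversed(t.transforms)])
    if isinstance(t, LinearTransform):
        return t.inverted()
    if isinstance(t, (BSplineTransform, DisplacementFieldTransform)):
        geom = t.domain if isinstance(t, BSplineTransform) else t.geometry
        tol = tolerance if tolerance is not None else 0.05 * float(np.min(geom.spacing))
        if tol <= 0:
            raise ValueError("tolerance must be positive")
        return _invert_nonlinear(t, tol)
    raise TypeError(f"cannot invert {type(t).__name__}")


def warp_mask(m: BinaryMask, t, target_geometry: Geometry | None = None) -> BinaryMask:
    """Propagate a binary mask through a transform onto a target grid.

    The mask is resampled with linear interpolation and thresholded at 0.5,
    which gives smoother boundaries (hence less discretization noise in the
    volume estimate) than nearest-neighbor resampling.
    """
    as_vol = Volume(m.data.astype(float), m.spacing, m.origin,
                    orientation_label=m.orientation_label)
    warped = apply_transform(as_vol, t, interpolation="linear",
                             target_geometry=target_geometry, cval=0.0)
    return BinaryMask((warped.data >= 0.5).astype(np.uint8), warped.spacing,
                      warped.origin, orientation_label=m.orientation_label)


# ---------------------------------------------------------------------------
# Serialization (JSON parameter files)


def save_transform(t, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(t.to_dict(), fh)
    return path


def _from_dict(d: dict):
    typ = d["type"]
    if typ == "linear":
        return LinearTransform(d["kind"], np.array(d["matrix"]),
                               np.array(d["offset"]), np.array(d["center"]))
    if typ == "bspline":
        g = d["domain"]
        return BSplineTransform(np.array(d["grid_origin"]),
                                np.array(d["grid_spacing"]),
                                np.array(d["coefficients"]),
                                Geometry(tuple(g["shape"]), g["spacing"], g["origin"]))
    if typ == "displacement_field":
        g = d["geometry"]
        return DisplacementFieldTransform(
            Geometry(tuple(g["shape"]), g["spacing"], g["origin"]),
            np.array(d["field"]))
    if typ == "chain":
        return TransformChain([_from_dict(x) for x in d["transforms"]])
    raise ValueError(f"unknown transform type {typ!r}")


def load_transform(path: str | Path):
    with open(path) as fh:
        return _from_dict(json.load(fh))
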