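"""Single-stage intensity-based registration.

Each stage optimizes one transform family (translation, rigid, similarity,
affine, or cubic B-spline free-form deformation) by seeded gradient descent
over a smoothing-only coarse-to-fine schedule: the images are progressively
less Gaussian-blurred but never down-sampled, which suits the speckled,
shadow-laden character of 3D ultrasound.

Two optimizer modes are provided, mirroring the standard / adaptive
gradient-descent pair of mainstream registration toolkits: both use the
decaying gain ``a_k = sp_a / (A + k)^alpha`` (alpha = 0.602, A = 50) applied
to the infinity-norm-normalized gradient, so ``sp_a`` is an initial step in
mm; the adaptive mode calibrates ``sp_a`` from the first gradient so the
first step moves at most one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial.transform import Rotation

from .transforms import BSplineTransform, LinearTransform
from .volume import Geometry, Volume

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "blur",
    "intensity_metric",
    "register",
]

_FAMILIES = ("translation", "rigid", "similarity", "affine", "bspline")
_ALPHA = 0.602
_A = 50.0


@dataclass
class RegistrationParams:
    """Tunables of one registration stage.

    The fields mirror the handful of parameters that in practice need
    per-stage tweaking when a registration misbehaves: the optimizer mode,
    its step-size scale ``sp_a``, the blurring (image-pyramid) schedule, and
    an optional pre-blur of both images before the stage.
    """

    family: str
    metric: str | None = None           # ssd | ncc; None -> ncc linear, ssd bspline
    optimizer: str = "adaptive_gd"      # standard_gd | adaptive_gd
    sp_a: float = 10.0                  # initial-step scale, mm (standard_gd)
    pyramid_schedule: tuple = (4.0, 2.0, 1.0, 0.0)   # Gaussian sigmas, voxels
    max_iterations: int = 50            # per pyramid level
    pre_blur_sigma: float = 0.0         # voxels; 0 = off
    seed: int = 0
    bspline_grid_spacing: float = 8.0   # control-point spacing, voxels
    sample_fraction: float | None = None  # None -> full below 64^3, 20% above

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown transform family {self.family!r}")
        if self.metric not in (None, "ssd", "ncc"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.optimizer not in ("standard_gd", "adaptive_gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.sp_a <= 0:
            raise ValueError("sp_a must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        sched = tuple(float(s) for s in self.pyramid_schedule)
        if any(s < 0 for s in sched):
            raise ValueError("pyramid sigmas must be nonnegative")
        if any(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError("pyramid_schedule must be nonincreasing")
        self.pyramid_schedule = sched

    @property
    def effective_metric(self) -> str:
        if self.metric is not None:
            return self.metric
        return "ssd" if self.family == "bspline" else "ncc"

    def with_(self, **kw) -> "RegistrationParams":
        return dc_replace(self, **kw)


@dataclass
class RegistrationResult:
    transform: object
    final_metric: float
    iterations_used: list = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.final_metric):
            raise ValueError("final metric is not finite")


# ---------------------------------------------------------------------------
# Building blocks


def blur(v: Volume, sigma: float) -> Volume:
    """Gaussian smoothing (sigma in voxels) at unchanged resolution.

    The coarse-to-fine schedule blurs but never down-samples, so the output
    grid always equals the input grid.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return v.copy()
    return dc_replace(v, data=gaussian_filter(v.data.astype(float), sigma))


def intensity_metric(fixed: Volume, moving_resampled: Volume, metric: str) -> float:
    """Similarity of two volumes on an identical grid.

    ``ssd``: mean squared intensity difference (lower is better).
    ``ncc``: Pearson correlation of intensities (higher is better).
    """
    if fixed.shape != moving_resampled.shape:
        raise ValueError("intensity_metric requires identical grids")
    a = fixed.data.ravel().astype(float)
    b = moving_resampled.data.ravel().astype(float)
    if metric == "ssd":
        return float(np.mean((a - b) ** 2))
    if metric == "ncc":
        return _ncc(a, b)
    raise ValueError(f"unknown metric {metric!r}")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(ac @ bc / (na * nb))


def _loss_and_dm(fv: np.ndarray, mv: np.ndarray, metric: str):
    """Loss (lower = better) and its gradient w.r.t. the moving samples.

    The ssd loss is normalized by the fixed image's variance so that loss
    magnitudes are comparable across metrics and intensity scales (the
    reported final metric stays the plain mean squared difference).
    """
    n = fv.size
    if metric == "ssd":
        varf = float(np.var(fv))
        scale = varf if varf > 0 else 1.0
        r = mv - fv
        return float(np.mean(r**2)) / scale, 2.0 * r / (n * scale)
    # ncc loss = 1 - corr
    fc = fv - fv.mean()
    mc = mv - mv.mean()
    nf = np.linalg.norm(fc)
    nm = np.linalg.norm(mc)
    if nf == 0 or nm == 0:
        raise ValueError("correlation undefined for a constant image")
    corr = float(fc @ mc / (nf * nm))
    dm = -(fc / (nf * nm) - corr * mc / nm**2)
    return 1.0 - corr, dm


# ---------------------------------------------------------------------------
# Linear-family parameterization
#
# Parameters live in a scaled space where a unit change moves a point at the
# edge of the field of view by roughly 1 mm, making gradient components
# commensurate across translations (mm), rotations (rad) and scalings.


def _domain_radius(geom: Geometry) -> float:
    return float(np.linalg.norm(np.asarray(geom.shape) * geom.spacing) / 2.0)


def _n_params(family: str) -> int:
    return {"translation": 3, "rigid": 6, "similarity": 7, "affine": 12}[family]


def _linear_from_q(family: str, q: np.ndarray, center: np.ndarray,
                   rho: float) -> LinearTransform:
    if family == "translation":
        return LinearTransform("translation", np.eye(3), q[:3], center)
    if family == "rigid":
        R = Rotation.from_euler("xyz", q[:3] / rho).as_matrix()
        return LinearTransform("rigid", R, q[3:6], center)
    if family == "similarity":
        R = Rotation.from_euler("xyz", q[:3] / rho).as_matrix()
        s = float(np.exp(q[6] / rho))
        return LinearTransform("similarity", s * R, q[3:6], center)
    if family == "affine":
        M = np.eye(3) + q[:9].reshape(3, 3) / rho
        return LinearTransform("affine", M, q[9:12], center)
    raise ValueError(family)


def _q_from_linear(family: str, t: LinearTransform, center: np.ndarray,
                   rho: float) -> np.ndarray:
    """Scaled parameter vector reproducing ``t``'s action (center re-based)."""
    # re-express t about the requested center: offset changes by (M - I)(c' - c)
    off = t.offset + (t.matrix - np.eye(3)) @ (t.center - center)
    q = np.zeros(_n_params(family))
    if family == "translation":
        q[:3] = off
        return q
    if family == "affine":
        q[:9] = ((t.matrix - np.eye(3)) * rho).ravel()
        q[9:12] = off
        return q
    M = t.matrix
    s = float(np.linalg.det(M)) ** (1.0 / 3.0)
    R = M / s
    ang = Rotation.from_matrix(R).as_euler("xyz")
    q[:3] = ang * rho
    q[3:6] = off
    if family == "similarity":
        q[6] = np.log(s) * rho
    return q


# ---------------------------------------------------------------------------
# Optimizer


def _gain(k: int, sp_a: float) -> float:
    return sp_a / (_A + k) ** _ALPHA


def _descend(q0, loss_grad, params: RegistrationParams, min_spacing: float):
    """Normalized-gradient descent with the decaying gain schedule.

    Returns (best_q, best_loss, iterations, diverged).  ``loss_grad(q)`` must
    return (loss, gradient).  Divergence = the loss worsened monotonically
    over the whole level.
    """
    q = q0.copy()
    loss0, g = loss_grad(q)
    if loss0 <= 1e-6:  # already aligned to working precision
        return q, loss0, 0, False
    gmax = float(np.max(np.abs(g)))
    if params.optimizer == "adaptive_gd":
        sp_a = min_spacing * (_A**_ALPHA) if gmax > 0 else params.sp_a
    else:
        sp_a = params.sp_a
    best_q, best_loss = q.copy(), loss0
    prev_loss = loss0
    improved_once = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        if gmax == 0:
            break
        step = _gain(it - 1, sp_a)
        q = q - step * g / gmax
        loss, g = loss_grad(q)
        gmax = float(np.max(np.abs(g)))
        if loss < best_loss:
            best_loss, best_q = loss, q.copy()
        if loss < prev_loss:
            improved_once = True
        prev_loss = loss
        if step < 1e-3 * min_spacing:
            break
    diverged = (it >= 3) and (not improved_once) and (prev_loss > loss0)
    return best_q, best_loss, it, diverged


# ---------------------------------------------------------------------------
# Registration driver


def _sample_indices(n_total: int, params: RegistrationParams, level: int) -> np.ndarray:
    frac = params.sample_fraction
    if frac is None:
        frac = 1.0 if n_total <= 64**3 else 0.2
    n = int(round(frac * n_total))
    n = max(min(n, n_total), min(n_total, 512))
    if n == n_total:
        return np.arange(n_total)
    rng = np.random.default_rng([params.seed, level, 17])
    return rng.choice(n_total, size=n, replace=False)


def _resample_at(data: np.ndarray, geom_moving: Volume, pts: np.ndarray,
                 cval: float, order: int = 1) -> np.ndarray:
    idx = (pts - geom_moving.origin[:, None]) / geom_moving.spacing[:, None]
    return map_coordinates(data, idx, order=order, mode="constant", cval=cval)


def register(fixed: Volume, moving: Volume, params: RegistrationParams,
             initial_transform: LinearTransform | None = None) -> RegistrationResult:
    """Estimate the transform of ``params.family`` aligning moving to fixed.

    The result transform maps fixed-space points to moving-space points, so
    ``apply_transform(moving, result.transform, target_geometry=fixed)``
    produces the registered moving image.  Deterministic for a given seed.
    """
    metric_name = params.effective_metric
    fixed_w = fixed
    moving_w = moving
    if params.pre_blur_sigma > 0:
        fixed_w = blur(fixed_w, params.pre_blur_sigma)
        moving_w = blur(moving_w, params.pre_blur_sigma)

    geom = fixed.geometry()
    all_pts = geom.voxel_centers_world()
    nz = moving.data[moving.data != 0]
    cval = float(nz.mean()) if nz.size else 0.0
    min_spacing = float(np.min(fixed.spacing))

    if params.family == "bspline":
        return _register_bspline(fixed_w, moving_w, params, geom, all_pts,
                                 cval, min_spacing, metric_name)
    return _register_linear(fixed_w, moving_w, params, geom, all_pts, cval,
                            min_spacing, metric_name, initial_transform)


def _register_linear(fixed_w, moving_w, params, geom, all_pts, cval,
                     min_spacing, metric_name, initial_transform):
    center = Volume(fixed_w.data, fixed_w.spacing, fixed_w.origin).world_center()
    rho = _domain_radius(geom)
    npar = _n_params(params.family)
    q = np.zeros(npar)
    if initial_transform is not None:
        q = _q_from_linear(params.family, initial_transform, center, rho)
    delta = 0.5  # central-difference step, scaled units (~mm)

    iterations = []
    diverged_any = False
    n_total = all_pts.shape[1]
    for level, sigma in enumerate(params.pyramid_schedule):
        f_l = blur(fixed_w, sigma).data
        m_l = blur(moving_w, sigma).data.astype(float)
        sel = _sample_indices(n_total, params, level)
        pts = np.ascontiguousarray(all_pts[:, sel])
        fv = f_l.ravel()[sel].astype(float)

        def loss_only(qv):
            t = _linear_from_q(params.family, qv, center, rho)
            mv = _resample_at(m_l, moving_w, t.apply_points(pts), cval)
            loss, _ = _loss_and_dm(fv, mv, metric_name)
            return loss

        def loss_grad(qv):
            loss = loss_only(qv)
            g = np.empty_like(qv)
            for i in range(qv.size):
                qp = qv.copy(); qp[i] += delta
                qm = qv.copy(); qm[i] -= delta
                g[i] = (loss_only(qp) - loss_only(qm)) / (2 * delta)
            return loss, g

        q, _, its, diverged = _descend(q, loss_grad, params, min_spacing)
        iterations.append(its)
        diverged_any = diverged_any or diverged

    t_final = _linear_from_q(params.family, q, center, rho)
    converged = not diverged_any
    # guarantee no-worse-than-initial on the finest level
    t_init = (initial_transform if initial_transform is not None
              else LinearTransform.identity(center))
    final_metric, t_final, fell_back = _finalize(
        fixed_w, moving_w, all_pts, cval, metric_name, t_final, t_init, params)
    return RegistrationResult(t_final, final_metric, iterations,
                              converged and not fell_back)


def _register_bspline(fixed_w, moving_w, params, geom, all_pts, cval,
                      min_spacing, metric_name):
    gs_mm = params.bspline_grid_spacing * fixed_w.spacing
    t0 = BSplineTransform.for_domain(geom, gs_mm)
    cshape = t0.coefficients.shape
    ncp = int(np.prod(cshape[1:]))
    q = np.zeros(3 * ncp)

    iterations = []
    diverged_any = False
    n_total = all_pts.shape[1]
    for level, sigma in enumerate(params.pyramid_schedule):
        f_l = blur(fixed_w, sigma).data
        m_l = blur(moving_w, sigma).data.astype(float)
        grads = np.gradient(m_l)
        grads = [g / s for g, s in zip(grads, moving_w.spacing)]
        sel = _sample_indices(n_total, params, level)
        pts = np.ascontiguousarray(all_pts[:, sel])
        fv = f_l.ravel()[sel].astype(float)
        W = t0.basis_matrix(pts)
        WT = W.T.tocsr()

        def loss_grad(qv):
            coef = qv.reshape(3, ncp)
            disp = np.stack([W @ coef[a] for a in range(3)])
            y = pts + disp
            mv = _resample_at(m_l, moving_w, y, cval)
            loss, dm = _loss_and_dm(fv, mv, metric_name)
            g = np.empty_like(coef)
            for a in range(3):
                ga = _resample_at(grads[a], moving_w, y, 0.0)
                g[a] = WT @ (dm * ga)
            return loss, g.ravel()

        q, _, its, diverged = _descend(q, loss_grad, params, min_spacing)
        iterations.append(its)
        diverged_any = diverged_any or diverged

    t_final = BSplineTransform(t0.grid_origin, t0.grid_spacing,
                               q.reshape(cshape), geom)
    t_init = BSplineTransform(t0.grid_origin, t0.grid_spacing,
                              np.zeros(cshape), geom)
    final_metric, t_final, fell_back = _finalize(
        fixed_w, moving_w, all_pts, cval, metric_name, t_final, t_init, params)
    return RegistrationResult(t_final, final_metric, iterations,
                              (not diverged_any) and not fell_back)


def _better(metric_name: str, a: float, b: float) -> bool:
    """Is metric value ``a`` better than ``b``?"""
    return a < b if metric_name == "ssd" else a > b


def _finalize(fixed_w, moving_w, all_pts, cval, metric_name, t_final, t_init,
              params):
    """Evaluate the final metric; fall back to the initial transform if the
    optimization ended worse than it started (flagged as not converged)."""
    sel = _sample_indices(all_pts.shape[1], params, level=len(params.pyramid_schedule))
    pts = np.ascontiguousarray(all_pts[:, sel])
    fv = fixed_w.data.ravel()[sel].astype(float)
    m_data = moving_w.data.astype(float)

    def metric_of(t):
        mv = _resample_at(m_data, moving_w, t.apply_points(pts), cval)
        if metric_name == "ssd":
            return float(np.mean((mv - fv) ** 2))
        return _ncc(fv, mv)

    m_fin = metric_of(t_final)
    m_ini = metric_of(t_init)
    if _better(metric_name, m_ini, m_fin):  # optimization ended strictly worse
        return m_ini, t_init, True
    return m_fin, t_final, False
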