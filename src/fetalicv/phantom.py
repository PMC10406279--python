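"""Synthetic fetal-head phantoms with exact ground-truth ICV.

A phantom emulates the salient features of a 3D B-mode fetal head sweep: a
bright ellipsoidal cranial shell ("skull") enclosing textured brain tissue
with a few darker ventricle-like inclusions, multiplicative log-normal
speckle, an acoustic-shadow sector zeroed behind the skull, and zero padding
outside a conical sweep field of view.  The ground-truth ICV mask is the set
of voxel centers inside the inner cranial surface, so the true ICV (mask
voxel count x voxel volume) is exact by construction and any measurement
error is attributable to the registration pipeline alone.

An optional left-right asymmetry (shorter right half-axis plus a laterally
offset inclusion) makes the phantoms chiral, so a mirrored scan genuinely
mismatches an unmirrored model - the failure mode the consensus QC is
designed to catch.  Two size presets bracket the ~20-week (~100 cm^3) and
~30-week (~300 cm^3) intracranial volumes; they are labels for size classes,
not claims of anatomical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np

from .volume import BinaryMask, Volume, write_volume

__all__ = [
    "PhantomSpec",
    "make_head_phantom",
    "make_cohort",
    "preset_spec",
    "write_cohort",
]


@dataclass
class PhantomSpec:
    """Deterministic recipe for one synthetic head volume."""

    semi_axes: tuple = (26.0, 33.0, 28.0)   # inner cranial ellipsoid, mm
    shell_thickness: float = 3.0            # bright skull shell, mm
    tissue_mean: float = 90.0               # interior grayscale
    shell_mean: float = 220.0
    background_mean: float = 40.0
    speckle_sigma: float = 0.20             # log-normal multiplicative scale
    shadow_sector: tuple | None = (2, 40.0)  # (axis, angular width deg)
    orientation_label: str = "Left"
    spacing: tuple = (2.0, 2.0, 2.0)        # mm
    grid_shape: tuple = (48, 48, 48)
    internal_structures: int = 2            # darker ventricle-like inclusions
    seed: int = 0
    lr_asymmetry: float = 0.0   # fractional shortening of the +x half-axis
    notch_fraction: float = 0.0  # one-sided skull-base opening (0 = none)
    shell_lr_gradient: float = 0.0  # lateral echogenicity gradient of the shell
    center_offset_mm: tuple = (0.0, 0.0, 0.0)  # rigid jitter: translation
    rotation_deg: tuple = (0.0, 0.0, 0.0)      # rigid jitter: Euler angles
    sweep_apex_offset_mm: float = 24.0      # cone apex height above the grid

    def __post_init__(self) -> None:
        sa = np.asarray(self.semi_axes, float)
        if not (np.all(sa > self.shell_thickness) and self.shell_thickness > 0):
            raise ValueError("require semi_axes > shell_thickness > 0")
        if not (0 <= self.lr_asymmetry < 1):
            raise ValueError("lr_asymmetry must be in [0, 1)")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be nonnegative")
        sp = np.asarray(self.spacing, float)
        half_extent = np.asarray(self.grid_shape) * sp / 2.0
        outer = sa + self.shell_thickness
        if np.any(outer + 2 * sp > half_extent):
            raise ValueError("grid must contain the outer ellipsoid with a "
                             ">=2-voxel margin on each side")


def preset_spec(age_group: str, **overrides) -> PhantomSpec:
    """Size-class presets for the two gestational-age groups.

    ``"20w"`` gives an inner ellipsoid of ~100 cm^3, ``"30w"`` ~300 cm^3,
    bracketing the two cohort size classes.  Both presets are chiral
    (``lr_asymmetry`` 0.25) so Left/Right orientations are distinguishable.
    """
    if age_group == "20w":
        base = dict(semi_axes=(26.0, 33.0, 28.0), spacing=(2.0, 2.0, 2.0))
    elif age_group == "30w":
        base = dict(semi_axes=(38.0, 48.0, 41.0), spacing=(2.75, 2.75, 2.75))
    else:
        raise ValueError(f"unknown age group {age_group!r}")
    base.update(grid_shape=(48, 48, 48), lr_asymmetry=0.35,
                notch_fraction=0.35, shell_lr_gradient=0.35,
                internal_structures=4)
    base.update(overrides)
    return PhantomSpec(**base)


def _rotation_matrix(angles_deg) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_euler("xyz", np.asarray(angles_deg, float),
                               degrees=True).as_matrix()


def _inside_lr_ellipsoid(h: np.ndarray, semi_axes: np.ndarray,
                         asym: float) -> np.ndarray:
    """Points (3, N) in head frame inside the chiral (egg-like) ellipsoid.

    The +x half-axis is shortened by the asymmetry fraction; the surface
    remains continuous across x = 0.
    """
    ax_minus, ay, az = semi_axes
    ax_plus = ax_minus * (1.0 - asym)
    ax_eff = np.where(h[0] >= 0, ax_plus, ax_minus)
    q = (h[0] / ax_eff) ** 2 + (h[1] / ay) ** 2 + (h[2] / az) ** 2
    return q <= 1.0


def make_head_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask, float]:
    """Render one phantom; bit-identical for a fixed spec and seed.

    Returns the grayscale volume, the ground-truth ICV mask (voxel centers
    inside the inner cranial surface) and the exact true ICV in cm^3.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing, float)
    # origin centers the grid on world (0, 0, 0)
    origin = -spacing * (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    X = origin[:, None] + spacing[:, None] * idx   # world coords, (3, N)

    semi = np.asarray(spec.semi_axes, float)
    R = _rotation_matrix(spec.rotation_deg)
    c = np.asarray(spec.center_offset_mm, float)
    H = R.T @ (X - c[:, None])                     # head-frame coords

    inner = _inside_lr_ellipsoid(H, semi, spec.lr_asymmetry)
    outer = _inside_lr_ellipsoid(H, semi + spec.shell_thickness,
                                 spec.lr_asymmetry)

    img = np.full(X.shape[1], spec.background_mean)
    img[outer] = spec.shell_mean
    img[inner] = spec.tissue_mean

    # angle-dependent skull echogenicity: one flank of the shell reflects
    # more strongly than the other, a lateral brightness gradient that flips
    # under mirroring
    if spec.shell_lr_gradient != 0:
        shell_sel = outer & ~inner
        gain = 1.0 + spec.shell_lr_gradient * (H[0, shell_sel] / semi[0])
        img[shell_sel] = img[shell_sel] * np.clip(gain, 0.2, None)

    # skull-base-like opening: on the far -x side the bright shell is absent
    # and the tissue darker, a strongly one-sided intensity feature (the ICV
    # mask is unaffected; only the rendering changes)
    if spec.notch_fraction > 0:
        cut = -(1.0 - spec.notch_fraction) * semi[0]
        in_notch = H[0] <= cut
        img[in_notch & outer & ~inner] = spec.tissue_mean * 0.5
        img[in_notch & inner] = spec.tissue_mean * 0.6

    # lateralized internal structures with mixed contrast (dark
    # ventricle-like, bright choroid-plexus-like); their one-sided placement
    # makes the interior, like the outline, chiral
    inclusions = [((-0.40, 0.15, 0.0), 0.35), ((0.25, -0.30, 0.20), 2.0),
                  ((-0.15, 0.35, -0.30), 0.35), ((0.30, 0.10, 0.35), 2.0)]
    for k in range(min(spec.internal_structures, len(inclusions))):
        fc, contrast = inclusions[k]
        fc = np.asarray(fc) * semi + rng.uniform(-1.0, 1.0, 3)  # mm jitter
        r_inc = 0.22 * semi
        q = (((H - fc[:, None]) / r_inc[:, None]) ** 2).sum(axis=0)
        img[(q <= 1.0) & inner] = spec.tissue_mean * contrast

    if spec.speckle_sigma > 0:
        noise = rng.normal(0.0, spec.speckle_sigma, img.shape)
        img = img * np.exp(noise - spec.speckle_sigma**2 / 2.0)

    # acoustic shadow: zero a wedge outside the cranial interior
    if spec.shadow_sector is not None:
        axis, width_deg = spec.shadow_sector
        axes2d = [a for a in range(3) if a != int(axis)]
        phi = np.arctan2(X[axes2d[1]], X[axes2d[0]])
        in_wedge = np.abs(phi) <= np.deg2rad(width_deg) / 2.0
        img[in_wedge & ~inner] = 0.0

    # conical sweep field of view along axis 2, apex above the grid
    z_apex = origin[2] - spec.sweep_apex_offset_mm
    half_angle = np.deg2rad(65.0 / 2.0)
    lateral = np.sqrt(X[0] ** 2 + X[1] ** 2)
    in_cone = lateral <= np.tan(half_angle) * (X[2] - z_apex)
    img[~in_cone] = 0.0
    img = np.clip(img, 0.0, None)

    data = img.reshape(shape)
    mask = inner.reshape(shape).astype(np.uint8)
    if spec.orientation_label == "Right":
        data = np.flip(data, axis=0).copy()
        mask = np.flip(mask, axis=0).copy()

    vol = Volume(data, spacing, origin, orientation_label=spec.orientation_label)
    icv_mask = BinaryMask(mask, spacing, origin,
                          orientation_label=spec.orientation_label)
    return vol, icv_mask, icv_mask.volume_cm3


def make_cohort(n: int, base_spec: PhantomSpec,
                scale_range: tuple = (0.9, 1.1),
                jitter: bool = True, seed: int = 0,
                max_shift_mm: float = 4.0, max_rot_deg: float = 5.0) -> list:
    """A cohort of phantoms with inter-subject scale and pose variation.

    Each subject draws an isotropic scale uniformly from ``scale_range`` and,
    if ``jitter`` is on, a small rigid perturbation (uniform translation up
    to ``max_shift_mm``, Euler rotations up to ``max_rot_deg``); speckle is
    independent per subject.  Returns ``[(Volume, BinaryMask, true_icv_cm3),
    ...]``, deterministic per seed.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    lo, hi = float(scale_range[0]), float(scale_range[1])
    if hi < lo:
        raise ValueError("empty scale range")
    out = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        s = rng.uniform(lo, hi)
        shift = rng.uniform(-max_shift_mm, max_shift_mm, 3) if jitter else np.zeros(3)
        rot = rng.uniform(-max_rot_deg, max_rot_deg, 3) if jitter else np.zeros(3)
        spec_i = dc_replace(
            base_spec,
            semi_axes=tuple(s * np.asarray(base_spec.semi_axes)),
            center_offset_mm=tuple(shift),
            rotation_deg=tuple(rot),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(make_head_phantom(spec_i))
    return out


def write_cohort(cohort: list, out_dir: str | Path, prefix: str = "subj"):
    """Write cohort volumes/masks as NIfTI plus a manifest table (CSV).

    Returns the manifest as a pandas DataFrame (one row per subject with the
    file paths and exact true ICV).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, mask, true_icv) in enumerate(cohort):
        vid = f"{prefix}{i:03d}"
        vpath = out_dir / f"{vid}.nii.gz"
        mpath = out_dir / f"{vid}_mask.nii.gz"
        write_volume(vol, vpath)
        write_volume(mask, mpath)
        rows.append({"subject_id": vid, "volume": str(vpath), "mask": str(mpath),
                     "orientation": vol.orientation_label,
                     "true_icv_cm3": true_icv})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df
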