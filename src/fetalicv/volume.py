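"""Volumes, binary masks, NIfTI I/O and sweep-boundary preprocessing.

The scans handled here are 3D grayscale fetal-head ultrasound volumes exported
to NIfTI-1, together with binary intracranial-volume (ICV) masks defined on the
same voxel grid.  Geometry is axis-aligned: voxel ``(i, j, k)`` sits at world
position ``origin + spacing * (i, j, k)`` in millimetres.  Axis 0 is taken as
the left-right axis; the two mirror-image head orientations produced by the
ultrasound export are tracked with an explicit ``"Left"`` / ``"Right"`` label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "replace_zero_voxels",
    "canonicalize_orientation",
    "ORIENTATIONS",
]

ORIENTATIONS = ("Left", "Right")

#: axis along which Left/Right mirroring flips the data
LR_AXIS = 0


@dataclass
class Volume:
    """A 3D scalar image with axis-aligned geometry in mm."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation_label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def world_center(self) -> np.ndarray:
        """World coordinate of the geometric center of the grid."""
        return self.origin + self.spacing * (np.asarray(self.shape) - 1) / 2.0

    def geometry(self) -> "Geometry":
        return Geometry(tuple(self.shape), self.spacing.copy(), self.origin.copy())

    def same_geometry(self, other: "Volume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy(), spacing=self.spacing.copy(),
                       origin=self.origin.copy())


@dataclass
class Geometry:
    """Shape + spacing + origin of an axis-aligned grid (no pixel data)."""

    shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def voxel_centers_world(self) -> np.ndarray:
        """(3, N) world coordinates of all voxel centers, C-order."""
        idx = np.indices(self.shape, dtype=float).reshape(3, -1)
        return self.origin[:, None] + self.spacing[:, None] * idx


class BinaryMask(Volume):
    """A {0,1}-valued grid sharing the geometry conventions of :class:`Volume`."""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {vals[:10]}")
        self.data = arr.astype(np.uint8)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        """Mask volume: voxel count x single-voxel volume, in cm^3."""
        return self.voxel_count * self.voxel_volume_cm3


# ---------------------------------------------------------------------------
# NIfTI I/O


def _check_3d_header(img: nib.Nifti1Image, path: str | Path) -> None:
    if len(img.shape) == 4 and img.shape[3] == 1:
        return  # degenerate singleton 4th axis is tolerated
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D image in {path}, got shape {img.shape}")


def read_volume(path: str | Path, orientation_label: str = "unknown") -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    Spacing is taken from the header zooms and the origin from the affine
    translation.  The image must be 3D with strictly positive voxel sizes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    _check_3d_header(img, path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        data = data[..., 0]
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive spacing {spacing} in {path}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return Volume(data=data, spacing=spacing, origin=origin,
                  orientation_label=orientation_label)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI-1 file holding a {0,1} mask."""
    v = read_volume(path)
    return BinaryMask(data=(v.data > 0.5).astype(np.uint8), spacing=v.spacing,
                      origin=v.origin, orientation_label=v.orientation_label)


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a Volume or BinaryMask as NIfTI-1.

    Masks are stored with an 8-bit integer scalar type; grayscale volumes as
    float32.  The affine is diagonal (axis-aligned grid) with the volume's
    spacing and origin.
    """
    path = Path(path)
    affine = np.diag(np.append(v.spacing, 1.0))
    affine[:3, 3] = v.origin
    if isinstance(v, BinaryMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(v.spacing))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Sweep-boundary preprocessing


def replace_zero_voxels(v: Volume) -> Volume:
    """Fill exactly-zero voxels with the mean grayscale of the nonzero voxels.

    Zero voxels in exported ultrasound volumes are padding outside the sweep
    field of view (plus acoustic-shadow dropout); the sharp black border they
    create misleads intensity-based registration.  Replacing them with the
    mean of the *nonzero* voxels turns black padding gray without shifting the
    fill value toward black (which averaging over all voxels, zeros included,
    would do).
    """
    zero = v.data == 0
    nonzero_count = v.data.size - int(zero.sum())
    if nonzero_count == 0:
        raise ValueError("all-zero volume: no nonzero voxels to average")
    if not zero.any():
        return v.copy()
    fill = float(v.data[~zero].mean())
    out = v.data.astype(np.float64, copy=True)
    out[zero] = fill
    return replace(v, data=out)


def canonicalize_orientation(v: Volume, target: str) -> Volume:
    """Mirror a volume into the requested Left/Right head orientation.

    The export chain produces two mirror-image head orientations; scans are
    mirrored along the left-right axis into the orientation of the brain model
    they will be registered to.  Applying the operation twice with swapped
    targets restores the original data (involution), and the grayscale
    histogram is preserved exactly.
    """
    if target not in ORIENTATIONS:
        raise ValueError(f"target orientation must be one of {ORIENTATIONS}")
    if v.orientation_label not in ORIENTATIONS:
        raise ValueError(
            "volume orientation is unknown; label it 'Left' or 'Right' "
            "(manual sorting) before canonicalization"
        )
    if v.orientation_label == target:
        return v.copy()
    out = replace(v, data=np.flip(v.data, axis=LR_AXIS).copy())
    out.orientation_label = target
    return out
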