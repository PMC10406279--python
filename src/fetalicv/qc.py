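"""Consensus quality control for automatic ICV measurements.

Two checks guard each measurement.  First, the two independently implemented
registration pipelines must agree: the standard deviation of their two ICV
values is compared against a threshold, either an absolute bound in cm^3 or a
fraction of the mean ICV (a band of roughly 7.5-12% of the mean is the
practical range; 10% is the default).  Second, the elastix-style pipeline's
final registration average must overlap the subject scan: the overlap
similarity

    Similarity = sum(a * b) / sqrt(sum(a^2) * sum(b^2))

over all voxels ranges from 0 (no overlap) to 1 (full overlap) for
nonnegative images, and values below 0.7 indicate a wrong registration.

The module also houses the mask smoothing used when finalizing ICV masks
(3x3x3 median filter applied three times) and the overlay rendering that
supports visual inspection of failed cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter

from .volume import BinaryMask, Volume

__all__ = [
    "QCDecision",
    "overlap_similarity",
    "two_value_sd",
    "sd_gate",
    "similarity_gate",
    "smooth_mask",
    "render_overlay",
    "SIMILARITY_FLOOR",
]

#: pass floor of the overlap-similarity gate ("below 0.7" fails; 0.7 passes)
SIMILARITY_FLOOR = 0.7


@dataclass
class QCDecision:
    """Outcome of the consensus gates for one subject."""

    sd_value: float                 # cm^3
    sd_threshold: float             # cm^3
    threshold_rule: str             # absolute | fraction_of_mean
    fraction: float = 0.10
    similarity: float | None = None  # in [0, 1]; None if not computed
    verdict: str = "pass"           # pass | retry | excluded
    reason: str = ""

    def __post_init__(self) -> None:
        if self.threshold_rule not in ("absolute", "fraction_of_mean"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.verdict not in ("pass", "retry", "excluded"):
            raise ValueError(f"unknown verdict {self.verdict!r}")


def overlap_similarity(a: Volume | np.ndarray, b: Volume | np.ndarray) -> float:
    """Overlap similarity sum(a*b) / sqrt(sum(a^2) * sum(b^2)).

    Both inputs must share a grid and be nonnegative with at least one
    nonzero voxel; the value is then in [0, 1]: 1 for full overlap (e.g. any
    volume against itself), 0 when the nonzero supports are disjoint.
    """
    x = (a.data if isinstance(a, Volume) else np.asarray(a)).astype(float)
    y = (b.data if isinstance(b, Volume) else np.asarray(b)).astype(float)
    if x.shape != y.shape:
        raise ValueError("overlap_similarity requires identical grids")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("overlap_similarity requires nonnegative intensities")
    sx = float(np.sum(x * x))
    sy = float(np.sum(y * y))
    if sx == 0 or sy == 0:
        raise ValueError("overlap similarity undefined for an all-zero volume")
    return float(np.sum(x * y) / np.sqrt(sx * sy))


def two_value_sd(a: float, b: float) -> float:
    """Sample standard deviation of two values, |a - b| / sqrt(2).

    The sample (n-1) convention is the conservative choice: it is sqrt(2)
    times larger than the population SD of the pair, so the gate errs toward
    flagging disagreement.
    """
    return abs(a - b) / np.sqrt(2.0)


def sd_gate(icv_a: float, icv_b: float, rule: str = "fraction_of_mean",
            threshold_or_fraction: float = 0.10) -> QCDecision:
    """Agreement gate on the two pipelines' ICVs.

    ``absolute`` compares the two-value SD against a fixed cm^3 threshold
    (10 cm^3 at 20 weeks and 20 cm^3 at 30 weeks are the reference choices);
    ``fraction_of_mean`` against ``fraction x mean(icv_a, icv_b)``.
    """
    if icv_a <= 0 or icv_b <= 0:
        raise ValueError("ICV values must be positive")
    if threshold_or_fraction <= 0:
        raise ValueError("threshold/fraction must be positive")
    sd = two_value_sd(icv_a, icv_b)
    if rule == "absolute":
        thr = float(threshold_or_fraction)
        frac = 0.0
    elif rule == "fraction_of_mean":
        frac = float(threshold_or_fraction)
        thr = frac * (icv_a + icv_b) / 2.0
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    ok = sd <= thr
    return QCDecision(
        sd_value=sd, sd_threshold=thr, threshold_rule=rule, fraction=frac,
        verdict="pass" if ok else "retry",
        reason="" if ok else f"pipeline SD {sd:.3g} cm^3 exceeds {thr:.3g} cm^3",
    )


def similarity_gate(sim: float, floor: float = SIMILARITY_FLOOR) -> bool:
    """True iff the overlap similarity passes (fails only strictly below floor)."""
    if not (0.0 <= sim <= 1.0 + 1e-12):
        raise ValueError(f"similarity must be in [0, 1], got {sim}")
    return sim >= floor


def smooth_mask(m: BinaryMask, kernel: int = 3, repeats: int = 3) -> BinaryMask:
    """Median-smooth a binary mask: kernel^3 median filter applied repeatedly.

    The default (kernel of three voxels, three passes) removes isolated
    voxels and gently rounds the mask boundary without materially changing
    its volume.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    out = m.data.astype(np.uint8)
    for _ in range(repeats):
        out = median_filter(out, size=kernel, mode="constant", cval=0)
    return BinaryMask(out, m.spacing, m.origin, orientation_label=m.orientation_label)


_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}


def render_overlay(v: Volume, m: BinaryMask, out_dir: str | Path,
                   subject_id: str = "subject",
                   planes: tuple = ("axial", "coronal", "sagittal"),
                   slice_index: int | None = None) -> list[Path]:
    """Write per-plane PNGs of the mask contour over the grayscale slice.

    Supports the visual part of quality control: when the SD gate flags a
    subject, the overlays show which pipeline's mask went wrong.  Files are
    named ``{subject_id}_{plane}.png``; an empty mask produces contour-free
    images with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not v.same_geometry(m):
        raise ValueError("volume and mask must share geometry")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if m.voxel_count == 0:
        import warnings
        warnings.warn(f"empty mask for {subject_id}: overlays have no contour")
    written = []
    for plane in planes:
        if plane not in _PLANE_AXIS:
            raise ValueError(f"unknown plane {plane!r}")
        ax_idx = _PLANE_AXIS[plane]
        n = v.shape[ax_idx]
        idx = n // 2 if slice_index is None else int(slice_index)
        if not (0 <= idx < n):
            raise IndexError(f"slice index {idx} out of range for {plane} (n={n})")
        sl = [slice(None)] * 3
        sl[ax_idx] = idx
        img = v.data[tuple(sl)]
        msk = m.data[tuple(sl)]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(img.T, cmap="gray", origin="lower")
        if msk.any():
            ax.contour(msk.T, levels=[0.5], colors="lime", linewidths=1.0)
        ax.set_title(f"{subject_id} {plane} [{idx}]", fontsize=8)
        ax.axis("off")
        path = out_dir / f"{subject_id}_{plane}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
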