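"""Searchlight geometry: sphere offsets, neighborhood index, map smoothing.

A searchlight is the set of in-mask voxels within a fixed radius of a center
voxel; one searchlight is placed on every in-mask voxel, and neighborhoods are
truncated (not padded) at mask and grid boundaries. The default distance metric
is voxel-index units; a millimetre metric is available for anisotropic voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import Mask

__all__ = ["SphereSpec", "SearchlightIndex", "sphere_offsets", "build_index",
           "smooth_map", "fwhm_to_sigma"]

#: FWHM of a Gaussian = 2*sqrt(2 ln 2) * sigma
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SphereSpec:
    """Searchlight sphere: radius plus the metric the radius is measured in."""

    radius: float = 3.0
    metric: str = "voxel"  # "voxel" (index units) or "mm"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be non-negative, got {self.radius}")
        if self.metric not in ("voxel", "mm"):
            raise ValueError(f"metric must be 'voxel' or 'mm', got {self.metric!r}")


@dataclass
class SearchlightIndex:
    """Per-center neighborhoods expressed as in-mask column indices."""

    centers: np.ndarray                 # flat (C-order) voxel indices, mask order
    neighborhoods: list                 # per center: int array of TrialSet columns
    k_total: int
    shape: tuple[int, int, int]
    small: np.ndarray = field(default=None)  # True where size < min_voxels

    def sizes(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighborhoods])


def sphere_offsets(spec: SphereSpec, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """All integer index offsets within the sphere, in sorted (lexicographic) order.

    Under the "voxel" metric the radius is compared against the Euclidean norm of
    the index offset; under "mm" each axis is first scaled by its voxel size.
    Always contains (0, 0, 0).
    """
    if not np.isfinite(spec.radius):
        raise ValueError("radius must be finite")
    scale = np.ones(3) if spec.metric == "voxel" else np.asarray(voxel_size, float)
    if np.any(scale <= 0):
        raise ValueError("voxel sizes must be positive")
    reach = [int(math.floor(spec.radius / s)) for s in scale]
    ax = [np.arange(-r, r + 1) for r in reach]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    d2 = (offs * scale) ** 2
    keep = d2.sum(axis=1) <= spec.radius ** 2 + 1e-12
    offs = offs[keep]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return offs[order]


def build_index(mask: Mask, spec: SphereSpec, voxel_size=(1.0, 1.0, 1.0),
                min_voxels: int = 2) -> SearchlightIndex:
    """One searchlight per in-mask voxel; neighborhoods intersected with the mask.

    Searchlights with fewer than ``min_voxels`` members (possible at boundaries)
    are flagged in ``small`` but retained.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot build a searchlight index on an empty mask")
    shape = mask.shape
    offs = sphere_offsets(spec, voxel_size)
    # map each in-mask voxel to its TrialSet column
    col_of = np.full(shape, -1, dtype=np.int64)
    flat = mask.linear_indices()
    col_of.ravel()[flat] = np.arange(len(flat))
    centers_ijk = np.column_stack(np.nonzero(mask.members))
    neighborhoods = []
    for c in centers_ijk:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        cols = col_of[pts[:, 0], pts[:, 1], pts[:, 2]]
        neighborhoods.append(cols[cols >= 0].astype(np.int64))
    small = np.array([len(n) < min_voxels for n in neighborhoods])
    return SearchlightIndex(centers=flat, neighborhoods=neighborhoods,
                            k_total=len(flat), shape=shape, small=small)


def fwhm_to_sigma(fwhm_mm: float, voxel_size) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return fwhm_mm / _FWHM_PER_SIGMA / np.asarray(voxel_size, dtype=float)


def smooth_map(values: np.ndarray, fwhm_mm: float, mask: Mask,
               voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Mask-normalized Gaussian smoothing of an in-mask value vector.

    The value field (zero-filled outside the mask) and the mask indicator are
    convolved with the same Gaussian kernel and divided, so voxels near the mask
    boundary are renormalized rather than pulled toward the background; a
    constant map therefore stays constant. ``fwhm_mm = 0`` returns a copy.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be non-negative, got {fwhm_mm}")
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_voxels,):
        raise ValueError("values length must equal the mask voxel count")
    if fwhm_mm == 0:
        return values.copy()
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size)
    vol = np.zeros(mask.shape)
    vol.ravel()[mask.linear_indices()] = values
    num = gaussian_filter(vol, sigma=sigma, mode="constant")
    den = gaussian_filter(mask.members.astype(np.float64), sigma=sigma, mode="constant")
    out = np.zeros_like(vol)
    inm = mask.members
    out[inm] = num[inm] / den[inm]
    return out.ravel()[mask.linear_indices()]
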