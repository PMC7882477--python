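"""Volumetric IO and the masking/linearization contract.

All modules share one spatial convention: voxel indices are 0-based ``(i, j, k)``
array indices, world coordinates exist only through the NIfTI affine, and an
in-mask voxel vector is linearized in C (row-major) order of the mask array,
i.e. the column order of a :class:`TrialSet` is ``np.flatnonzero(mask.members)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.filebasedimages import ImageFileError

__all__ = [
    "VolumeGrid",
    "Mask",
    "TrialSet",
    "load_volume",
    "save_map",
    "load_mask",
    "stack_trials",
    "scatter_to_grid",
    "load_labels",
    "save_labels",
]


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel-size metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        One scalar per voxel.
    affine : ndarray, shape (4, 4)
        Voxel-index to world (mm) map.
    voxel_size : tuple of float
        Physical edge length per axis in mm; all components must be positive.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate volume shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Mask:
    """A boolean voxel-membership volume."""

    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.members.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={self.members.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.members.shape

    @property
    def n_voxels(self) -> int:
        return int(self.members.sum())

    def linear_indices(self) -> np.ndarray:
        """C-order flat indices of in-mask voxels — the TrialSet column order."""
        return np.flatnonzero(self.members)


@dataclass
class TrialSet:
    """Trial-by-voxel activation matrix with binary condition labels.

    ``activations[i]`` is the in-mask voxel vector of trial ``i`` (column order
    per :meth:`Mask.linear_indices`); ``labels`` take values in {+1, -1}.
    """

    activations: np.ndarray
    labels: np.ndarray
    run_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.activations.ndim != 2:
            raise ValueError("activations must be a 2-D trial-by-voxel matrix")
        if self.labels.shape != (self.activations.shape[0],):
            raise ValueError("labels length must equal the number of trials")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
        if len(set(np.unique(self.labels))) < 2:
            raise ValueError("both condition labels (+1 and -1) must be present")
        if not np.all(np.isfinite(self.activations)):
            raise ValueError("activations contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.activations.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.activations.shape[1]


def load_volume(path) -> VolumeGrid:
    """Load a single 3-D NIfTI-1 volume; no resampling or reorientation.

    Raises
    ------
    ValueError
        If the file is not a readable NIfTI volume or is not 3-D.
    """
    try:
        img = nib.load(str(path))
    except ImageFileError as exc:
        raise ValueError(f"not a readable volume file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={data.ndim}: {path}")
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(data=np.asarray(data, dtype=np.float64), affine=img.affine,
                      voxel_size=tuple(float(z) for z in zooms))


def _make_img(data: np.ndarray, like: VolumeGrid | None, voxel_size) -> nib.Nifti1Image:
    if like is not None:
        affine = like.affine
    else:
        affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(voxel_size)
    return img


def save_map(grid: VolumeGrid, mask: Mask, path) -> None:
    """Write a map as NIfTI, setting out-of-mask voxels to the background value 0.

    In-mask values are written at double precision.
    """
    if grid.shape != mask.shape:
        raise ValueError(f"map shape {grid.shape} != mask shape {mask.shape}")
    if mask.n_voxels == 0:
        raise ValueError("mask has no member voxels")
    out = np.where(mask.members, grid.data, 0.0)
    _make_img(out, grid, grid.voxel_size).to_filename(str(path))


def load_mask(path) -> Mask:
    """Load a mask volume; nonzero finite voxels are members (NaN = out-of-mask)."""
    grid = load_volume(path)
    members = np.isfinite(grid.data) & (grid.data != 0)
    return Mask(members=members)


def stack_trials(volumes, labels, mask: Mask, run_id=None) -> TrialSet:
    """Stack one volume per trial into a :class:`TrialSet` over ``mask``."""
    volumes = list(volumes)
    labels = np.asarray(labels, dtype=int)
    if len(volumes) != len(labels):
        raise ValueError("number of volumes must equal number of labels")
    flat = mask.linear_indices()
    rows = []
    for i, vol in enumerate(volumes):
        if vol.shape != mask.shape:
            raise ValueError(
                f"volume {i} shape {vol.shape} does not match mask shape {mask.shape}")
        rows.append(vol.data.ravel()[flat])
    return TrialSet(activations=np.vstack(rows), labels=labels,
                    run_id=None if run_id is None else np.asarray(run_id, dtype=int))


def scatter_to_grid(values: np.ndarray, mask: Mask, background: float = 0.0) -> np.ndarray:
    """Scatter an in-mask value vector back to a full 3-D array."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_voxels,):
        raise ValueError(
            f"expected {mask.n_voxels} in-mask values, got {values.shape}")
    out = np.full(np.prod(mask.shape), background, dtype=np.float64)
    out[mask.linear_indices()] = values
    return out.reshape(mask.shape)


def load_labels(path) -> np.ndarray:
    """Read per-trial labels from a two-column text table (trial index, label)."""
    table = np.loadtxt(str(path), dtype=int, ndmin=2)
    if table.shape[1] != 2:
        raise ValueError("labels table must have two columns: trial index, label")
    order = np.argsort(table[:, 0])
    return table[order, 1]


def save_labels(labels, path) -> None:
    labels = np.asarray(labels, dtype=int)
    table = np.column_stack([np.arange(len(labels)), labels])
    np.savetxt(str(path), table, fmt="%d")
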