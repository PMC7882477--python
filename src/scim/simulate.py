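"""Synthetic trial datasets with a known informative template region.

Each simulated dataset emulates a sparse-imaging decoding experiment: 80
trials (40 per condition), one acquired volume per trial. Outside a binary
"template" mask, voxel activations are drawn per trial from one normal
distribution common to both conditions (no information anywhere). Inside the
template, activations are drawn from class-specific normal distributions and
then spatially smoothed with a 3-mm-FWHM Gaussian to introduce the local
spatial correlations that real BOLD activations show; the template therefore
defines the ground truth against which result maps are scored.

Default moments: background N(0, 1), in-template class means +/- delta/2 with
delta = 0.5 and unit class SDs. Default grid 30 x 30 x 20 voxels at 3 x 3 x 4
mm. All randomness derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import Mask, TrialSet
from .searchlight import SphereSpec, fwhm_to_sigma, sphere_offsets

__all__ = ["SimulationSpec", "build_template_mask", "simulate_trials"]


@dataclass
class SimulationSpec:
    """Generator settings; defaults are the study conditions."""

    grid_shape: tuple[int, int, int] = (30, 30, 20)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)
    template: Mask | None = None          # None -> one centered radius-3 blob
    n_per_class: tuple[int, int] = (40, 40)
    background_mean: float = 0.0
    background_sd: float = 1.0
    class_means: tuple[float, float] = (0.25, -0.25)   # (+1 class, -1 class)
    class_sds: tuple[float, float] = (1.0, 1.0)
    fwhm: float = 3.0                     # mm, in-template smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.class_sds) or self.background_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("need at least one trial per class")

    @property
    def n_trials(self) -> int:
        return sum(self.n_per_class)


def build_template_mask(grid_shape, blobs, voxel_size=(1.0, 1.0, 1.0),
                        metric: str = "voxel") -> Mask:
    """Union of spheres: ``blobs`` is a list of ``(center_ijk, radius)``.

    Blobs entirely outside the grid contribute nothing (with a warning).
    """
    members = np.zeros(grid_shape, dtype=bool)
    any_inside = False
    for center, radius in blobs:
        offs = sphere_offsets(SphereSpec(radius=radius, metric=metric), voxel_size)
        pts = np.asarray(center, int) + offs
        ok = np.all((pts >= 0) & (pts < np.asarray(grid_shape)), axis=1)
        if not ok.any():
            import warnings
            warnings.warn(f"template blob at {tuple(center)} lies entirely "
                          "outside the grid", stacklevel=2)
            continue
        any_inside = True
        pts = pts[ok]
        members[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    if not any_inside:
        raise ValueError("no template blob intersects the grid")
    return Mask(members=members)


def _default_template(grid_shape, voxel_size) -> Mask:
    # radius shrinks on small grids so the template never fills the volume
    center = tuple(s // 2 for s in grid_shape)
    radius = float(max(1, min(3, min(grid_shape) // 2 - 1)))
    return build_template_mask(grid_shape, [(center, radius)], voxel_size)


def simulate_trials(spec: SimulationSpec):
    """Generate one dataset: returns ``(TrialSet, brain_mask, template_mask)``.

    The brain mask is the full grid. The balanced +1/-1 label sequence is
    shuffled by the seed; the whole dataset is a pure function of ``spec``.
    """
    template = spec.template or _default_template(spec.grid_shape, spec.voxel_size)
    if template.shape != tuple(spec.grid_shape):
        raise ValueError("template mask shape does not match the grid")
    if template.n_voxels == 0:
        raise ValueError("template mask is empty")
    brain = Mask(members=np.ones(spec.grid_shape, dtype=bool))

    rng = np.random.default_rng(spec.seed)
    labels = np.r_[np.ones(spec.n_per_class[0], int), -np.ones(spec.n_per_class[1], int)]
    rng.shuffle(labels)

    tmpl = template.members
    sigma = fwhm_to_sigma(spec.fwhm, spec.voxel_size) if spec.fwhm > 0 else None
    if sigma is not None:
        tmpl_f = gaussian_filter(tmpl.astype(np.float64), sigma=sigma, mode="constant")

    flat = brain.linear_indices()
    rows = np.empty((spec.n_trials, brain.n_voxels))
    for i, lab in enumerate(labels):
        vol = rng.normal(spec.background_mean, spec.background_sd, spec.grid_shape)
        ci = 0 if lab == 1 else 1
        act = rng.normal(spec.class_means[ci], spec.class_sds[ci], spec.grid_shape)
        if sigma is not None:
            # mask-normalized smoothing confined to the template, so the
            # class signal correlates across neighbors but does not leak out
            num = gaussian_filter(np.where(tmpl, act, 0.0), sigma=sigma, mode="constant")
            act = np.where(tmpl, num / np.where(tmpl, tmpl_f, 1.0), 0.0)
        vol = np.where(tmpl, act, vol)
        rows[i] = vol.ravel()[flat]
    return TrialSet(activations=rows, labels=labels), brain, template
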