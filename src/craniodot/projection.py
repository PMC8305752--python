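"""Spatial scalp projection and spherical masks.

The classic cranio-cerebral correspondence estimator: a scalp location is
projected along the ray toward the brain centre; the first point where the
ray enters the brain mask is the cortical intersection, and the Euclidean
distance from the scalp position to it is the scalp-projection
scalp-to-cortex distance.  A variant that returns the globally nearest
brain-surface voxel is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import SegmentedHeadVolume

__all__ = ["ProjectionResult", "project_to_cortex", "spherical_mask",
           "EmptyMaskError"]


class EmptyMaskError(ValueError):
    """A spherical mask contains no brain voxels where they are required."""


@dataclass(frozen=True)
class ProjectionResult:
    electrode: str
    scalp_position: tuple[float, float, float]
    intersection: tuple[float, float, float]
    projection_distance_mm: float
    direction: tuple[float, float, float]

    @property
    def intersection_xyz(self) -> np.ndarray:
        return np.asarray(self.intersection)


def project_to_cortex(position: np.ndarray, head: SegmentedHeadVolume,
                      name: str = "", mode: str = "first_entry") -> ProjectionResult:
    """Project a scalp position to the brain surface.

    ``mode='first_entry'`` (default) marches from the position toward the
    brain-mask centroid in quarter-voxel steps and refines the first brain
    entry by bisection to 0.05 mm.  ``mode='global_nearest'`` instead
    returns the brain-surface voxel centre closest to the scalp position.
    """
    p = np.asarray(position, dtype=float)
    brain = head.brain_mask
    if not brain.any():
        raise ValueError("head model has an empty brain mask")

    if mode == "global_nearest":
        surf_ijk = _brain_surface_voxels(head, brain)
        pts = head.ijk_to_world(surf_ijk)
        d = np.linalg.norm(pts - p, axis=1)
        k = int(np.argmin(d))
        u = (pts[k] - p) / max(d[k], 1e-12)
        return ProjectionResult(name, tuple(p), tuple(pts[k]), float(d[k]), tuple(u))
    if mode != "first_entry":
        raise ValueError(f"unknown projection mode {mode!r}")

    centroid = head.brain_centroid()
    u = centroid - p
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise ValueError("scalp position coincides with the brain centroid")
    u = u / nu

    def inside(t: float) -> bool:
        q = np.rint(head.world_to_ijk(p + t * u)).astype(int)
        if np.any(q < 0) or np.any(q >= head.shape):
            return False
        return bool(brain[tuple(q)])

    step = 0.25 * head.voxel_size_mm
    t_max = nu + np.linalg.norm(np.asarray(head.shape)) * head.voxel_size_mm
    t = 0.0
    while not inside(t):
        t += step
        if t > t_max:
            raise ValueError(
                "projection ray exited the volume without entering the brain "
                "(malformed head model)")
    lo, hi = max(t - step, 0.0), t
    while hi - lo > 0.05:
        mid = 0.5 * (lo + hi)
        if inside(mid):
            hi = mid
        else:
            lo = mid
    t_hit = hi
    q = p + t_hit * u
    return ProjectionResult(name, tuple(p), tuple(q), float(t_hit), tuple(u))


def _brain_surface_voxels(head: SegmentedHeadVolume, brain: np.ndarray) -> np.ndarray:
    """Indices of brain voxels with at least one 6-neighbour outside the mask."""
    from scipy.ndimage import binary_erosion
    core = binary_erosion(brain)
    return np.argwhere(brain & ~core)


def spherical_mask(center: np.ndarray, radius_mm: float,
                   head: SegmentedHeadVolume, brain_only: bool = False
                   ) -> np.ndarray:
    """Voxel indices (N, 3) whose centres lie within ``radius_mm`` of a point.

    With ``brain_only=True`` the mask is restricted to brain voxels and an
    :class:`EmptyMaskError` is raised if none fall inside the sphere.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    c = np.asarray(center, dtype=float)
    cijk = head.world_to_ijk(c)
    rvox = radius_mm / head.voxel_size_mm
    lo = np.maximum(np.floor(cijk - rvox).astype(int), 0)
    hi = np.minimum(np.ceil(cijk + rvox).astype(int) + 1, head.shape)
    if np.any(lo >= hi):
        idx = np.empty((0, 3), dtype=int)
    else:
        ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                                 indexing="ij")
        box = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        d2 = np.sum((box - cijk) ** 2, axis=1)
        idx = box[d2 <= rvox ** 2]
    if brain_only:
        if len(idx):
            keep = head.brain_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
            idx = idx[keep]
        if len(idx) == 0:
            raise EmptyMaskError(
                f"no brain voxels within {radius_mm} mm of {np.round(c, 1)}")
    return idx
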