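"""Channel PMDFs and the DOT scalp-to-cortex distance estimators.

Three estimators of the distance from a scalp location to the cortex:

* ``scalp_projection`` — geometric (see :mod:`.projection`);
* ``direct_dot`` — distance to the brain voxel with maximum single-optode
  fluence inside a spherical search mask;
* ``sd_channel_dot`` — distance to the voxel with maximum source-detector
  channel sensitivity (PMDF, the voxelwise product of the source and
  detector fluence volumes) inside the mask.

The search mask is a 15 mm sphere centred, by default, on the cortical
projection point of the electrode / channel location; centring on the raw
scalp location is available behind a flag (the two conventions appear
interchangeably in the literature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Channel
from .phantom import SegmentedHeadVolume
from .projection import ProjectionResult, project_to_cortex, spherical_mask
from .transport import FluenceVolume

__all__ = ["PMDFVolume", "DistanceRecord", "compute_pmdf",
           "direct_dot_distance", "sd_channel_distance", "DEFAULT_RADIUS_MM"]

DEFAULT_RADIUS_MM = 15.0


@dataclass
class PMDFVolume:
    """Photon measurement density function of one S-D channel.

    Voxelwise product of the source and detector fluence volumes (arbitrary
    units); symmetric under swapping source and detector.
    """

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    def argmax_in(self, idx: np.ndarray) -> tuple[np.ndarray, float]:
        vals = self.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        k = int(np.argmax(vals))
        return idx[k], float(vals[k])


@dataclass(frozen=True)
class DistanceRecord:
    location: str
    method: str                       # scalp_projection | direct_dot | sd_channel_dot
    distance_mm: float                # NaN when flagged
    target_ijk: tuple[int, int, int] | None
    profile: str = ""
    status: str = "ok"                # ok | no_fluence


def compute_pmdf(src: FluenceVolume, det: FluenceVolume,
                 channel: str = "") -> PMDFVolume:
    """Elementwise product of two fluence volumes on the same grid."""
    if src.data.shape != det.data.shape:
        raise ValueError("source and detector fluence grids differ in shape")
    if src.voxel_size_mm != det.voxel_size_mm or \
            not np.allclose(src.origin_mm, det.origin_mm):
        raise ValueError("source and detector fluence grids differ in geometry")
    return PMDFVolume(src.data * det.data, src.voxel_size_mm,
                      src.origin_mm.copy(), channel=channel)


def _masked_argmax(volume, scalp_pos: np.ndarray, head: SegmentedHeadVolume,
                   mask_idx: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Max-value voxel in the mask; ties broken toward the scalp position,
    then by lowest linear index.  None when the field is all zero there."""
    vals = volume.data[mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2]]
    vmax = vals.max()
    if vmax <= 0.0:
        return None
    ties = mask_idx[vals == vmax]
    if len(ties) > 1:
        pts = head.ijk_to_world(ties)
        d = np.linalg.norm(pts - scalp_pos, axis=1)
        lin = np.ravel_multi_index(ties.T, head.shape)
        order = np.lexsort((lin, np.round(d, 9)))
        ties = ties[order]
    return ties[0], float(vmax)


def _anchor_point(scalp_pos: np.ndarray, head: SegmentedHeadVolume,
                  projection: ProjectionResult | None,
                  mask_center: str) -> np.ndarray:
    if mask_center == "projection":
        if projection is None:
            projection = project_to_cortex(scalp_pos, head)
        return projection.intersection_xyz
    if mask_center == "scalp":
        return np.asarray(scalp_pos, dtype=float)
    raise ValueError(f"unknown mask_center {mask_center!r}")


def direct_dot_distance(electrode: str, scalp_pos: np.ndarray,
                        fluence: FluenceVolume, projection: ProjectionResult,
                        head: SegmentedHeadVolume,
                        radius_mm: float = DEFAULT_RADIUS_MM,
                        mask_center: str = "projection",
                        profile: str = "") -> DistanceRecord:
    """Distance from the electrode to the peak direct-DOT fluence voxel."""
    center = _anchor_point(scalp_pos, head, projection, mask_center)
    idx = spherical_mask(center, radius_mm, head, brain_only=True)
    hit = _masked_argmax(fluence, np.asarray(scalp_pos), head, idx)
    if hit is None:
        return DistanceRecord(electrode, "direct_dot", float("nan"), None,
                              profile, status="no_fluence")
    tgt, _ = hit
    d = float(np.linalg.norm(head.ijk_to_world(tgt) - np.asarray(scalp_pos)))
    return DistanceRecord(electrode, "direct_dot", d, tuple(int(v) for v in tgt),
                          profile)


def sd_channel_distance(channel: Channel, pmdf: PMDFVolume,
                        head: SegmentedHeadVolume,
                        radius_mm: float = DEFAULT_RADIUS_MM,
                        scalp_position: np.ndarray | None = None,
                        projection: ProjectionResult | None = None,
                        mask_center: str = "projection",
                        profile: str = "") -> DistanceRecord:
    """Distance from the channel's scalp location to its PMDF peak voxel.

    The channel scalp location defaults to the channel's scalp-snapped
    source-detector midpoint; the pipeline passes the centre electrode
    position (the point equidistant from source and detector on the
    layout), which coincides with it for along-curve channels.
    """
    sp = np.asarray(scalp_position if scalp_position is not None
                    else channel.midpoint, dtype=float)
    center = _anchor_point(sp, head, projection, mask_center)
    idx = spherical_mask(center, radius_mm, head, brain_only=True)
    hit = _masked_argmax(pmdf, sp, head, idx)
    name = channel.center_name
    if hit is None:
        return DistanceRecord(name, "sd_channel_dot", float("nan"), None,
                              profile, status="no_fluence")
    tgt, _ = hit
    d = float(np.linalg.norm(head.ijk_to_world(tgt) - sp))
    return DistanceRecord(name, "sd_channel_dot", d, tuple(int(v) for v in tgt),
                          profile)
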