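"""Probabilistic scalp-location-to-ROI mapping and look-up tables.

For every scalp location a 15 mm sphere is placed at the method-specific
cortical anchor (projection intersection or fluence/PMDF peak) and the
atlas regions of the brain voxels inside the sphere are tabulated as
percentages.  Tables built per age profile are classified for cross-age
consistency by thresholding each profile's region list (boundary-inclusive,
default 25%) and comparing the surviving region sets: identical sets across
all profiles are *consistent*, a nonempty intersection is *partial*, an
empty intersection is *discrepant*.  Channel specificity expresses the
share of a channel's total in-brain PMDF sensitivity attributable to each
region.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import AtlasVolume, SegmentedHeadVolume
from .projection import EmptyMaskError, spherical_mask
from .sensitivity import DEFAULT_RADIUS_MM, PMDFVolume

__all__ = ["RoiMappingRow", "ConsistencyReport", "SpecificityRow",
           "map_location_to_rois", "build_lookup_table",
           "consistency_across_profiles", "channel_specificity",
           "lookup_table_frame", "lookup_table_json"]

log = logging.getLogger("craniodot.roi")

CONSISTENT, PARTIAL, DISCREPANT = "consistent", "partial", "discrepant"


@dataclass
class RoiMappingRow:
    location: str
    method: str
    level: str                                  # coarse | fine
    regions: list[tuple[str, float]]            # (region, % of in-mask brain voxels)
    profile: str = ""
    status: str = "ok"                          # ok | empty

    def as_dict(self) -> dict[str, float]:
        return dict(self.regions)

    def thresholded(self, threshold_percent: float) -> frozenset[str]:
        """Regions at or above the threshold (boundary-inclusive)."""
        return frozenset(r for r, p in self.regions if p >= threshold_percent)


@dataclass
class ConsistencyReport:
    level: str
    method: str
    threshold_percent: float
    rows: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def classes(self) -> dict[str, str]:
        return {r["location"]: r["class"] for r in self.rows}


@dataclass
class SpecificityRow:
    channel: str
    level: str
    regions: list[tuple[str, float]]            # (region, % of total sensitivity)

    def as_dict(self) -> dict[str, float]:
        return dict(self.regions)


def map_location_to_rois(center: np.ndarray, atlas: AtlasVolume,
                         head: SegmentedHeadVolume,
                         radius_mm: float = DEFAULT_RADIUS_MM,
                         level: str = "coarse", location: str = "",
                         method: str = "", profile: str = "",
                         denominator: str = "brain") -> RoiMappingRow:
    """Tabulate atlas regions inside a sphere as percentages.

    Percentages are of the in-mask *brain* voxel count (the default) or of
    the full in-mask voxel count (``denominator='all'``), and sum to 100
    over the listed regions.
    """
    labels = atlas.labels(level)
    names = atlas.names(level)
    try:
        idx = spherical_mask(center, radius_mm, head, brain_only=True)
    except EmptyMaskError:
        log.warning("empty ROI mapping for %s at %s", location or "location",
                    np.round(np.asarray(center), 1))
        return RoiMappingRow(location, method, level, [], profile, status="empty")
    vals = labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    if denominator == "brain":
        total = len(vals)
    elif denominator == "all":
        total = len(spherical_mask(center, radius_mm, head, brain_only=False))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    regions = []
    for lab in np.unique(vals):
        if lab == 0:
            continue
        cnt = int(np.sum(vals == lab))
        regions.append((names[int(lab)], 100.0 * cnt / total))
    regions.sort(key=lambda t: (-t[1], t[0]))
    return RoiMappingRow(location, method, level, regions, profile)


def build_lookup_table(anchors: dict[str, np.ndarray], atlas: AtlasVolume,
                       head: SegmentedHeadVolume, method: str, profile: str,
                       radius_mm: float = DEFAULT_RADIUS_MM,
                       levels: tuple[str, ...] = ("coarse", "fine"),
                       scalp_centers: dict[str, np.ndarray] | None = None,
                       ) -> dict[str, dict[str, RoiMappingRow]]:
    """One look-up table for one (method, profile) combination.

    ``anchors`` maps each scalp location name to its method-specific
    cortical anchor point (mask centre).  Returns
    ``{level: {location: RoiMappingRow}}``; locations with a missing anchor
    are emitted with an ``empty`` status row.
    """
    out: dict[str, dict[str, RoiMappingRow]] = {lv: {} for lv in levels}
    for loc, anchor in anchors.items():
        for lv in levels:
            if anchor is None:
                out[lv][loc] = RoiMappingRow(loc, method, lv, [], profile,
                                             status="empty")
                continue
            out[lv][loc] = map_location_to_rois(
                anchor, atlas, head, radius_mm, lv,
                location=loc, method=method, profile=profile)
    return out


def consistency_across_profiles(tables: dict[str, dict[str, RoiMappingRow]],
                                threshold_percent: float = 25.0,
                                level: str = "coarse",
                                method: str = "") -> ConsistencyReport:
    """Classify each location's thresholded ROI sets across age profiles.

    ``tables`` maps profile name -> {location: RoiMappingRow}.  Locations
    missing from some profile are classified from the available ones and
    flagged.
    """
    if len(tables) < 2:
        raise ValueError("consistency requires tables for at least 2 profiles")
    if not 0 < threshold_percent <= 100:
        raise ValueError("threshold_percent must lie in (0, 100]")
    report = ConsistencyReport(level, method, threshold_percent)
    locations = sorted({loc for tab in tables.values() for loc in tab})
    for loc in locations:
        sets = {}
        for prof, tab in tables.items():
            if loc in tab:
                sets[prof] = tab[loc].thresholded(threshold_percent)
        flagged = len(sets) < len(tables)
        vals = list(sets.values())
        inter = frozenset.intersection(*vals) if vals else frozenset()
        if vals and all(v == vals[0] for v in vals) and vals[0]:
            clazz = CONSISTENT
        elif inter:
            clazz = PARTIAL
        else:
            clazz = DISCREPANT
        report.rows.append({
            "location": loc, "class": clazz, "incomplete": flagged,
            **{f"rois_{p}": "|".join(sorted(s)) for p, s in sets.items()},
        })
    return report


def channel_specificity(pmdf: PMDFVolume, atlas: AtlasVolume,
                        head: SegmentedHeadVolume, level: str = "coarse",
                        channel: str = "") -> SpecificityRow:
    """Share (%) of total in-brain PMDF sensitivity per atlas region."""
    if pmdf.data.shape != head.labels.shape:
        raise ValueError("PMDF and atlas/head grids are misaligned")
    labels = atlas.labels(level)
    names = atlas.names(level)
    brain = head.brain_mask
    total = float(pmdf.data[brain].sum())
    if total <= 0.0:
        raise ValueError("channel has zero in-brain sensitivity")
    regions = []
    for lab, name in names.items():
        s = float(pmdf.data[(labels == lab) & brain].sum())
        if s > 0.0:
            regions.append((name, 100.0 * s / total))
    regions.sort(key=lambda t: (-t[1], t[0]))
    return SpecificityRow(channel or pmdf.channel, level, regions)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def lookup_table_frame(table: dict[str, dict[str, RoiMappingRow]]) -> pd.DataFrame:
    """Long-format DataFrame of a look-up table (one row per region entry)."""
    recs = []
    for lv, rows in table.items():
        for loc, row in rows.items():
            if not row.regions:
                recs.append({"location": loc, "level": lv, "region": None,
                             "percent": np.nan, "method": row.method,
                             "profile": row.profile, "status": row.status})
            for region, pct in row.regions:
                recs.append({"location": loc, "level": lv, "region": region,
                             "percent": pct, "method": row.method,
                             "profile": row.profile, "status": row.status})
    return pd.DataFrame(recs)


def lookup_table_json(table: dict[str, dict[str, RoiMappingRow]],
                      path: str | Path) -> None:
    payload = {
        lv: {loc: {"method": row.method, "profile": row.profile,
                   "status": row.status,
                   "regions": [{"region": r, "percent": p}
                               for r, p in row.regions]}
             for loc, row in rows.items()}
        for lv, rows in table.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
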