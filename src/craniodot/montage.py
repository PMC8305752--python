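"""Virtual 10-10 / 10-5 optode montages on a voxelized scalp surface.

The 81 10-10 positions are constructed from the cranial fiducials by
tracing plane-surface intersection curves and subdividing them by arc
length, following the standard proportional layout: the midline sagittal
curve Nz-Vz-Iz, the lowest circumference through the preauricular points,
the second circumference through Fpz/T7/Oz/T8, and one traced row curve per
coronal level in between.  The 10-5 superset (358 locations) adds named
scalp midpoints of adjacent 10-10 pairs, and the source-detector channel
sets (251 at each level) pair electrodes that flank a common centre
electrode; both come from the frozen layout tables in :mod:`._layout`.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._layout import CHANNELS_10_10, CHANNELS_10_5, GRID, MIDPOINTS_10_5
from .phantom import AIR, SegmentedHeadVolume

__all__ = [
    "ScalpSurface", "Electrode", "Montage", "Channel",
    "construct_10_10", "construct_10_5", "enumerate_channels",
    "classify_electrode", "electrode_table", "channel_table",
]

log = logging.getLogger("craniodot.montage")

NAMES_10_10 = sorted(GRID)


# ---------------------------------------------------------------------------
# scalp surface
# ---------------------------------------------------------------------------

def _labels_at(head: SegmentedHeadVolume, pts: np.ndarray) -> np.ndarray:
    """Nearest-voxel labels for an (N, 3) array of world points (air outside)."""
    ijk = np.rint(head.world_to_ijk(pts)).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.asarray(head.shape)), axis=-1)
    out = np.full(len(pts), AIR, dtype=np.int16)
    if np.any(ok):
        sel = ijk[ok]
        out[ok] = head.labels[sel[:, 0], sel[:, 1], sel[:, 2]]
    return out


class ScalpSurface:
    """The outer scalp/air boundary of a segmented head volume.

    The surface is star-shaped about the head centroid for the phantoms and
    real heads this package targets, which lets every query be answered by
    radial ray casting with bisection refinement (0.05 mm).
    """

    def __init__(self, head: SegmentedHeadVolume):
        self.head = head
        ijk = np.argwhere(head.labels != AIR)
        if len(ijk) == 0:
            raise ValueError("volume contains no head voxels")
        self.center = head.ijk_to_world(ijk.mean(axis=0))
        self._rmax = float(np.linalg.norm(
            np.asarray(head.shape) * head.voxel_size_mm)) / 2 * 1.8

    # -- ray casting --------------------------------------------------------
    def _boundary(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Distance along each ray to the outer head/air boundary.

        Coarse march at half-voxel steps, then bisection to 0.05 mm.
        Returns NaN where the ray never leaves (or never meets) the head.
        """
        origins = np.atleast_2d(origins).astype(float)
        dirs = np.atleast_2d(dirs).astype(float)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        step = 0.5 * self.head.voxel_size_mm
        ts = np.arange(0.0, self._rmax, step)
        pts = origins[:, None, :] + ts[None, :, None] * dirs[:, None, :]
        lab = _labels_at(self.head, pts.reshape(-1, 3)).reshape(len(origins), len(ts))
        nonair = lab != AIR
        any_head = nonair.any(axis=1)
        # outermost non-air sample index
        last = len(ts) - 1 - np.argmax(nonair[:, ::-1], axis=1)
        lo = ts[last]
        hi = lo + step
        for _ in range(6):
            mid = 0.5 * (lo + hi)
            m_lab = _labels_at(self.head, origins + mid[:, None] * dirs)
            inside = m_lab != AIR
            lo = np.where(inside, mid, lo)
            hi = np.where(inside, hi, mid)
        out = 0.5 * (lo + hi)
        out[~any_head] = np.nan
        return out

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        """Surface distance from the head centre along direction(s)."""
        d = np.atleast_2d(dirs)
        r = self._boundary(np.repeat(self.center[None, :], len(d), axis=0), d)
        return r if np.asarray(dirs).ndim > 1 else float(r[0])

    def snap(self, point: np.ndarray) -> np.ndarray:
        """Nearest surface realization of a point along its centre ray.

        The voxelized boundary is a ~half-voxel sawtooth around the true
        surface, so the radius is averaged over a small angular
        neighbourhood and then clamped back into the boundary voxel of the
        centre ray; the result lies on (within half a voxel of) a scalp
        voxel adjacent to air.
        """
        p = np.asarray(point, dtype=float)
        u = p - self.center
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            raise ValueError("cannot snap the centre point to the surface")
        u = u / nu
        r0 = self.radius(u)
        if not np.isfinite(r0):
            raise ValueError("ray does not intersect the head surface")
        # angular neighbourhood of ~0.7 voxel on the surface
        t1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(u, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(u, t1)
        eps = 0.7 * self.head.voxel_size_mm / r0
        dirs = [u]
        for a, b in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)):
            d = u + eps * (a * t1 + b * t2)
            dirs.append(d / np.linalg.norm(d))
        rr = self.radius(np.asarray(dirs))
        # the voxel-face boundary is an unbiased estimator of the true
        # surface, so the neighbourhood mean tracks it to a fraction of a
        # voxel; clamp only against smoothing pathologies
        r = float(np.nanmean(rr))
        vox = self.head.voxel_size_mm
        r = min(max(r, r0 - 1.5 * vox), r0 + 1.5 * vox) - 0.05
        return self.center + r * u

    def outward_normal(self, point: np.ndarray) -> np.ndarray:
        """Approximate outward normal (radial direction) at a surface point."""
        u = np.asarray(point, dtype=float) - self.center
        return u / np.linalg.norm(u)

    # -- arc tracing --------------------------------------------------------
    def trace_arc(self, p_from: np.ndarray, p_to: np.ndarray,
                  via: np.ndarray | None = None, n_samples: int = 721
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Trace the surface curve cut by the plane through the end points.

        The plane contains ``p_from``, ``p_to`` and, when given, ``via``
        (otherwise the head centre); the arc from ``p_from`` to ``p_to`` is
        taken through the ``via`` side.  Returns (polyline points,
        cumulative arc length).
        """
        p0 = np.asarray(p_from, float)
        p1 = np.asarray(p_to, float)
        aux = np.asarray(via, float) if via is not None else self.center
        nrm = np.cross(p1 - p0, aux - p0)
        if np.linalg.norm(nrm) < 1e-9:
            raise ValueError("degenerate (collinear) points define no plane")
        nrm = nrm / np.linalg.norm(nrm)
        # in-plane origin: projection of the head centre onto the plane
        O = self.center - np.dot(self.center - p0, nrm) * nrm
        e1 = p0 - O
        if np.linalg.norm(e1) < 1e-9:
            raise ValueError("arc start coincides with the in-plane origin")
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)

        def angle(p):
            v = p - O
            return np.arctan2(np.dot(v, e2), np.dot(v, e1))

        a1 = angle(p1) % (2 * np.pi)
        candidates = [a1, a1 - 2 * np.pi]
        if via is not None:
            av = angle(aux)
            # pick the sweep that passes through the via angle
            def contains(sweep, a):
                a = a % (2 * np.pi) if sweep > 0 else -((-a) % (2 * np.pi))
                return 0 <= a <= sweep if sweep > 0 else sweep <= a <= 0
            sweep = next((s for s in candidates if abs(s) > 1e-9 and contains(s, av)),
                         candidates[0])
        else:
            sweep = min(candidates, key=abs)
        phis = np.linspace(0.0, sweep, n_samples)
        dirs = np.cos(phis)[:, None] * e1[None, :] + np.sin(phis)[:, None] * e2[None, :]
        rr = self._boundary(np.repeat(O[None, :], n_samples, axis=0), dirs)
        if np.any(~np.isfinite(rr)):
            raise ValueError("plane-surface intersection left the head (open surface?)")
        # suppress the voxelization sawtooth before measuring arc length
        dphi = abs(sweep) / max(n_samples - 1, 1)
        sigma = self.head.voxel_size_mm / max(float(np.median(rr)) * dphi, 1e-9)
        if sigma > 0.5:
            from scipy.ndimage import gaussian_filter1d
            rr = gaussian_filter1d(rr, sigma, mode="reflect")
        pts = O[None, :] + rr[:, None] * dirs
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return pts, s

    def arc_points(self, p_from, p_to, fractions: Iterable[float],
                   via=None) -> np.ndarray:
        """Surface points at arc-length fractions of the traced curve."""
        pts, s = self.trace_arc(p_from, p_to, via=via)
        total = s[-1]
        out = []
        for f in fractions:
            target = f * total
            i = int(np.searchsorted(s, target, side="right") - 1)
            i = min(max(i, 0), len(s) - 2)
            w = (target - s[i]) / max(s[i + 1] - s[i], 1e-12)
            p = (1 - w) * pts[i] + w * pts[i + 1]
            out.append(self.snap(p))
        return np.asarray(out)


# ---------------------------------------------------------------------------
# electrodes and montages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Electrode:
    name: str
    position: tuple[float, float, float]
    system: str                     # "10-10" or "10-5"
    group: int | None               # 1-4 for 10-10 names, None for 10-5-only
    hemisphere: str                 # left / right / midline
    region_class: str               # frontal / central_posterior

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position)


@dataclass
class Montage:
    """Ordered electrode list with name lookup."""

    electrodes: list[Electrode]
    system: str
    provenance: dict = field(default_factory=dict)
    _by_name: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {e.name: e for e in self.electrodes}
        if len(self._by_name) != len(self.electrodes):
            raise ValueError("duplicate electrode names in montage")

    def __len__(self) -> int:
        return len(self.electrodes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Electrode:
        return self._by_name[name]

    def positions(self) -> np.ndarray:
        return np.asarray([e.position for e in self.electrodes])

    def to_json(self, path) -> None:
        import json
        from pathlib import Path
        payload = {"system": self.system, "provenance": self.provenance,
                   "electrodes": [{"name": e.name,
                                   "position_mm": list(e.position),
                                   "group": e.group,
                                   "hemisphere": e.hemisphere,
                                   "region_class": e.region_class}
                                  for e in self.electrodes]}
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class Channel:
    """A source-detector pair centred on a 10-10 electrode."""

    center_name: str
    source_name: str
    detector_name: str
    midpoint: tuple[float, float, float]   # scalp-snapped S-D midpoint
    separation_mm: float
    level: str                             # "10-10" or "10-5"

    @property
    def scalp_position(self) -> np.ndarray:
        """The channel's scalp location: the centre electrode position is the
        point equidistant from source and detector on this layout."""
        return np.asarray(self.midpoint)


# -- classification ---------------------------------------------------------

_G2 = {"N1", "N2", "I1", "I2"}
_G3 = {"Fp1", "Fp2", "O1", "O2"}


def classify_electrode(name: str) -> tuple[int, str, str]:
    """(group, hemisphere, region_class) for a 10-10 electrode name.

    Group 1: midline (z) curve.  Group 2: lowest circumference curves
    (9/10-index plus N1/N2, I1/I2).  Group 3: second circumference
    (7/8-index plus Fp1/Fp2, O1/O2).  Group 4: the enclosed remainder.
    Hemisphere follows name parity (odd = left, even = right, z = midline);
    the frontal / central-posterior split follows the name prefix.
    """
    if name not in GRID:
        raise KeyError(f"unknown 10-10 electrode label {name!r}")
    if name.endswith("z"):
        group, hemi = 1, "midline"
    else:
        digits = "".join(ch for ch in name if ch.isdigit())
        idx = int(digits)
        hemi = "left" if idx % 2 == 1 else "right"
        if idx in (9, 10) or name in _G2:
            group = 2
        elif idx in (7, 8) or name in _G3:
            group = 3
        else:
            group = 4
    region = "frontal" if name[0] in "NFA" else "central_posterior"
    return group, hemi, region


def _hemisphere_from_grid(pairs) -> str:
    ic = np.mean([(GRID[a][1] + GRID[b][1]) / 2 for a, b in pairs])
    if abs(ic - 10) < 1e-9:
        return "midline"
    return "left" if ic < 10 else "right"


def _region_from_grid(pairs) -> str:
    r = np.mean([(GRID[a][0] + GRID[b][0]) / 2 for a, b in pairs])
    return "frontal" if r < 4.5 else "central_posterior"


# -- construction -----------------------------------------------------------

_ROW_SPECS = [
    # (left anchor, midline anchor, right anchor, left names, right names)
    ("AF7", "AFz", "AF8", ["AF3"], ["AF4"]),
    ("F7", "Fz", "F8", ["F5", "F3", "F1"], ["F6", "F4", "F2"]),
    ("FT7", "FCz", "FT8", ["FC5", "FC3", "FC1"], ["FC6", "FC4", "FC2"]),
    ("T7", "Cz", "T8", ["C5", "C3", "C1"], ["C6", "C4", "C2"]),
    ("TP7", "CPz", "TP8", ["CP5", "CP3", "CP1"], ["CP6", "CP4", "CP2"]),
    ("P7", "Pz", "P8", ["P5", "P3", "P1"], ["P6", "P4", "P2"]),
    ("PO7", "POz", "PO8", ["PO3"], ["PO4"]),
]

_MIDLINE = ["Nz", "Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz", "Iz"]
_LOW_L = ["N1", "AF9", "F9", "FT9", "T9", "TP9", "P9", "PO9", "I1"]
_LOW_R = ["N2", "AF10", "F10", "FT10", "T10", "TP10", "P10", "PO10", "I2"]
_C2_L = ["Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1"]
_C2_R = ["Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2"]


def construct_10_10(surface: ScalpSurface, fiducials) -> Montage:
    """Build the 81-position 10-10 montage from the cranial fiducials."""
    f = {k: surface.snap(fiducials[k]) for k in ("Nz", "Iz", "Vz", "LPA", "RPA")}
    for a, b in (("Nz", "Iz"), ("LPA", "RPA"), ("Nz", "Vz")):
        if np.linalg.norm(f[a] - f[b]) < 4 * surface.head.voxel_size_mm:
            raise ValueError(f"degenerate fiducials: {a} and {b} nearly coincide")

    pos: dict[str, np.ndarray] = {}
    # midline sagittal curve Nz -> Vz -> Iz
    mid_pts = surface.arc_points(f["Nz"], f["Iz"], [k / 10 for k in range(11)],
                                 via=f["Vz"])
    pos.update(zip(_MIDLINE, mid_pts))
    # lowest circumference curves through the preauricular points
    for names, via in ((_LOW_L, f["LPA"]), (_LOW_R, f["RPA"])):
        pts = surface.arc_points(f["Nz"], f["Iz"], [k / 10 for k in range(1, 10)],
                                 via=via)
        pos.update(zip(names, pts))
    # second circumference through Fpz / T7 / Oz / T8: the plane through
    # Fpz and Oz that runs laterally (contains the x direction)
    width = float(np.max(np.abs(surface.head.shape)) * surface.head.voxel_size_mm)
    for names, sgn in ((_C2_L, -1.0), (_C2_R, 1.0)):
        via = 0.5 * (pos["Fpz"] + pos["Oz"]) + np.array([sgn * width, 0.0, 0.0])
        pts = surface.arc_points(pos["Fpz"], pos["Oz"],
                                 [k / 10 for k in range(1, 10)], via=via)
        pos.update(zip(names, pts))
    # interior row curves between homologous lateral and midline points;
    # each half-row lies in the plane through its anchors and the head centre
    for left, mid, right, lnames, rnames in _ROW_SPECS:
        nseg = len(lnames) + 1
        for anchor, names in ((left, lnames), (right, rnames)):
            pts = surface.arc_points(pos[anchor], pos[mid],
                                     [k / nseg for k in range(1, nseg)])
            pos.update(zip(names, pts))

    order = (_MIDLINE + _LOW_L + _LOW_R + _C2_L + _C2_R
             + [n for spec in _ROW_SPECS for n in spec[3] + spec[4]])
    electrodes = []
    for nm in order:
        g, h, rc = classify_electrode(nm)
        electrodes.append(Electrode(nm, tuple(pos[nm]), "10-10", g, h, rc))
    assert len(electrodes) == 81
    return Montage(electrodes, "10-10",
                   provenance={"fiducials": {k: v.tolist() for k, v in f.items()}})


def construct_10_5(montage_10_10: Montage, surface: ScalpSurface) -> Montage:
    """Extend a 10-10 montage to the 358-location 10-5 set.

    Each table entry names a scalp midpoint of one or more adjacent 10-10
    pairs (several defining pairs share one location where layout diagonals
    cross); midpoints are snapped to the scalp and deduplicated by position
    at half a voxel.
    """
    if len(montage_10_10) != 81:
        raise ValueError("construct_10_5 requires the full 81-electrode montage")
    electrodes = [Electrode(e.name, e.position, "10-5", e.group, e.hemisphere,
                            e.region_class) for e in montage_10_10.electrodes]
    taken = montage_10_10.positions()
    tol = 0.5 * surface.head.voxel_size_mm
    new_pos: list[np.ndarray] = []
    for name, pairs in MIDPOINTS_10_5:
        mids = [0.5 * (montage_10_10[a].xyz + montage_10_10[b].xyz) for a, b in pairs]
        p = surface.snap(np.mean(mids, axis=0))
        if new_pos:
            d = np.linalg.norm(np.asarray(new_pos) - p, axis=1)
            if d.min() < tol:
                log.warning("10-5 midpoint %s deduplicated against an existing "
                            "location (%.2f mm apart)", name, d.min())
                continue
        new_pos.append(p)
        electrodes.append(Electrode(name, tuple(p), "10-5", None,
                                    _hemisphere_from_grid(pairs),
                                    _region_from_grid(pairs)))
    m = Montage(electrodes, "10-5", provenance=dict(montage_10_10.provenance))
    if np.min(np.linalg.norm(taken[:, None, :] - np.asarray(new_pos)[None, :, :],
                             axis=2)) < tol:
        raise ValueError("a 10-5 midpoint collides with a 10-10 electrode name")
    return m


def enumerate_channels(montage: Montage, level: str,
                       surface: ScalpSurface | None = None) -> list[Channel]:
    """Source-detector channels centred on 10-10 electrodes.

    ``level='10-10'`` pairs adjacent 10-10 electrodes flanking each centre;
    ``level='10-5'`` uses the half-span 10-5 midpoints of the same layout
    combinations.  Each pair is emitted once.
    """
    table = {"10-10": CHANNELS_10_10, "10-5": CHANNELS_10_5}.get(level)
    if table is None:
        raise ValueError(f"unknown channel level {level!r}")
    if level == "10-5" and montage.system != "10-5":
        raise ValueError("10-5 channels require the 10-5 montage")
    channels = []
    centers_seen: dict[str, int] = {}
    for center, src, det in table:
        if src not in montage or det not in montage:
            continue
        ps, pd = montage[src].xyz, montage[det].xyz
        mid = 0.5 * (ps + pd)
        if surface is not None:
            mid = surface.snap(mid)
        sep = float(np.linalg.norm(ps - pd))
        channels.append(Channel(center, src, det, tuple(mid), sep, level))
        centers_seen[center] = centers_seen.get(center, 0) + 1
    for nm in NAMES_10_10:
        if nm not in centers_seen:
            log.warning("electrode %s centres no %s channel", nm, level)
    return channels


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def electrode_table(montage: Montage) -> pd.DataFrame:
    rows = [{"name": e.name, "x_mm": e.position[0], "y_mm": e.position[1],
             "z_mm": e.position[2], "system": e.system, "group": e.group,
             "hemisphere": e.hemisphere, "region_class": e.region_class}
            for e in montage.electrodes]
    return pd.DataFrame(rows)


def channel_table(channels: list[Channel]) -> pd.DataFrame:
    rows = [{"center": c.center_name, "source": c.source_name,
             "detector": c.detector_name, "separation_mm": c.separation_mm,
             "x_mm": c.midpoint[0], "y_mm": c.midpoint[1], "z_mm": c.midpoint[2],
             "level": c.level}
            for c in channels]
    return pd.DataFrame(rows)
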