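"""End-to-end orchestration across age profiles, summaries and reports.

One pipeline run executes, per age profile: phantom generation, montage and
channel construction, scalp projections, Monte Carlo fluence per required
optode, channel PMDFs, the three distance estimators, ROI look-up tables;
then cross-profile distance summaries, ordering checks and the cross-age
consistency report.  Everything is deterministic under the master seed:
each optode's photon stream is seeded from (master seed, profile, optode
name), so adding optodes never perturbs the results of others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import roi as roi_mod
from .montage import (Channel, Montage, ScalpSurface, channel_table,
                      classify_electrode, construct_10_10, construct_10_5,
                      electrode_table, enumerate_channels)
from .phantom import (AGE_PROFILES, PROFILE_ORDER, AgeProfile, AtlasVolume,
                      FiducialSet, SegmentedHeadVolume,
                      TissueOpticalProperties, default_optical_properties,
                      generate_phantom, write_volume)
from .projection import ProjectionResult, project_to_cortex
from .roi import RoiMappingRow, build_lookup_table, consistency_across_profiles
from .sensitivity import (DEFAULT_RADIUS_MM, DistanceRecord, compute_pmdf,
                          direct_dot_distance, sd_channel_distance)
from .transport import FluenceVolume, SourceSpec, simulate_fluence

__all__ = ["PipelineConfig", "ProfileResult", "PipelineResult",
           "run_pipeline", "run_profile", "analyze_head",
           "summarize_distances",
           "check_orderings", "distance_frame", "child_seed", "topomap_coords"]

log = logging.getLogger("craniodot.pipeline")

ALL_METHODS = ("scalp_projection", "direct_dot", "sd_channel_dot")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis constants and problem sizes for one pipeline run."""

    profiles: tuple[str, ...] = PROFILE_ORDER
    voxel_size_mm: float = 2.0
    photons: int = 10_000
    master_seed: int = 0
    radius_mm: float = DEFAULT_RADIUS_MM
    threshold_percent: float = 25.0
    methods: tuple[str, ...] = ALL_METHODS
    #: centre electrodes whose channels (and optodes) are simulated;
    #: None = all 81
    channel_centers: tuple[str, ...] | None = None
    channel_level: str = "10-10"
    mask_center: str = "projection"
    fresnel: bool = False
    save_volumes: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("at least one profile is required")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not 0 < self.threshold_percent <= 100:
            raise ValueError("threshold_percent must lie in (0, 100]")
        if self.photons < 1:
            raise ValueError("photons must be >= 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def child_seed(master_seed: int, profile: str, optode: str) -> int:
    """Stable per-optode seed derived from (master seed, profile, optode)."""
    h = hashlib.sha256(f"{master_seed}|{profile}|{optode}".encode()).digest()
    return int.from_bytes(h[:8], "little") & 0x7FFFFFFFFFFFFFFF


@dataclass
class ProfileResult:
    profile: str
    head: SegmentedHeadVolume
    fiducials: FiducialSet
    atlas: AtlasVolume
    montage_10_10: Montage
    montage_10_5: Montage
    channels: list[Channel]
    projections: dict[str, ProjectionResult]
    fluences: dict[str, FluenceVolume]
    distances: list[DistanceRecord]
    lookup_tables: dict[str, dict[str, dict[str, RoiMappingRow]]]  # method->level->loc
    anchors: dict[str, dict[str, np.ndarray | None]]               # method->loc


@dataclass
class PipelineResult:
    config: PipelineConfig
    profiles: dict[str, ProfileResult] = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)
    distance_table: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    orderings: dict | None = None
    consistency: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-profile stages
# ---------------------------------------------------------------------------

def _resolve_profile(name: str) -> AgeProfile:
    if name not in AGE_PROFILES:
        raise KeyError(f"unknown packaged profile {name!r}")
    return AGE_PROFILES[name]


def run_profile(config: PipelineConfig, profile: AgeProfile,
                props: TissueOpticalProperties | None = None) -> ProfileResult:
    """Run all per-profile stages for one age profile."""
    head, fid, atlas = generate_phantom(profile, config.voxel_size_mm,
                                        seed=config.master_seed)
    return analyze_head(config, profile.name, head, fid, atlas, props)


def analyze_head(config: PipelineConfig, name: str, head: SegmentedHeadVolume,
                 fid: FiducialSet, atlas: AtlasVolume,
                 props: TissueOpticalProperties | None = None) -> ProfileResult:
    """Per-head stages on a supplied segmented volume (phantom or MRI-derived:
    a NIfTI label volume with a fiducial JSON and an aligned atlas)."""
    props = props or default_optical_properties()
    t0 = time.time()
    surface = ScalpSurface(head)
    m10 = construct_10_10(surface, fid)
    m5 = construct_10_5(m10, surface)
    level_montage = m10 if config.channel_level == "10-10" else m5
    channels = enumerate_channels(level_montage, config.channel_level)
    centers = (set(config.channel_centers) if config.channel_centers is not None
               else {e.name for e in m10.electrodes})
    channels = [c for c in channels if c.center_name in centers]
    log.info("[%s] phantom+montage ready (%.1fs)", name, time.time() - t0)

    # projections for every 10-10 electrode (cheap, also anchors the tables)
    projections = {e.name: project_to_cortex(e.xyz, head, name=e.name)
                   for e in m10.electrodes}

    distances: list[DistanceRecord] = []
    if "scalp_projection" in config.methods:
        for e in m10.electrodes:
            if e.name not in centers:
                continue
            pr = projections[e.name]
            distances.append(DistanceRecord(
                e.name, "scalp_projection", pr.projection_distance_mm,
                tuple(np.rint(head.world_to_ijk(pr.intersection_xyz)).astype(int)),
                name))

    # Monte Carlo fluence for the optodes the requested methods need
    need_mc = {m for m in config.methods if m != "scalp_projection"}
    fluences: dict[str, FluenceVolume] = {}
    if need_mc:
        optodes: dict[str, np.ndarray] = {}
        if "direct_dot" in config.methods:
            for e in m10.electrodes:
                if e.name in centers:
                    optodes[e.name] = e.xyz
        if "sd_channel_dot" in config.methods:
            for c in channels:
                optodes[c.source_name] = level_montage[c.source_name].xyz
                optodes[c.detector_name] = level_montage[c.detector_name].xyz
        t0 = time.time()
        for optode, pos in sorted(optodes.items()):
            d = -surface.outward_normal(pos)
            src = SourceSpec(tuple(pos), tuple(d), config.photons,
                             child_seed(config.master_seed, name, optode))
            fluences[optode] = simulate_fluence(head, props, src,
                                              fresnel=config.fresnel,
                                              label=optode)
        log.info("[%s] %d optode simulations (%.1fs)", name,
                 len(optodes), time.time() - t0)
    else:
        log.info("[%s] Monte Carlo stage skipped (methods=%s)", name,
                 config.methods)

    anchors: dict[str, dict[str, np.ndarray | None]] = {}
    if "scalp_projection" in config.methods:
        anchors["scalp_projection"] = {
            e.name: projections[e.name].intersection_xyz for e in m10.electrodes}

    if "direct_dot" in config.methods:
        dd_anchor: dict[str, np.ndarray | None] = {}
        for e in m10.electrodes:
            if e.name not in centers or e.name not in fluences:
                dd_anchor[e.name] = None
                continue
            rec = direct_dot_distance(e.name, e.xyz, fluences[e.name],
                                      projections[e.name], head,
                                      config.radius_mm, config.mask_center,
                                      name)
            distances.append(rec)
            dd_anchor[e.name] = (head.ijk_to_world(np.asarray(rec.target_ijk))
                                 if rec.target_ijk is not None else None)
        anchors["direct_dot"] = dd_anchor

    if "sd_channel_dot" in config.methods:
        sd_anchor: dict[str, np.ndarray | None] = {e.name: None
                                                   for e in m10.electrodes}
        by_center: dict[str, list[Channel]] = {}
        for c in channels:
            by_center.setdefault(c.center_name, []).append(c)
        for center, chans in sorted(by_center.items()):
            sp = m10[center].xyz
            recs: list[tuple[Channel, DistanceRecord]] = []
            for c in sorted(chans, key=lambda c: (c.separation_mm,
                                                  c.source_name, c.detector_name)):
                pmdf = compute_pmdf(fluences[c.source_name],
                                    fluences[c.detector_name],
                                    channel=f"{c.source_name}-{c.detector_name}")
                recs.append((c, sd_channel_distance(
                    c, pmdf, head, config.radius_mm, scalp_position=sp,
                    projection=projections[center],
                    mask_center=config.mask_center, profile=name)))
            ok = [(c, r) for c, r in recs if r.status == "ok"]
            if not ok:
                distances.append(DistanceRecord(center, "sd_channel_dot",
                                                float("nan"), None,
                                                name, status="no_fluence"))
                continue
            # one row per channel position: mean over its channels, with the
            # shortest-separation channel's peak voxel as the cortical anchor
            mean_d = float(np.mean([r.distance_mm for _, r in ok]))
            anchor_rec = ok[0][1]
            distances.append(DistanceRecord(center, "sd_channel_dot", mean_d,
                                            anchor_rec.target_ijk, name))
            sd_anchor[center] = head.ijk_to_world(np.asarray(anchor_rec.target_ijk))
        anchors["sd_channel_dot"] = sd_anchor

    lookup = {}
    for method, anc in anchors.items():
        lookup[method] = build_lookup_table(anc, atlas, head, method,
                                            name, config.radius_mm)
    return ProfileResult(name, head, fid, atlas, m10, m5, channels,
                         projections, fluences, distances, lookup, anchors)


# ---------------------------------------------------------------------------
# cross-profile assembly
# ---------------------------------------------------------------------------

def distance_frame(results: dict[str, ProfileResult]) -> pd.DataFrame:
    """Long-format distance table with electrode factor columns."""
    recs = []
    for res in results.values():
        for r in res.distances:
            g, h, rc = classify_electrode(r.location)
            recs.append({"profile": r.profile, "location": r.location,
                         "method": r.method, "distance_mm": r.distance_mm,
                         "target_ijk": (None if r.target_ijk is None
                                        else "/".join(map(str, r.target_ijk))),
                         "group": g, "hemisphere": h, "region_class": rc,
                         "status": r.status})
    return pd.DataFrame(recs)


def summarize_distances(table: pd.DataFrame,
                        factors: tuple[str, ...] = ("profile", "method", "group")
                        ) -> pd.DataFrame:
    """Descriptive cell means/SDs/counts of distance by factor combination.

    Cells with a single observation report a null SD; empty cells are
    simply absent (n = 0).  No inferential statistics are computed.
    """
    missing = [f for f in factors if f not in table.columns]
    if missing:
        raise KeyError(f"missing factor columns: {missing}")
    t = table.dropna(subset=["distance_mm"])
    grp = t.groupby(list(factors))["distance_mm"]
    out = grp.agg(mean="mean", sd="std", n="count").reset_index()
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out


def check_orderings(table: pd.DataFrame, voxel_size_mm: float = 2.0) -> dict:
    """Ordering flags with observed margins (report only, never raises).

    Checks the method ordering (S-D channel DOT >= scalp projection >=
    direct DOT - one voxel), the electrode-group ordering (2 > 1 > 3 > 4)
    and the hemispheric difference sign, per profile and pooled.
    """
    t = table.dropna(subset=["distance_mm"])
    out: dict = {"per_profile": {}}

    def method_flags(df) -> dict:
        m = df.groupby("method")["distance_mm"].mean()
        flags = {}
        if {"sd_channel_dot", "scalp_projection"} <= set(m.index):
            flags["sd_ge_projection"] = bool(m["sd_channel_dot"] >= m["scalp_projection"])
            flags["sd_minus_projection_mm"] = float(m["sd_channel_dot"]
                                                    - m["scalp_projection"])
        if {"direct_dot", "scalp_projection"} <= set(m.index):
            flags["projection_ge_direct_minus_voxel"] = bool(
                m["scalp_projection"] >= m["direct_dot"] - voxel_size_mm)
            sub = df[df["method"].isin(["direct_dot", "scalp_projection"])]
            wide = sub.pivot_table(index=["profile", "location"],
                                   columns="method", values="distance_mm")
            if {"direct_dot", "scalp_projection"} <= set(wide.columns):
                flags["direct_projection_abs_diff_mm"] = float(
                    (wide["direct_dot"] - wide["scalp_projection"]).abs().mean())
        return flags

    def group_flags(df) -> dict:
        g = df.groupby("group")["distance_mm"].mean()
        flags = {}
        for a, b in ((2, 1), (1, 3), (3, 4)):
            if a in g.index and b in g.index:
                flags[f"group{a}_gt_group{b}"] = bool(g[a] > g[b])
                flags[f"group{a}_minus_group{b}_mm"] = float(g[a] - g[b])
        return flags

    def hemi_flags(df) -> dict:
        lat = df[df["hemisphere"].isin(["left", "right"])]
        if lat.empty:
            return {}
        m = lat.groupby("hemisphere")["distance_mm"].mean()
        if not {"left", "right"} <= set(m.index):
            return {}
        diff = float(m["left"] - m["right"])
        return {"left_minus_right_mm": diff,
                "asymmetry_sign": int(np.sign(diff)) if abs(diff) > voxel_size_mm / 2
                else 0,
                "no_asymmetry": bool(abs(diff) <= voxel_size_mm / 2)}

    out["pooled"] = {**method_flags(t), **group_flags(t), **hemi_flags(t)}
    for prof, df in t.groupby("profile"):
        out["per_profile"][prof] = {**method_flags(df), **group_flags(df),
                                    **hemi_flags(df)}
    # profile-size monotonicity (in packaged order) per method
    order = [p for p in PROFILE_ORDER if p in set(t["profile"])]
    mono = {}
    for method, df in t.groupby("method"):
        means = df.groupby("profile")["distance_mm"].mean()
        seq = [float(means[p]) for p in order if p in means.index]
        mono[method] = {"profiles": order, "means_mm": seq,
                        "monotone_nondecreasing": bool(
                            all(b >= a for a, b in zip(seq, seq[1:])))}
    out["profile_monotonicity"] = mono
    return out


def topomap_coords(montage: Montage) -> pd.DataFrame:
    """2D azimuthal-equidistant layout coordinates for plotting exports."""
    apex = max(montage.electrodes, key=lambda e: e.position[2]).xyz
    center = np.mean(montage.positions(), axis=0)
    rows = []
    for e in montage.electrodes:
        v = e.xyz - center
        v = v / np.linalg.norm(v)
        up = apex - center
        up = up / np.linalg.norm(up)
        costh = np.clip(v @ up, -1, 1)
        theta = np.arccos(costh)
        az = np.arctan2(v[0], v[1])
        rows.append({"name": e.name, "u": theta * np.sin(az),
                     "v": theta * np.cos(az)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 profiles: dict[str, AgeProfile] | None = None,
                 props: TissueOpticalProperties | None = None) -> PipelineResult:
    """Run the full analysis; failed profiles are recorded, not fatal."""
    result = PipelineResult(config)
    catalogue = profiles or AGE_PROFILES
    for name in config.profiles:
        try:
            prof = catalogue[name] if name in catalogue else _resolve_profile(name)
            result.profiles[name] = run_profile(config, prof, props)
        except Exception as exc:  # noqa: BLE001 - stage isolation by contract
            log.error("[%s] profile failed: %s", name, exc)
            result.failures.append({"profile": name, "error": str(exc),
                                    "type": type(exc).__name__})
    if result.profiles:
        result.distance_table = distance_frame(result.profiles)
        if len(result.distance_table):
            result.summary = summarize_distances(result.distance_table)
            result.orderings = check_orderings(result.distance_table,
                                               config.voxel_size_mm)
        if len(result.profiles) >= 2:
            for method in config.methods:
                for level in ("coarse", "fine"):
                    tabs = {p: r.lookup_tables[method][level]
                            for p, r in result.profiles.items()
                            if method in r.lookup_tables}
                    if len(tabs) >= 2:
                        rep = consistency_across_profiles(
                            tabs, config.threshold_percent, level, method)
                        result.consistency[f"{method}_{level}"] = rep.frame()
    if config.output_dir:
        _write_artifacts(result, Path(config.output_dir))
    return result


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(result.config)
    (out / "manifest.json").write_text(json.dumps(
        {"config": cfg, "profiles_done": sorted(result.profiles),
         "failures": result.failures}, indent=1, default=str))
    if result.distance_table is not None:
        result.distance_table.to_csv(out / "distances.csv", index=False)
    if result.summary is not None:
        result.summary.to_csv(out / "summary.csv", index=False)
    if result.orderings is not None:
        (out / "orderings.json").write_text(json.dumps(result.orderings, indent=1))
    for key, frame in result.consistency.items():
        frame.to_csv(out / f"consistency_{key}.csv", index=False)
    for pname, res in result.profiles.items():
        electrode_table(res.montage_10_5).to_csv(
            out / f"electrodes_{pname}.csv", index=False)
        channel_table(res.channels).to_csv(out / f"channels_{pname}.csv",
                                           index=False)
        topomap_coords(res.montage_10_10).to_csv(
            out / f"topomap_{pname}.csv", index=False)
        for method, table in res.lookup_tables.items():
            roi_mod.lookup_table_frame(table).to_csv(
                out / f"lookup_{method}_{pname}.csv", index=False)
            roi_mod.lookup_table_json(table,
                                      out / f"lookup_{method}_{pname}.json")
        if result.config.save_volumes:
            write_volume(out / f"head_{pname}.nii.gz", res.head.labels,
                         res.head.voxel_size_mm, res.head.origin_mm)
            for oname, flu in res.fluences.items():
                write_volume(out / f"fluence_{pname}_{oname}.nii.gz",
                             flu.data.astype(np.float32),
                             flu.voxel_size_mm, flu.origin_mm)
                (out / f"fluence_{pname}_{oname}.json").write_text(json.dumps(
                    {"seed": flu.source.seed, "photons": flu.source.n_photons,
                     "position": list(flu.source.position),
                     "direction": list(flu.source.direction)}))
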