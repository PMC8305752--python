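"""Scalp-location-to-ROI mapping, consistency classes and specificity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from craniodot.phantom import (AGE_PROFILES, SegmentedHeadVolume,
                               generate_phantom)
from craniodot.roi import (CONSISTENT, DISCREPANT, PARTIAL, RoiMappingRow,
                           channel_specificity,
                           consistency_across_profiles, map_location_to_rois)
from craniodot.sensitivity import PMDFVolume


@pytest.fixture(scope="module")
def head_atlas():
    head, _, atlas = generate_phantom(AGE_PROFILES["12mo"], 2.0, 0)
    return head, atlas


def test_mask_inside_one_fine_region_is_100pct(head_atlas):
    head, atlas = head_atlas
    # centre of mass of one fine region, small radius
    fid = max(atlas.fine_names, key=lambda f: (atlas.fine_labels == f).sum())
    ijk = np.argwhere(atlas.fine_labels == fid)
    center = head.ijk_to_world(ijk.mean(axis=0))
    row = map_location_to_rois(center, atlas, head, radius_mm=4.0, level="fine")
    assert row.regions and row.regions[0][0] == atlas.fine_names[fid]
    assert row.regions[0][1] == pytest.approx(100.0)


def test_percentages_match_exhaustive_scan(head_atlas):
    """The mapping equals a brute-force per-voxel accumulation."""
    head, atlas = head_atlas
    center = head.brain_centroid() + np.array([12.0, 18.0, 9.0])
    for level in ("coarse", "fine"):
        row = map_location_to_rois(center, atlas, head, 15.0, level)
        X, Y, Z = head.voxel_centers_world()
        d2 = (X - center[0])**2 + (Y - center[1])**2 + (Z - center[2])**2
        inside = (d2 <= 15.0**2) & head.brain_mask
        labs = atlas.labels(level)[inside]
        total = labs.size
        expect = {atlas.names(level)[int(l)]: 100.0 * np.sum(labs == l) / total
                  for l in np.unique(labs) if l != 0}
        assert dict(row.regions) == pytest.approx(expect)
        assert sum(p for _, p in row.regions) == pytest.approx(100.0, abs=0.01)


def test_mapping_percentages_sum_to_100(age_run):
    for res in age_run.profiles.values():
        for table in res.lookup_tables.values():
            for rows in table.values():
                for row in rows.values():
                    if row.status == "ok" and row.regions:
                        assert sum(p for _, p in row.regions) == \
                            pytest.approx(100.0, abs=0.01)


def test_empty_mask_yields_flagged_row(head_atlas):
    head, atlas = head_atlas
    far = head.origin_mm  # grid corner, far from the brain
    row = map_location_to_rois(far, atlas, head, 5.0, "coarse")
    assert row.status == "empty" and row.regions == []


def test_threshold_is_boundary_inclusive():
    row = RoiMappingRow("Cz", "sd_channel_dot", "coarse",
                        [("frontal", 75.1), ("parietal_central", 25.0),
                         ("occipital", 24.9)])
    kept = row.thresholded(25.0)
    assert "parietal_central" in kept
    assert "occipital" not in kept


def _tables(per_profile_sets):
    out = {}
    for prof, locsets in per_profile_sets.items():
        out[prof] = {loc: RoiMappingRow(loc, "m", "coarse",
                                        [(r, p) for r, p in regions])
                     for loc, regions in locsets.items()}
    return out


def test_consistency_classes_on_constructed_cases():
    tables = _tables({
        "young": {"A": [("r1", 60.0), ("r2", 40.0)],
                  "B": [("r1", 60.0), ("r2", 40.0)],
                  "C": [("r1", 100.0)]},
        "old":   {"A": [("r1", 60.0), ("r2", 40.0)],
                  "B": [("r1", 90.0), ("r3", 10.0)],
                  "C": [("r9", 100.0)]},
    })
    rep = consistency_across_profiles(tables, 25.0, "coarse")
    classes = rep.classes()
    assert classes["A"] == CONSISTENT
    assert classes["B"] == PARTIAL
    assert classes["C"] == DISCREPANT


def test_identical_profiles_all_consistent(age_run):
    res = next(iter(age_run.profiles.values()))
    tab = res.lookup_tables["scalp_projection"]["coarse"]
    rep = consistency_across_profiles({"a": tab, "b": tab}, 25.0, "coarse")
    assert all(r["class"] == CONSISTENT for r in rep.rows
               if tab[r["location"]].thresholded(25.0))


def test_shifting_sector_boundary_degrades_border_locations():
    """Rotating the atlas sector boundaries with 'age' turns
    boundary-adjacent locations partial/discrepant while interior locations
    stay consistent."""
    from craniodot.montage import ScalpSurface, construct_10_10
    from craniodot.roi import build_lookup_table
    from craniodot.projection import project_to_cortex
    tabs = {}
    for label, rot in (("young", 0.0), ("old", 25.0)):
        prof = dataclasses.replace(AGE_PROFILES["2yr"], name=label,
                                   atlas_rotation_deg=rot)
        head, fid, atlas = generate_phantom(prof, 2.0, 0)
        surface = ScalpSurface(head)
        m10 = construct_10_10(surface, fid)
        anchors = {e.name: project_to_cortex(e.xyz, head).intersection_xyz
                   for e in m10.electrodes}
        tabs[label] = build_lookup_table(anchors, atlas, head, "scalp_projection",
                                         label, levels=("coarse",))["coarse"]
    rep = consistency_across_profiles(tabs, 25.0, "coarse")
    classes = rep.classes()
    assert sum(c != CONSISTENT for c in classes.values()) >= 5
    assert sum(c == CONSISTENT for c in classes.values()) >= 30


@given(st.lists(
    st.tuples(st.sampled_from(["r1", "r2", "r3", "r4"]),
              st.floats(1.0, 100.0)),
    min_size=1, max_size=4, unique_by=lambda t: t[0]),
    st.lists(st.tuples(st.sampled_from(["r1", "r2", "r3", "r4"]),
                       st.floats(1.0, 100.0)),
             min_size=1, max_size=4, unique_by=lambda t: t[0]),
    st.floats(5.0, 50.0), st.floats(1.0, 49.0))
def test_raising_threshold_never_improves_class(regions_a, regions_b, t_low,
                                                dt):
    """Classification order consistent > partial > discrepant is monotone
    non-improving in the threshold."""
    rank = {CONSISTENT: 2, PARTIAL: 1, DISCREPANT: 0}
    tables = _tables({"p1": {"L": regions_a}, "p2": {"L": regions_b}})
    lo = consistency_across_profiles(tables, t_low, "coarse").classes()["L"]
    hi = consistency_across_profiles(tables, min(t_low + dt, 100.0),
                                     "coarse").classes()["L"]
    assert rank[hi] <= rank[lo]


def test_mapping_stable_under_translation(head_atlas):
    head, atlas = head_atlas
    shift = np.array([6.2, -3.4, 9.8])
    moved_head = SegmentedHeadVolume(head.labels, head.voxel_size_mm,
                                     head.origin_mm + shift, head.label_names)
    moved_atlas = dataclasses.replace(atlas)
    center = head.brain_centroid() + np.array([10.0, 5.0, 12.0])
    r0 = map_location_to_rois(center, atlas, head, 15.0, "coarse")
    r1 = map_location_to_rois(center + shift, moved_atlas, moved_head, 15.0,
                              "coarse")
    assert dict(r0.regions) == pytest.approx(dict(r1.regions))


# -- specificity ------------------------------------------------------------

def test_specificity_single_region_is_100(head_atlas):
    head, atlas = head_atlas
    data = np.zeros(head.shape)
    target = 1
    m = (atlas.coarse_labels == target) & head.brain_mask
    data[m] = 0.5
    pmdf = PMDFVolume(data, head.voxel_size_mm, head.origin_mm, "t")
    row = channel_specificity(pmdf, atlas, head, "coarse")
    assert row.regions == [(atlas.coarse_names[target], pytest.approx(100.0))]


def test_specificity_matches_bruteforce(head_atlas):
    head, atlas = head_atlas
    rng = np.random.default_rng(3)
    data = rng.random(head.shape)
    pmdf = PMDFVolume(data, head.voxel_size_mm, head.origin_mm, "t")
    row = channel_specificity(pmdf, atlas, head, "coarse")
    brain = head.brain_mask
    total = data[brain].sum()
    expect = {}
    for lab, name in atlas.coarse_names.items():
        s = data[(atlas.coarse_labels == lab) & brain].sum()
        if s > 0:
            expect[name] = 100.0 * s / total
    assert dict(row.regions) == pytest.approx(expect)
    assert sum(p for _, p in row.regions) == pytest.approx(100.0, abs=0.01)


def test_specificity_threshold_filter_semantics(head_atlas):
    head, atlas = head_atlas
    rng = np.random.default_rng(4)
    data = rng.random(head.shape) ** 8        # sparse-ish sensitivity
    pmdf = PMDFVolume(data, head.voxel_size_mm, head.origin_mm, "t")
    row = channel_specificity(pmdf, atlas, head, "fine")
    above = {r for r, p in row.regions if p > 1.0}
    nonzero = {r for r, p in row.regions if p > 0.0}
    assert above <= nonzero


def test_specificity_zero_sensitivity_errors(head_atlas):
    head, atlas = head_atlas
    pmdf = PMDFVolume(np.zeros(head.shape), head.voxel_size_mm,
                      head.origin_mm, "t")
    with pytest.raises(ValueError, match="zero"):
        channel_specificity(pmdf, atlas, head, "coarse")
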