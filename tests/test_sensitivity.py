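"""PMDF computation and the DOT distance estimators."""

import numpy as np
import pytest

from craniodot.sensitivity import (compute_pmdf,
                                   direct_dot_distance, sd_channel_distance)
from craniodot.transport import FluenceVolume, SourceSpec


def _flu(data, vox=2.0, origin=None):
    origin = origin if origin is not None else -np.ones(3) * (data.shape[0] - 1)
    src = SourceSpec((0, 0, 0), (0, 0, 1), 1, 0)
    return FluenceVolume(np.asarray(data, float), vox, origin, src, 0, 1, 0)


def test_pmdf_is_elementwise_product():
    a = _flu(np.full((5, 5, 5), 0.5))
    b = _flu(np.full((5, 5, 5), 0.2))
    p = compute_pmdf(a, b)
    assert np.allclose(p.data, 0.1)
    q = compute_pmdf(b, a)
    assert np.array_equal(p.data, q.data)      # commutative
    z = compute_pmdf(a, _flu(np.zeros((5, 5, 5))))
    assert not z.data.any()                    # zero detector -> zero PMDF


def test_pmdf_grid_mismatch_errors():
    a = _flu(np.ones((5, 5, 5)))
    with pytest.raises(ValueError):
        compute_pmdf(a, _flu(np.ones((6, 6, 6))))
    with pytest.raises(ValueError):
        compute_pmdf(a, _flu(np.ones((5, 5, 5)), vox=1.0))


def test_direct_dot_tie_breaks_toward_scalp(sphere):
    """Equal-maximum voxels resolve to the scalp-nearest one, then to the
    lowest linear index."""
    head = sphere.head
    e = sphere.m10["Cz"]
    from craniodot.projection import project_to_cortex
    pr = project_to_cortex(e.xyz, head, "Cz")
    data = np.zeros(head.shape)
    flu = FluenceVolume(data, head.voxel_size_mm, head.origin_mm,
                        SourceSpec(tuple(e.xyz), (0, 0, -1), 1, 0), 0, 1, 0)
    near = np.rint(head.world_to_ijk(pr.intersection_xyz
                                     + 2.0 * np.asarray(pr.direction))).astype(int)
    far = np.rint(head.world_to_ijk(pr.intersection_xyz
                                    + 8.0 * np.asarray(pr.direction))).astype(int)
    data[tuple(near)] = 1.0
    data[tuple(far)] = 1.0
    rec = direct_dot_distance("Cz", e.xyz, flu, pr, head)
    assert rec.target_ijk == tuple(int(v) for v in near)

    # exact distance tie: two voxels mirrored about the scalp ray
    data[...] = 0.0
    i, j, k = near
    data[i - 1, j, k] = 1.0
    data[i + 1, j, k] = 1.0
    rec2 = direct_dot_distance("Cz", e.xyz, flu, pr, head)
    lin1 = np.ravel_multi_index((i - 1, j, k), head.shape)
    lin2 = np.ravel_multi_index((i + 1, j, k), head.shape)
    assert np.ravel_multi_index(rec2.target_ijk, head.shape) == min(lin1, lin2)


def test_all_zero_fluence_flagged(sphere):
    from craniodot.projection import project_to_cortex
    e = sphere.m10["Pz"]
    pr = project_to_cortex(e.xyz, sphere.head, "Pz")
    flu = FluenceVolume(np.zeros(sphere.head.shape), sphere.head.voxel_size_mm,
                        sphere.head.origin_mm,
                        SourceSpec(tuple(e.xyz), (0, 0, -1), 1, 0), 0, 1, 0)
    rec = direct_dot_distance("Pz", e.xyz, flu, pr, sphere.head)
    assert rec.status == "no_fluence"
    assert np.isnan(rec.distance_mm)


def test_direct_dot_close_to_projection_on_sphere(sphere_mc, sphere):
    """The fluence peak sits just inside the cortical surface, so the
    direct-DOT distance tracks the 10 mm projection distance within 4 mm."""
    recs = {r.location: r for r in sphere_mc.distances
            if r.method == "direct_dot"}
    assert recs
    for name, rec in recs.items():
        assert rec.status == "ok"
        assert abs(rec.distance_mm - 10.0) <= 4.0, name


def test_target_inside_search_sphere(sphere_mc, sphere):
    for rec in sphere_mc.distances:
        if rec.method != "direct_dot" or rec.target_ijk is None:
            continue
        pr = sphere_mc.projections[rec.location]
        target = sphere.head.ijk_to_world(np.asarray(rec.target_ijk))
        assert np.linalg.norm(target - pr.intersection_xyz) <= 15.0 + 1e-9


def test_sd_record_invariant_under_source_detector_swap(sphere_mc, sphere):
    ch = next(c for c in sphere_mc.channels if c.center_name == "Cz")
    fs = sphere_mc.fluences[ch.source_name]
    fd = sphere_mc.fluences[ch.detector_name]
    sp = sphere.m10["Cz"].xyz
    pr = sphere_mc.projections["Cz"]
    r1 = sd_channel_distance(ch, compute_pmdf(fs, fd), sphere.head,
                             scalp_position=sp, projection=pr)
    r2 = sd_channel_distance(ch, compute_pmdf(fd, fs), sphere.head,
                             scalp_position=sp, projection=pr)
    assert r1.distance_mm == r2.distance_mm
    assert r1.target_ijk == r2.target_ijk


def test_sd_deeper_than_projection_on_sphere(sphere_mc):
    by_m = {}
    for r in sphere_mc.distances:
        by_m.setdefault(r.method, []).append(r.distance_mm)
    assert np.mean(by_m["sd_channel_dot"]) > np.mean(by_m["scalp_projection"])


def test_wider_separation_does_not_get_shallower(sphere_mc, sphere):
    """10-10-level pairs (double the 10-5 span) peak at least as deep below
    the cortex as the half-span pairs at the same centre."""
    from craniodot.montage import enumerate_channels
    ch10 = [c for c in sphere_mc.channels if c.center_name == "Cz"]
    ch5_all = enumerate_channels(sphere.m5, "10-5")
    pr = sphere_mc.projections["Cz"]
    sp = sphere.m10["Cz"].xyz

    def depth(ch, fl_s, fl_d):
        rec = sd_channel_distance(ch, compute_pmdf(fl_s, fl_d), sphere.head,
                                  scalp_position=sp, projection=pr)
        return rec.distance_mm - pr.projection_distance_mm

    from craniodot.transport import simulate_fluence, SourceSpec
    from craniodot.phantom import default_optical_properties
    props = default_optical_properties()

    c10 = min(ch10, key=lambda c: c.separation_mm)
    # simulate the 10-5 optodes of the matching table row
    full10 = enumerate_channels(sphere.m10, "10-10")
    row = [i for i, c in enumerate(full10)
           if (c.center_name, c.source_name, c.detector_name)
           == (c10.center_name, c10.source_name, c10.detector_name)][0]
    c5 = ch5_all[row]
    flus = {}
    for nm, montage in ((c5.source_name, sphere.m5), (c5.detector_name, sphere.m5)):
        pos = montage[nm].xyz
        flus[nm] = simulate_fluence(
            sphere.head, props,
            SourceSpec(tuple(pos), tuple(-pos / np.linalg.norm(pos)), 20000, 21))
    d10 = depth(c10, sphere_mc.fluences[c10.source_name],
                sphere_mc.fluences[c10.detector_name])
    d5 = depth(c5, flus[c5.source_name], flus[c5.detector_name])
    assert d10 >= d5 - 2.0
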