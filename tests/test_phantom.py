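"""Head-phantom generator: shell geometry, atlas structure, I/O."""

import dataclasses

import numpy as np
import pytest

from craniodot.phantom import (AGE_PROFILES, AIR, CSF, GM, PROFILE_ORDER,
                               SCALP, SKULL, WM, AgeProfile,
                               check_shell_order,
                               generate_phantom, read_volume,
                               shell_sequence_along_ray, write_volume)


@pytest.mark.parametrize("name", PROFILE_ORDER)
def test_shell_order_holds_on_packaged_profiles(profile_phantoms, name):
    """Centroid rays encounter GM, CSF, skull, scalp, air with no shell
    skipped on at least 99% of directions."""
    head, _, _ = profile_phantoms[name]
    assert check_shell_order(head, n_rays=300, seed=7) >= 0.99


def test_tissue_volumes_grow_with_age(profile_phantoms):
    """Brain, skull and scalp volumes are monotone nondecreasing over the
    packaged infant-to-adult sequence."""
    prev = None
    for name in PROFILE_ORDER:
        head, _, _ = profile_phantoms[name]
        counts = {
            "brain": int(head.brain_mask.sum()),
            "skull": int((head.labels == SKULL).sum()),
            "scalp": int((head.labels == SCALP).sum()),
        }
        if prev is not None:
            for k in counts:
                assert counts[k] >= prev[k], (name, k)
        prev = counts


def test_atlas_two_level_nesting(profile_phantoms):
    """Every brain voxel carries one coarse and one fine label, and each
    fine region maps into exactly one coarse region (checked exhaustively)."""
    head, _, atlas = profile_phantoms["3mo"]
    brain = head.brain_mask
    assert np.all(atlas.coarse_labels[brain] > 0)
    assert np.all(atlas.fine_labels[brain] > 0)
    assert np.all(atlas.coarse_labels[~brain] == 0)
    fine = atlas.fine_labels[brain]
    coarse = atlas.coarse_labels[brain]
    for fid in np.unique(fine):
        owners = np.unique(coarse[fine == fid])
        assert len(owners) == 1
        assert atlas.fine_to_coarse[int(fid)] == int(owners[0])
    assert "cerebellum" in atlas.coarse_names.values()
    assert 5 <= len(atlas.coarse_names) <= 8
    assert 20 <= len(atlas.fine_names) <= 60


def test_sphere_boundary_radii(sphere):
    """On the R=80 sphere the air boundary sits at 80 +- 1 mm and the outer
    GM surface at 70 +- 1 mm along random centroid rays."""
    rng = np.random.default_rng(5)
    dirs = rng.normal(size=(40, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    head = sphere.head
    for u in dirs:
        rr = np.arange(40.0, 100.0, 0.25)
        labs = np.array([head.label_at(r * u) for r in rr])
        r_air = rr[np.argmax(labs == AIR)]
        gm_like = np.isin(labs, (GM, WM))
        r_gm = rr[len(labs) - 1 - np.argmax(gm_like[::-1])]
        assert abs(r_air - 80.0) <= 1.5
        assert abs(r_gm - 70.0) <= 1.5


def test_generation_is_deterministic():
    prof = AGE_PROFILES["3mo"]
    h1, f1, a1 = generate_phantom(prof, 2.0, seed=4)
    h2, f2, a2 = generate_phantom(prof, 2.0, seed=4)
    assert np.array_equal(h1.labels, h2.labels)
    assert np.array_equal(a1.fine_labels, a2.fine_labels)
    for k in f1.points:
        assert np.array_equal(f1[k], f2[k])


def test_anterior_csf_gradient_widens_front_gap():
    """With a 4 mm anterior gap gradient the scalp-to-GM gap at the nasion
    pole exceeds the inion-pole gap by the gradient (voxel-quantized)."""
    base = AGE_PROFILES["12mo"]
    prof = dataclasses.replace(base, name="grad", ap_gap_gradient_mm=4.0)
    head, _, _ = generate_phantom(prof, 2.0, 0)

    def gap(direction):
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        rr = np.arange(20.0, 90.0, 0.1)
        labs = np.array([head.label_at(r * u) for r in rr])
        gm_like = np.isin(labs, (GM, WM))
        r_gm = rr[len(labs) - 1 - np.argmax(gm_like[::-1])]
        r_air = rr[np.argmax(labs == AIR)]
        return r_air - r_gm

    # average a few near-axis rays to suppress face quantization
    offs = [(0, 0), (0.06, 0), (-0.06, 0), (0, 0.06), (0, -0.06)]
    front = np.mean([gap((dx, 1.0, dz)) for dx, dz in offs])
    back = np.mean([gap((dx, -1.0, dz)) for dx, dz in offs])
    assert abs((front - back) - 4.0) <= 2.0


def test_fiducials_lie_on_scalp_boundary(sphere):
    for name in ("Nz", "Iz", "Vz", "LPA", "RPA", "M1", "M2"):
        p = sphere.fiducials[name]
        u = p / np.linalg.norm(p)
        inner = sphere.head.label_at(p - 1.9 * u)
        outer = sphere.head.label_at(p + 2.1 * u)
        assert inner == SCALP
        assert outer == AIR


def test_hemispheric_asymmetry_offsets_one_side():
    prof = dataclasses.replace(AGE_PROFILES["2yr"], name="asym",
                               hemispheric_asymmetry_mm=4.0)
    head, _, _ = generate_phantom(prof, 2.0, 0)
    brain = head.brain_mask
    idx = np.argwhere(brain)
    pts = head.ijk_to_world(idx)
    left_max = np.abs(pts[pts[:, 0] < 0, 0]).max()
    right_max = np.abs(pts[pts[:, 0] > 0, 0]).max()
    assert right_max - left_max >= 2.0  # left GM pulled deeper


def test_volume_io_roundtrip(tmp_path, sphere):
    path = tmp_path / "head.nii.gz"
    write_volume(path, sphere.head.labels, sphere.head.voxel_size_mm,
                 sphere.head.origin_mm)
    back = read_volume(path, kind="labels")
    assert np.array_equal(back.labels, sphere.head.labels)
    assert back.voxel_size_mm == sphere.head.voxel_size_mm
    assert np.allclose(back.origin_mm, sphere.head.origin_mm)

    rng = np.random.default_rng(0)
    field = rng.random((9, 9, 9)).astype(np.float32)
    fp = tmp_path / "field.nii.gz"
    write_volume(fp, field, 2.0, np.zeros(3))
    data, vox, origin = read_volume(fp, kind="field")
    assert np.unravel_index(np.argmax(data), data.shape) == \
        np.unravel_index(np.argmax(field), field.shape)
    assert np.array_equal(data, field)


def test_volume_io_rejects_unknown_labels(tmp_path):
    bad = np.full((4, 4, 4), 9, dtype=np.int16)
    path = tmp_path / "bad.nii.gz"
    write_volume(path, bad, 2.0, np.zeros(3))
    with pytest.raises(ValueError, match="9"):
        read_volume(path, kind="labels")


@pytest.mark.parametrize("kwargs", [
    {"scalp_mm": -1.0}, {"csf_mm": 0.0},
    {"semi_axes_mm": (8.0, 8.0, 8.0)},      # thinner than the shell stack
])
def test_profile_validation_errors(kwargs):
    base = dict(name="bad", semi_axes_mm=(60.0, 70.0, 55.0),
                scalp_mm=3.0, skull_mm=3.0, csf_mm=3.0)
    base.update(kwargs)
    with pytest.raises(ValueError):
        AgeProfile(**base)


def test_shell_sequence_starts_interior_ends_air(sphere):
    seq = shell_sequence_along_ray(sphere.head, (0.3, 0.5, 0.8))
    assert seq[0] in (WM, GM)
    assert seq[-1] == AIR
    assert seq.index(GM) < seq.index(CSF) < seq.index(SKULL)
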