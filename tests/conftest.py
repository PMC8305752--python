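"""Shared fixtures: phantoms, montages and the cross-profile pipeline run.

Expensive artifacts (the concentric-sphere benchmark head, the packaged
profile montages, and the all-electrode Monte Carlo pipeline run) are built
once per session and shared across test modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

from craniodot import (PipelineConfig, run_pipeline)
from craniodot.montage import (Montage, ScalpSurface, construct_10_10,
                               construct_10_5, enumerate_channels)
from craniodot.phantom import (AGE_PROFILES, AtlasVolume, FiducialSet,
                               SegmentedHeadVolume, concentric_spheres_profile,
                               generate_phantom)

settings.register_profile("suite", derandomize=True, max_examples=40,
                          deadline=None)
settings.load_profile("suite")

SPHERE_R = 80.0
SPHERE_SHELLS = (4.0, 4.0, 2.0)   # scalp, skull, CSF mm


@dataclass
class SphereBench:
    head: SegmentedHeadVolume
    fiducials: FiducialSet
    atlas: AtlasVolume
    surface: ScalpSurface
    m10: Montage
    m5: Montage
    ch10: list
    ch5: list
    profile: object


@pytest.fixture(scope="session")
def sphere() -> SphereBench:
    """Concentric-sphere benchmark: R=80 mm scalp, 4/4/2 mm shells, 2 mm voxels."""
    prof = concentric_spheres_profile(SPHERE_R, *SPHERE_SHELLS)
    head, fid, atlas = generate_phantom(prof, 2.0, seed=0)
    surface = ScalpSurface(head)
    m10 = construct_10_10(surface, fid)
    m5 = construct_10_5(m10, surface)
    return SphereBench(head, fid, atlas, surface, m10, m5,
                       enumerate_channels(m10, "10-10"),
                       enumerate_channels(m5, "10-5"), prof)


@pytest.fixture(scope="session")
def profile_phantoms() -> dict:
    """Segmented heads for every packaged age profile (2 mm voxels)."""
    out = {}
    for name, prof in AGE_PROFILES.items():
        out[name] = generate_phantom(prof, 2.0, seed=0)
    return out


@pytest.fixture(scope="session")
def profile_montages(profile_phantoms) -> dict:
    """(m10, m5, ch10, ch5) per packaged profile."""
    out = {}
    for name, (head, fid, _) in profile_phantoms.items():
        surface = ScalpSurface(head)
        m10 = construct_10_10(surface, fid)
        m5 = construct_10_5(m10, surface)
        out[name] = (m10, m5, enumerate_channels(m10, "10-10"),
                     enumerate_channels(m5, "10-5"))
    return out


@pytest.fixture(scope="session")
def age_run():
    """Full pipeline over all packaged profiles, all 81 electrodes.

    8000 photons per optode: head-phantom walks terminate quickly, so this
    covers every electrode of every profile in about a minute while keeping
    Monte Carlo noise on profile means well below the profile spacing.
    """
    cfg = PipelineConfig(profiles=tuple(AGE_PROFILES), photons=8000,
                         master_seed=1)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def sphere_mc(sphere):
    """Pipeline stages on the sphere benchmark for a subset of centres."""
    from craniodot.pipeline import run_profile
    cfg = PipelineConfig(profiles=("sphere",), photons=20_000, master_seed=3,
                         channel_centers=("Cz", "Pz", "C3"))
    return run_profile(cfg, sphere.profile)
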