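"""Synthetic segmented head phantoms with age-like geometric structure.

The phantom is a nested-ellipsoid head model: white matter inside grey
matter, wrapped by CSF, skull and scalp shells, surrounded by air.  Shell
thicknesses, overall size, an anterior-posterior CSF-gap gradient, a signed
hemispheric offset of the grey-matter surface and an optional low-order
surface perturbation (a gyrification stand-in) are all controlled by an
:class:`AgeProfile`.  The packaged profile sequence emulates head growth
from two weeks of age to adulthood; the numbers are plausible-scale
configuration defaults, not anatomical measurements.

Every phantom comes with cranial fiducials placed at the analytic extreme
points of the scalp surface, and a two-level (coarse "lobar" / fine
"sublobar") sector atlas defined on the brain mask.

Coordinate conventions: world coordinates are millimetres, axis-aligned and
right-handed, with the head centred at the origin; voxel indices are
0-based; the left preauricular point lies on the -x side, the nasion on the
+y side and the vertex on the +z side.  Voxels are isotropic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "AIR", "SCALP", "SKULL", "CSF", "GM", "WM", "OTHER",
    "DEFAULT_LABEL_NAMES",
    "SegmentedHeadVolume", "TissueOpticalProperties", "FiducialSet",
    "AtlasVolume", "AgeProfile",
    "AGE_PROFILES", "PROFILE_ORDER", "concentric_spheres_profile",
    "default_optical_properties",
    "generate_phantom", "read_volume", "write_volume",
    "shell_sequence_along_ray", "check_shell_order",
]

# ---------------------------------------------------------------------------
# tissue labels
# ---------------------------------------------------------------------------

AIR, SCALP, SKULL, CSF, GM, WM, OTHER = 0, 1, 2, 3, 4, 5, 6

DEFAULT_LABEL_NAMES: dict[int, str] = {
    AIR: "air", SCALP: "scalp", SKULL: "skull", CSF: "CSF",
    GM: "GM", WM: "WM", OTHER: "other",
}

#: canonical shell order encountered travelling outward from the brain centre
SHELL_ORDER = (WM, GM, CSF, SKULL, SCALP, AIR)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SegmentedHeadVolume:
    """A 3D tissue-label grid with voxel geometry.

    ``labels`` holds one integer tissue label per voxel; ``label_names``
    maps each label value to a tissue name drawn from
    ``{air, scalp, skull, CSF, GM, WM, other}``.
    """

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray
    label_names: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        present = set(np.unique(self.labels).tolist())
        known = set(self.label_names)
        if not present <= known:
            raise ValueError(
                f"unknown label values present: {sorted(present - known)}")

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ijk_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Voxel index (may be fractional) -> world mm (voxel centres)."""
        return self.origin_mm + np.asarray(ijk, dtype=float) * self.voxel_size_mm

    def world_to_ijk(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.voxel_size_mm

    def label_at(self, xyz: np.ndarray) -> int:
        """Nearest-voxel label at a world position (air outside the grid)."""
        ijk = np.rint(self.world_to_ijk(xyz)).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.shape):
            return AIR
        return int(self.labels[tuple(ijk)])

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.labels == GM) | (self.labels == WM)

    def brain_centroid(self) -> np.ndarray:
        """Centroid (world mm) of the brain mask; the 'brain centre'."""
        ijk = np.argwhere(self.brain_mask)
        if len(ijk) == 0:
            raise ValueError("head model has an empty brain mask")
        return self.ijk_to_world(ijk.mean(axis=0))

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = [self.origin_mm[d] + np.arange(self.shape[d]) * self.voxel_size_mm
              for d in range(3)]
        return np.meshgrid(*ax, indexing="ij")


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Per-tissue NIR optical coefficients.

    ``mu_a``/``mu_s`` in 1/mm, Henyey-Greenstein anisotropy ``g`` and
    refractive index ``n`` per tissue name.
    """

    table: Mapping[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for tissue, (mu_a, mu_s, g, n) in self.table.items():
            if mu_a < 0 or mu_s < 0:
                raise ValueError(f"{tissue}: mu_a and mu_s must be >= 0")
            if not -1.0 < g < 1.0:
                raise ValueError(f"{tissue}: g must lie in (-1, 1)")
            if n < 1.0:
                raise ValueError(f"{tissue}: refractive index must be >= 1")
        if "air" in self.table and self.table["air"][1] != 0.0:
            raise ValueError("air must have mu_s = 0")

    def coefficient_arrays(self, label_names: Mapping[int, str]
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense per-label (mu_a, mu_s, g, n) arrays for the MC engine."""
        nmax = max(label_names) + 1
        mu_a = np.zeros(nmax); mu_s = np.zeros(nmax)
        g = np.zeros(nmax); n = np.ones(nmax)
        for lab, name in label_names.items():
            if name not in self.table:
                raise KeyError(f"no optical properties for tissue '{name}'")
            mu_a[lab], mu_s[lab], g[lab], n[lab] = self.table[name]
        return mu_a, mu_s, g, n


def default_optical_properties() -> TissueOpticalProperties:
    """Default NIR-band tissue coefficients.

    Values are configuration defaults on the scale of published ~800 nm
    tissue measurements, expressed in reduced-scattering-equivalent form
    (g = 0 with mu_s set to a typical mu_s'), which leaves diffuse transport
    beyond one transport mean free path unchanged while keeping desk-scale
    simulations affordable.
    """
    return TissueOpticalProperties({
        #               mu_a     mu_s    g    n
        "air":        (0.0,     0.0,   0.0, 1.0),
        "scalp":      (0.018,   0.76,  0.0, 1.37),
        "skull":      (0.016,   0.91,  0.0, 1.37),
        "CSF":        (0.0026,  0.10,  0.0, 1.33),
        "GM":         (0.018,   0.83,  0.0, 1.37),
        "WM":         (0.017,   1.19,  0.0, 1.37),
        "other":      (0.018,   0.80,  0.0, 1.37),
    })


@dataclass
class FiducialSet:
    """Named cranial landmark coordinates (world mm)."""

    points: Mapping[str, np.ndarray]

    REQUIRED = ("Nz", "Iz", "Vz", "LPA", "RPA", "M1", "M2")

    def __post_init__(self) -> None:
        missing = [k for k in self.REQUIRED if k not in self.points]
        if missing:
            raise ValueError(f"missing fiducials: {missing}")
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {k: list(map(float, v)) for k, v in self.points.items()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FiducialSet":
        return cls({k: np.array(v) for k, v in json.loads(Path(path).read_text()).items()})


@dataclass
class AtlasVolume:
    """Two-level sector atlas on the brain mask.

    Label 0 is background (non-brain); regions are numbered from 1.  Every
    fine region nests inside exactly one coarse region.
    """

    coarse_labels: np.ndarray
    fine_labels: np.ndarray
    coarse_names: Mapping[int, str]
    fine_names: Mapping[int, str]
    fine_to_coarse: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.coarse_labels.shape != self.fine_labels.shape:
            raise ValueError("coarse and fine grids must share a shape")

    def labels(self, level: str) -> np.ndarray:
        if level == "coarse":
            return self.coarse_labels
        if level == "fine":
            return self.fine_labels
        raise ValueError(f"unknown atlas level {level!r}")

    def names(self, level: str) -> Mapping[int, str]:
        return self.coarse_names if level == "coarse" else self.fine_names


@dataclass(frozen=True)
class AgeProfile:
    """Geometric parameters of one phantom.

    ``semi_axes_mm`` are the outer scalp semi-axes (x, y, z).  Shell
    thicknesses are radial, in mm.  ``ap_gap_gradient_mm`` widens the
    anterior CSF gap (extra CSF at the +y pole, tapering to zero at the -y
    pole).  ``hemispheric_asymmetry_mm`` > 0 deepens the left (-x) grey
    matter surface by that amount; < 0 deepens the right.
    ``inferior_gap_gradient_mm`` widens the gap toward the lowest
    circumference (zero at the vertex, the full value at the base),
    emulating the face/neck soft tissue that puts the lowest electrode ring
    farthest from the cortex on real heads.
    ``perturb_amplitude_mm``/``perturb_order`` add a low-order sinusoidal
    ripple to the GM surface.  ``atlas_rotation_deg`` rotates the angular
    sector boundaries of the generated atlas (used to emulate age-shifting
    region borders).
    """

    name: str
    semi_axes_mm: tuple[float, float, float]
    scalp_mm: float
    skull_mm: float
    csf_mm: float
    gm_mm: float = 3.0
    ap_gap_gradient_mm: float = 0.0
    inferior_gap_gradient_mm: float = 0.0
    hemispheric_asymmetry_mm: float = 0.0
    perturb_amplitude_mm: float = 0.0
    perturb_order: int = 6
    atlas_rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("scalp_mm", "skull_mm", "csf_mm", "gm_mm"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        total = self.scalp_mm + self.skull_mm + self.csf_mm + self.gm_mm
        extra = max(self.ap_gap_gradient_mm, 0.0) \
            + max(self.inferior_gap_gradient_mm, 0.0) \
            + abs(self.hemispheric_asymmetry_mm) + abs(self.perturb_amplitude_mm)
        if min(self.semi_axes_mm) <= total + extra:
            raise ValueError(
                f"profile '{self.name}': semi-axes {self.semi_axes_mm} do not "
                f"exceed the total shell thickness {total + extra:.1f} mm")


def _growth(w: float, scalp: float, skull: float, csf: float, inf: float,
            name: str) -> AgeProfile:
    return AgeProfile(name, (w, 1.25 * w, 0.95 * w), scalp, skull, csf,
                      inferior_gap_gradient_mm=inf)


#: Packaged infant-to-adult profile sequence.  Sizes and thicknesses are
#: monotone, plausible-scale defaults, NOT anatomical measurements.
AGE_PROFILES: dict[str, AgeProfile] = {
    "2wk":   _growth(44.0, 2.6, 2.6, 2.6, 2.0, "2wk"),
    "3mo":   _growth(50.0, 2.8, 2.9, 2.7, 2.2, "3mo"),
    "6mo":   _growth(53.0, 3.0, 3.2, 2.8, 2.4, "6mo"),
    "12mo":  _growth(56.0, 3.2, 3.5, 2.9, 2.6, "12mo"),
    "2yr":   _growth(59.0, 3.5, 3.9, 3.0, 2.8, "2yr"),
    "4yr":   _growth(62.0, 4.0, 4.4, 3.2, 3.2, "4yr"),
    "12yr":  _growth(67.0, 5.0, 5.4, 3.6, 3.8, "12yr"),
    "adult": _growth(72.0, 6.0, 6.5, 4.0, 4.5, "adult"),
}

PROFILE_ORDER = ("2wk", "3mo", "6mo", "12mo", "2yr", "4yr", "12yr", "adult")


def concentric_spheres_profile(radius_mm: float = 80.0, scalp_mm: float = 4.0,
                               skull_mm: float = 4.0, csf_mm: float = 2.0,
                               gm_mm: float = 15.0, name: str = "sphere") -> AgeProfile:
    """Concentric-sphere benchmark head (equal semi-axes, no gradients)."""
    return AgeProfile(name, (radius_mm, radius_mm, radius_mm),
                      scalp_mm, skull_mm, csf_mm, gm_mm=gm_mm)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(profile: AgeProfile, voxel_size_mm: float = 2.0,
                     seed: int = 0) -> tuple[SegmentedHeadVolume, FiducialSet, AtlasVolume]:
    """Generate a segmented head volume, fiducials and a two-level atlas.

    Deterministic given (profile, voxel size, seed); the seed only matters
    when the surface perturbation is active (random phase offsets).
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    a, b, c = profile.semi_axes_mm
    margin = 2 * voxel_size_mm
    half = np.array([a, b, c]) + margin
    n = 2 * np.ceil(half / voxel_size_mm).astype(int) + 1
    for axis, nv in enumerate(n):
        if (nv - 1) * voxel_size_mm / 2 < [a, b, c][axis] + 2 * voxel_size_mm - voxel_size_mm:
            raise ValueError(f"grid too small along axis {axis}")
    origin = -(n - 1) / 2.0 * voxel_size_mm
    head = SegmentedHeadVolume(np.zeros(tuple(n), dtype=np.int16),
                               voxel_size_mm, origin)

    X, Y, Z = head.voxel_centers_world()
    r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = 1.0 / np.maximum(r, 1e-9)
        ux, uy, uz = X * inv, Y * inv, Z * inv
        # distance from the centre to the scalp ellipsoid along each direction
        r_scalp = 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)

    r_skull = r_scalp - profile.scalp_mm
    r_csf = r_skull - profile.skull_mm
    # local extra gap: anterior-posterior gradient, vertex-to-base
    # gradient, hemispheric offset
    extra = profile.ap_gap_gradient_mm * 0.5 * (1.0 + uy) \
        + profile.inferior_gap_gradient_mm * 0.5 * (1.0 - uz)
    if profile.hemispheric_asymmetry_mm > 0:
        extra = extra + np.where(ux < 0, profile.hemispheric_asymmetry_mm, 0.0)
    elif profile.hemispheric_asymmetry_mm < 0:
        extra = extra + np.where(ux > 0, -profile.hemispheric_asymmetry_mm, 0.0)
    if profile.perturb_amplitude_mm != 0.0:
        rng = np.random.default_rng(seed)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        theta = np.arccos(np.clip(uz, -1, 1))
        phi = np.arctan2(ux, uy)
        extra = extra + profile.perturb_amplitude_mm * 0.5 * (
            1.0 + np.sin(profile.perturb_order * theta + ph1)
            * np.cos(profile.perturb_order * phi + ph2))
    r_gm = r_csf - profile.csf_mm - extra
    r_wm = r_gm - profile.gm_mm

    lab = head.labels
    lab[...] = AIR
    lab[r <= r_scalp] = SCALP
    lab[r <= r_skull] = SKULL
    lab[r <= r_csf] = CSF
    lab[r <= r_gm] = GM
    lab[r <= r_wm] = WM

    fid = FiducialSet({
        "Nz": (0.0, b, 0.0), "Iz": (0.0, -b, 0.0), "Vz": (0.0, 0.0, c),
        "LPA": (-a, 0.0, 0.0), "RPA": (a, 0.0, 0.0),
        "M1": _ellipsoid_point((-np.cos(np.deg2rad(20)), 0.0, -np.sin(np.deg2rad(20))), a, b, c),
        "M2": _ellipsoid_point((np.cos(np.deg2rad(20)), 0.0, -np.sin(np.deg2rad(20))), a, b, c),
    })

    atlas = _build_atlas(head, rotation_deg=profile.atlas_rotation_deg)
    return head, fid, atlas


def _ellipsoid_point(direction, a, b, c) -> np.ndarray:
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    rr = 1.0 / np.sqrt((u[0] / a) ** 2 + (u[1] / b) ** 2 + (u[2] / c) ** 2)
    return u * rr


# -- atlas ------------------------------------------------------------------

_COARSE_NAMES = {
    1: "frontal", 2: "occipital", 3: "temporal_left", 4: "temporal_right",
    5: "parietal_central", 6: "cerebellum",
}

_N_PHI, _N_THETA = 4, 2  # fine subdivision cells per coarse sector


def _build_atlas(head: SegmentedHeadVolume, rotation_deg: float = 0.0) -> AtlasVolume:
    """Angular-sector atlas about the brain centroid.

    Coarse level: six lobar-style sectors (frontal, occipital, left/right
    temporal, parietal/central, cerebellum).  Fine level: each coarse sector
    is intersected with a fixed longitude x colatitude grid, giving sublobar
    sectors that nest exactly.
    """
    brain = head.brain_mask
    centroid = head.brain_centroid()
    X, Y, Z = head.voxel_centers_world()
    dx, dy, dz = X - centroid[0], Y - centroid[1], Z - centroid[2]
    rr = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    inv = 1.0 / np.maximum(rr, 1e-9)
    ux, uy, uz = dx * inv, dy * inv, dz * inv
    if rotation_deg:
        ang = np.deg2rad(rotation_deg)
        uy, ux = uy * np.cos(ang) - ux * np.sin(ang), uy * np.sin(ang) + ux * np.cos(ang)

    coarse = np.zeros(head.shape, dtype=np.int16)
    cere = (uz < -0.3) & (uy < -0.1)
    frontal = ~cere & (uy >= 0.3)
    occip = ~cere & (uy <= -0.3)
    tl = ~cere & ~frontal & ~occip & (ux <= -0.35)
    tr = ~cere & ~frontal & ~occip & (ux >= 0.35)
    rest = ~(cere | frontal | occip | tl | tr)
    for lab_id, m in ((1, frontal), (2, occip), (3, tl), (4, tr), (5, rest), (6, cere)):
        coarse[m & brain] = lab_id

    # fine = coarse x fixed angular cell
    phi = np.arctan2(ux, uy)           # longitude, 0 = anterior
    theta = np.arccos(np.clip(uz, -1, 1))
    iphi = np.clip(((phi + np.pi) / (2 * np.pi) * _N_PHI).astype(int), 0, _N_PHI - 1)
    ith = np.clip((theta / np.pi * _N_THETA).astype(int), 0, _N_THETA - 1)
    cell = iphi * _N_THETA + ith
    fine = np.where(brain, (coarse - 1) * (_N_PHI * _N_THETA) + cell + 1, 0).astype(np.int16)
    fine[~brain] = 0

    fine_names = {}
    fine_to_coarse = {}
    for cid, cname in _COARSE_NAMES.items():
        for k in range(_N_PHI * _N_THETA):
            fid = (cid - 1) * (_N_PHI * _N_THETA) + k + 1
            if np.any(fine == fid):
                fine_names[fid] = f"{cname}_s{k + 1}"
                fine_to_coarse[fid] = cid
    fine[~np.isin(fine, list(fine_names) + [0])] = 0
    present_coarse = {cid: nm for cid, nm in _COARSE_NAMES.items() if np.any(coarse == cid)}
    return AtlasVolume(coarse, fine, present_coarse, fine_names, fine_to_coarse)


# ---------------------------------------------------------------------------
# volume I/O (NIfTI)
# ---------------------------------------------------------------------------

def write_volume(path: str | Path, data: np.ndarray, voxel_size_mm: float,
                 origin_mm: np.ndarray) -> None:
    """Write a label or scalar-field grid as NIfTI (voxel-centre origin)."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = np.asarray(origin_mm, dtype=float)
    if np.issubdtype(data.dtype, np.integer):
        img = nib.Nifti1Image(np.asarray(data, dtype=np.int16), affine)
    else:
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path: str | Path, kind: str = "labels",
                label_names: Mapping[int, str] | None = None):
    """Read a NIfTI volume.

    ``kind='labels'`` returns a :class:`SegmentedHeadVolume` (values are
    validated against ``label_names``); ``kind='field'`` returns
    ``(data, voxel_size_mm, origin_mm)`` for scalar fields.
    """
    img = nib.load(str(path))
    vox = float(img.header.get_zooms()[0])
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    data = np.asarray(img.dataobj)
    if kind == "field":
        return np.asarray(data, dtype=np.float32), vox, origin
    if kind != "labels":
        raise ValueError(f"unknown kind {kind!r}")
    names = dict(label_names or DEFAULT_LABEL_NAMES)
    data = np.asarray(data).astype(np.int16)
    present = set(np.unique(data).tolist())
    if not present <= set(names):
        raise ValueError(f"unknown label values on read: {sorted(present - set(names))}")
    return SegmentedHeadVolume(data, vox, origin, names)


# ---------------------------------------------------------------------------
# shell-order diagnostics
# ---------------------------------------------------------------------------

def shell_sequence_along_ray(head: SegmentedHeadVolume,
                             direction: np.ndarray) -> list[int]:
    """Distinct label sequence along the face-connected voxel chain from the
    brain centroid outward (exact grid traversal, so no voxel the ray passes
    through is skipped)."""
    centroid = head.brain_centroid()
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    vox = head.voxel_size_mm
    max_r = float(np.linalg.norm(np.asarray(head.shape)) * vox)
    # parameters of all axis-plane crossings within range
    start_ijk = head.world_to_ijk(centroid)
    ts = [0.0]
    for ax in range(3):
        if abs(u[ax]) < 1e-12:
            continue
        # planes sit halfway between voxel centres
        k0 = start_ijk[ax]
        first = np.floor(k0 + 0.5) + (0.5 if u[ax] > 0 else -0.5)
        step = 1.0 if u[ax] > 0 else -1.0
        plane = first
        while True:
            t = (plane - k0) * vox / u[ax]
            if t > max_r:
                break
            if t > 0:
                ts.append(t)
            plane += step
    ts = np.sort(np.asarray(ts))
    mids = 0.5 * (ts[:-1] + ts[1:])
    seq: list[int] = [head.label_at(centroid)]
    for t in mids:
        lab = head.label_at(centroid + t * u)
        if lab != seq[-1]:
            seq.append(lab)
        if lab == AIR:
            break
    return seq


def check_shell_order(head: SegmentedHeadVolume, n_rays: int = 1000,
                      seed: int = 0) -> float:
    """Fraction of random centroid rays whose tissue sequence respects the
    inside-out shell order (interior labels, then GM, CSF, skull, scalp, air
    with no shell skipped)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_rays, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    shells = (GM, CSF, SKULL, SCALP, AIR)
    ok = 0
    for d in u:
        seq = shell_sequence_along_ray(head, d)
        # every shell must appear, in inside-out order of first appearance
        # (boundary jitter from voxel sampling may repeat labels afterwards)
        try:
            firsts = [seq.index(s) for s in shells]
        except ValueError:
            continue
        if all(a < b for a, b in zip(firsts, firsts[1:])):
            ok += 1
    return ok / n_rays
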