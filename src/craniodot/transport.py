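"""Voxel Monte Carlo photon migration (time-integrated fluence).

A standard survival-weighted random walk on the segmented label grid:

* step lengths are sampled from ``exp(-mu_t s)`` with the total attenuation
  coefficient of the current tissue, traversing voxel boundaries exactly
  (DDA marching);
* at each interaction the photon weight is multiplied by the single-scatter
  albedo ``mu_s / mu_t`` (the absorbed share is bookkept), and a new
  direction is drawn from the Henyey-Greenstein phase function with the
  tissue anisotropy ``g``;
* fluence is tallied with the track-length estimator: every traversed
  segment adds ``weight x length`` to its voxel, normalised per launched
  photon and per voxel volume (units mm^-2 per photon);
* photons crossing into air (or off the grid) terminate as escaped weight;
  optionally a Fresnel specular reflection is applied at the air boundary;
* weights below 1e-4 play Russian roulette with survival probability 0.1.

The random stream is counter-based per photon index (splitmix64 seeded by
``(seed, photon id)``), so results are bit-reproducible and independent of
execution order.  An analytic diffusion-approximation oracle for the
infinite homogeneous medium is provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .phantom import AIR, SegmentedHeadVolume, TissueOpticalProperties

__all__ = ["SourceSpec", "FluenceVolume", "simulate_fluence",
           "diffusion_fluence_oracle", "ROULETTE_THRESHOLD", "ROULETTE_SURVIVAL"]

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class SourceSpec:
    """A pencil source on the scalp pointing into the head."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    n_photons: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("photon count must be >= 1")
        d = np.linalg.norm(self.direction)
        if not np.isfinite(d) or d < 1e-9:
            raise ValueError("source direction must be a nonzero vector")


@dataclass
class FluenceVolume:
    """Per-voxel photon fluence for one optode (track-length tally).

    ``data`` is on the head grid, in mm^-2 per launched photon.  The energy
    ledger (absorbed / escaped / roulette net) is kept for conservation
    checks.
    """

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray
    source: SourceSpec
    absorbed_weight: float
    escaped_weight: float
    roulette_net_weight: float
    label: str = ""

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def n_photons(self) -> int:
        return self.source.n_photons

    def conservation_error(self) -> float:
        """Relative weight-ledger error (should be ~ float precision)."""
        n = float(self.n_photons)
        return abs(self.absorbed_weight + self.escaped_weight
                   + self.roulette_net_weight - n) / n

    def argmax_in(self, idx: np.ndarray) -> tuple[np.ndarray, float]:
        """(voxel index, value) of the maximum over an (N, 3) index set."""
        vals = self.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        k = int(np.argmax(vals))
        return idx[k], float(vals[k])


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

_U64 = np.uint64
_MIX1 = _U64(0x9E3779B97F4A7C15)
_MIX2 = _U64(0xBF58476D1CE4E5B9)
_MIX3 = _U64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _splitmix(state):
    state = state + _U64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    z = z ^ (z >> _U64(31))
    return state, z


@njit(cache=True, inline="always")
def _uniform(state):
    state, z = _splitmix(state)
    return state, (np.float64(z >> _U64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def _mc_kernel(labels, mu_a, mu_s, g_arr, n_arr, vox, ox, oy, oz,
               px, py, pz, dx, dy, dz, n_photons, seed, fresnel):
    nx, ny, nz = labels.shape
    flu = np.zeros((nx, ny, nz), dtype=np.float32)
    absorbed = 0.0
    escaped = 0.0
    roulette = 0.0
    eps = 1e-6 * vox
    for pid in range(n_photons):
        state = _U64(seed) ^ (_U64(pid) * _MIX1 + _U64(0x632BE59BD9B4E019))
        state, _ = _splitmix(state)
        x, y, z = px, py, pz
        ux, uy, uz = dx, dy, dz
        w = 1.0
        state, u = _uniform(state)
        tau = -np.log(u)
        i = int(np.floor((x - ox) / vox + 0.5))
        j = int(np.floor((y - oy) / vox + 0.5))
        k = int(np.floor((z - oz) / vox + 0.5))
        while True:
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                escaped += w
                break
            lab = labels[i, j, k]
            if lab == 0:  # air: photon has left the head
                escaped += w
                break
            mua = mu_a[lab]
            mus = mu_s[lab]
            mut = mua + mus
            # distance to the voxel boundary along the current direction
            tb = 1e30
            axc = 0
            if ux > 0.0:
                t = ((i + 0.5) * vox + ox - x) / ux
                if t < tb:
                    tb = t; axc = 0
            elif ux < 0.0:
                t = ((i - 0.5) * vox + ox - x) / ux
                if t < tb:
                    tb = t; axc = 0
            if uy > 0.0:
                t = ((j + 0.5) * vox + oy - y) / uy
                if t < tb:
                    tb = t; axc = 1
            elif uy < 0.0:
                t = ((j - 0.5) * vox + oy - y) / uy
                if t < tb:
                    tb = t; axc = 1
            if uz > 0.0:
                t = ((k + 0.5) * vox + oz - z) / uz
                if t < tb:
                    tb = t; axc = 2
            elif uz < 0.0:
                t = ((k - 0.5) * vox + oz - z) / uz
                if t < tb:
                    tb = t; axc = 2
            if tb < 0.0:
                tb = 0.0
            if mut * tb < tau or mut <= 0.0:
                # traverse this voxel and cross into the neighbour
                flu[i, j, k] += w * tb
                if mut > 0.0:
                    tau -= mut * tb
                x += (tb + eps) * ux
                y += (tb + eps) * uy
                z += (tb + eps) * uz
                if axc == 0:
                    di = 1 if ux > 0.0 else -1
                    i2, j2, k2 = i + di, j, k
                elif axc == 1:
                    di = 1 if uy > 0.0 else -1
                    i2, j2, k2 = i, j + di, k
                else:
                    di = 1 if uz > 0.0 else -1
                    i2, j2, k2 = i, j, k + di
                if fresnel:
                    inb = 0 <= i2 < nx and 0 <= j2 < ny and 0 <= k2 < nz
                    lab2 = labels[i2, j2, k2] if inb else 0
                    if lab2 == 0:
                        # specular Fresnel reflection at the crossed face
                        n1 = n_arr[lab]
                        if axc == 0:
                            ci = abs(ux)
                        elif axc == 1:
                            ci = abs(uy)
                        else:
                            ci = abs(uz)
                        sin_t2 = n1 * np.sqrt(max(0.0, 1.0 - ci * ci))
                        if sin_t2 >= 1.0:
                            refl = 1.0  # total internal reflection
                        else:
                            ct = np.sqrt(1.0 - sin_t2 * sin_t2)
                            rs = (n1 * ci - ct) / (n1 * ci + ct)
                            rp = (n1 * ct - ci) / (n1 * ct + ci)
                            refl = 0.5 * (rs * rs + rp * rp)
                        state, u = _uniform(state)
                        if u < refl:
                            # step back inside and flip the crossed component
                            x -= 2.0 * eps * ux
                            y -= 2.0 * eps * uy
                            z -= 2.0 * eps * uz
                            if axc == 0:
                                ux = -ux
                            elif axc == 1:
                                uy = -uy
                            else:
                                uz = -uz
                            continue
                i, j, k = i2, j2, k2
                continue
            # interaction inside this voxel
            s = tau / mut
            flu[i, j, k] += w * s
            x += s * ux
            y += s * uy
            z += s * uz
            absorbed += w * (mua / mut)
            w *= mus / mut
            # scatter: Henyey-Greenstein; for g ~ 0 the phase function is
            # isotropic and a trig-free Marsaglia draw is used instead
            g = g_arr[lab]
            if abs(g) < 1e-6:
                while True:
                    state, u = _uniform(state)
                    a = 2.0 * u - 1.0
                    state, u = _uniform(state)
                    b = 2.0 * u - 1.0
                    s2 = a * a + b * b
                    if 1e-12 < s2 < 1.0:
                        break
                rt = 2.0 * np.sqrt(1.0 - s2)
                ux = a * rt
                uy = b * rt
                uz = 1.0 - 2.0 * s2
            else:
                state, u = _uniform(state)
                f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cost = (1.0 + g * g - f * f) / (2.0 * g)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
                sint = np.sqrt(max(0.0, 1.0 - cost * cost))
                state, u = _uniform(state)
                phi = 2.0 * np.pi * u
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    nux = sint * cosp
                    nuy = sint * sinp
                    nuz = cost if uz >= 0 else -cost
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                    nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                    nuz = -sint * cosp * den + uz * cost
                nn = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux, uy, uz = nux / nn, nuy / nn, nuz / nn
            state, u = _uniform(state)
            tau = -np.log(u)
            # Russian roulette below the weight floor
            if w < 1e-4:
                state, u = _uniform(state)
                if u < 0.1:
                    roulette -= w * (1.0 / 0.1 - 1.0)
                    w = w / 0.1
                else:
                    roulette += w
                    escaped += 0.0
                    break
    return flu, absorbed, escaped, roulette


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_fluence(head: SegmentedHeadVolume, props: TissueOpticalProperties,
                     source: SourceSpec, fresnel: bool = False,
                     label: str = "") -> FluenceVolume:
    """Run the Monte Carlo walk for one optode and return its fluence volume.

    Deterministic given ``source.seed``.  Raises before launch if optical
    properties are missing for any label present in the volume, or if the
    source's first step lands in air.
    """
    mu_a, mu_s, g_arr, n_arr = props.coefficient_arrays(head.label_names)
    present = np.unique(head.labels)
    for lab in present:
        if lab >= len(mu_a):
            raise KeyError(f"no optical properties for label {lab}")

    p = np.asarray(source.position, dtype=float)
    d = np.asarray(source.direction, dtype=float)
    d = d / np.linalg.norm(d)
    # the scalp position may sit within half a voxel of the boundary on
    # either side; start at the first tissue sample along the beam
    vox = head.voxel_size_mm
    start = None
    for t in np.arange(0.0, 3.0 * vox, 0.25 * vox):
        if head.label_at(p + t * d) != AIR:
            start = p + t * d
            break
    if start is None or head.label_at(start + vox * d) == AIR:
        raise ValueError("source direction points into air, not into the head")

    flu, absorbed, escaped, roulette = _mc_kernel(
        np.ascontiguousarray(head.labels, dtype=np.int16),
        mu_a, mu_s, g_arr, n_arr,
        float(head.voxel_size_mm),
        float(head.origin_mm[0]), float(head.origin_mm[1]), float(head.origin_mm[2]),
        float(start[0]), float(start[1]), float(start[2]),
        float(d[0]), float(d[1]), float(d[2]),
        int(source.n_photons), np.uint64(source.seed & 0xFFFFFFFFFFFFFFFF),
        bool(fresnel))
    norm = head.voxel_size_mm ** 3 * source.n_photons
    return FluenceVolume(flu.astype(np.float64) / norm, head.voxel_size_mm, head.origin_mm.copy(),
                         source, absorbed, escaped, roulette, label=label)


def diffusion_fluence_oracle(mu_a: float, mu_s_prime: float, r) -> float | np.ndarray:
    """Infinite-medium diffusion-approximation fluence of a point source.

    ``exp(-mu_eff r) / (4 pi D r)`` with ``D = 1/(3 (mu_a + mu_s'))`` and
    ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))``; units mm^-2 per unit source
    power.  Valid for ``r`` beyond a transport mean free path.
    """
    r = np.asarray(r, dtype=float)
    if mu_a <= 0 or mu_s_prime <= 0 or np.any(r <= 0):
        raise ValueError("mu_a, mu_s_prime and r must all be positive")
    D = 1.0 / (3.0 * (mu_a + mu_s_prime))
    mu_eff = np.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))
    out = np.exp(-mu_eff * r) / (4.0 * np.pi * D * r)
    return float(out) if out.ndim == 0 else out
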