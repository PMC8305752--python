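"""Monte Carlo photon transport: conservation, determinism, physics."""

import numpy as np
import pytest
from numba import njit

from craniodot.phantom import (GM, SegmentedHeadVolume,
                               TissueOpticalProperties,
                               default_optical_properties)
from craniodot.transport import (SourceSpec, _uniform, _U64,
                                 diffusion_fluence_oracle, simulate_fluence)


@pytest.fixture(scope="module")
def box_medium():
    """Homogeneous all-GM box, source at the centre (infinite-medium stand-in)."""
    n = 81
    labels = np.full((n, n, n), GM, dtype=np.int16)
    origin = -np.ones(3) * (n - 1) / 2 * 2.0
    head = SegmentedHeadVolume(labels, 2.0, origin, {0: "air", GM: "GM"})
    props = TissueOpticalProperties({"air": (0.0, 0.0, 0.0, 1.0),
                                     "GM": (0.01, 1.0, 0.0, 1.37)})
    return head, props


def _shell_mean(head, data, r, width=1.0):
    X, Y, Z = head.voxel_centers_world()
    R = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    sel = (R > r - width) & (R < r + width)
    return float(data[sel].mean())


def test_energy_conservation_with_roulette(sphere):
    """Escaped + absorbed + roulette-net weight equals launched weight to
    1e-6 relative, on a heterogeneous head."""
    pos = sphere.m10["Cz"].xyz
    src = SourceSpec(tuple(pos), tuple(-pos / np.linalg.norm(pos)), 5000, 11)
    flu = simulate_fluence(sphere.head, default_optical_properties(), src)
    assert flu.conservation_error() <= 1e-6
    assert np.all(flu.data >= 0.0)
    assert np.all(np.isfinite(flu.data))


def test_bit_identical_reruns(box_medium):
    head, props = box_medium
    a = simulate_fluence(head, props, SourceSpec((0, 0, 0), (0, 0, 1), 20000, 9))
    b = simulate_fluence(head, props, SourceSpec((0, 0, 0), (0, 0, 1), 20000, 9))
    assert np.array_equal(a.data, b.data)
    assert a.escaped_weight == b.escaped_weight
    c = simulate_fluence(head, props, SourceSpec((0, 0, 0), (0, 0, 1), 20000, 10))
    assert not np.array_equal(a.data, c.data)


def test_fluence_decays_from_source(box_medium):
    head, props = box_medium
    flu = simulate_fluence(head, props,
                           SourceSpec((0, 0, 0), (0, 0, 1), 50000, 2))
    means = [_shell_mean(head, flu.data, r) for r in (4, 8, 12, 16, 20)]
    assert all(b < a for a, b in zip(means, means[1:]))


def test_independent_seeds_agree_within_3se(box_medium):
    head, props = box_medium
    vals = []
    for seed in (1, 2, 3, 4):
        flu = simulate_fluence(head, props,
                               SourceSpec((0, 0, 0), (0, 0, 1), 8000, seed))
        vals.append(_shell_mean(head, flu.data, 10.0))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert np.all(np.abs(vals - vals.mean()) <= 3 * len(vals) ** 0.5 * se)


def test_diffusion_oracle_closed_form():
    mu_a, mu_sp, r = 0.01, 1.0, 10.0
    D = 1.0 / (3.0 * 1.01)
    mu_eff = np.sqrt(3 * 0.01 * 1.01)
    expected = np.exp(-mu_eff * r) / (4 * np.pi * D * r)
    assert diffusion_fluence_oracle(mu_a, mu_sp, r) == pytest.approx(expected,
                                                                    rel=1e-12)
    rr = np.linspace(0.5, 50, 200)
    vals = diffusion_fluence_oracle(mu_a, mu_sp, rr)
    assert np.all(np.diff(vals) < 0)
    assert diffusion_fluence_oracle(0.02, mu_sp, r) < expected
    with pytest.raises(ValueError):
        diffusion_fluence_oracle(-0.01, 1.0, 5.0)
    with pytest.raises(ValueError):
        diffusion_fluence_oracle(0.01, 1.0, 0.0)


def test_henyey_greenstein_sampler_moments():
    """The HG inversion reproduces E[cos] = g and the closed-form second
    moment of the phase function."""

    @njit(cache=True)
    def draws(g, n, seed):
        out = np.empty(n)
        state = _U64(seed)
        for i in range(n):
            state, u = _uniform(state)
            f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
            out[i] = (1.0 + g * g - f * f) / (2.0 * g)
        return out

    for g in (0.5, 0.9):
        c = draws(g, 400_000, 77)
        assert np.all((-1.0 <= c) & (c <= 1.0))
        assert c.mean() == pytest.approx(g, abs=0.005)
        # E[cos^2] of HG: (1 + 2 g^2 - ...) computed by quadrature
        from scipy.integrate import quad
        m2, _ = quad(lambda mu: mu ** 2 * 0.5 * (1 - g ** 2)
                     / (1 + g ** 2 - 2 * g * mu) ** 1.5, -1, 1)
        assert (c ** 2).mean() == pytest.approx(m2, abs=0.005)


def test_anisotropic_walk_conserves_and_decays(sphere):
    props = TissueOpticalProperties({
        "air": (0.0, 0.0, 0.0, 1.0), "scalp": (0.018, 7.6, 0.9, 1.37),
        "skull": (0.016, 9.1, 0.9, 1.37), "CSF": (0.0026, 1.0, 0.9, 1.33),
        "GM": (0.018, 8.3, 0.9, 1.37), "WM": (0.017, 11.9, 0.9, 1.37),
        "other": (0.018, 8.0, 0.9, 1.37)})
    pos = sphere.m10["Cz"].xyz
    flu = simulate_fluence(sphere.head, props,
                           SourceSpec(tuple(pos), tuple(-pos / np.linalg.norm(pos)),
                                      2000, 5))
    assert flu.conservation_error() <= 1e-6
    assert flu.data.max() > 0


def test_fresnel_flag_reduces_escape(sphere):
    """Index-mismatched boundaries reflect some outbound photons back."""
    pos = sphere.m10["Cz"].xyz
    src = SourceSpec(tuple(pos), tuple(-pos / np.linalg.norm(pos)), 4000, 6)
    props = default_optical_properties()
    matched = simulate_fluence(sphere.head, props, src, fresnel=False)
    fresnel = simulate_fluence(sphere.head, props, src, fresnel=True)
    assert fresnel.conservation_error() <= 1e-6
    assert fresnel.escaped_weight < matched.escaped_weight


def test_source_validation(sphere, box_medium):
    head, props = box_medium
    with pytest.raises(ValueError):
        SourceSpec((0, 0, 0), (0, 0, 1), 0, 1)
    pos = sphere.m10["Cz"].xyz
    with pytest.raises(ValueError, match="air"):
        simulate_fluence(sphere.head, default_optical_properties(),
                         SourceSpec(tuple(pos), tuple(pos / np.linalg.norm(pos)),
                                    100, 1))
    bad_props = TissueOpticalProperties({"air": (0.0, 0.0, 0.0, 1.0)})
    with pytest.raises(KeyError):
        simulate_fluence(sphere.head, bad_props,
                         SourceSpec(tuple(pos), tuple(-pos / np.linalg.norm(pos)),
                                    100, 1))
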