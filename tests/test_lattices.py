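"""Lattice specs, force fields, regions and unit conventions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import heatchain as hc
from heatchain import exact
from heatchain.lattices import (
    MassDisorderedSpec,
    PBDSpec,
    ReservoirConfig,
    UniformHarmonicSpec,
    build_force,
    from_natural_units,
    load_mass_table,
    load_spec,
    pbd_harmonic_limit,
    region_of,
    save_mass_table,
    save_spec,
    to_natural_units,
    NATURAL,
    PHYSICAL_EV_NM_U,
)


def _fd_gradient(ff, x, eps=1e-6):
    n = len(x)
    g = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = eps
        g[i] = (ff.energy(x + e) - ff.energy(x - e)) / (2 * eps)
    return g


def _specs():
    return [
        UniformHarmonicSpec(n_sites=7, n_reservoir=2, mass=1.3, coupling=0.8,
                            onsite=1.7),
        MassDisorderedSpec.sample(n_sites=7, n_reservoir=2, mass=1.1, delta=0.3,
                                  coupling=1.2, onsite=0.6, seed=4),
        PBDSpec(n_sites=7, n_reservoir=2),
    ]


@pytest.mark.parametrize("spec", _specs(), ids=["uniform", "disordered", "pbd"])
def test_force_is_negative_energy_gradient(spec):
    """-dH/dx at random displacements matches central finite differences."""
    ff = build_force(spec)
    scale = 0.02 if isinstance(spec, PBDSpec) else 1.0
    rng = np.random.default_rng(11)
    for _ in range(3):
        x = scale * rng.normal(size=spec.n_sites)
        f = ff.forces(x)
        fd = -_fd_gradient(ff, x, eps=1e-6 * scale)
        assert np.allclose(f, fd, rtol=1e-6, atol=1e-6 * np.max(np.abs(f) + 1))


def test_uniform_equilibrium_and_single_site_forces():
    spec = UniformHarmonicSpec(n_sites=5, n_reservoir=1, coupling=1.4, onsite=0.9)
    ff = build_force(spec)
    assert ff.energy(np.zeros(5)) == 0.0
    assert np.all(ff.forces(np.zeros(5)) == 0.0)
    x = np.zeros(5)
    x[2] = 0.3
    f = ff.forces(x)
    D, K = spec.onsite, spec.coupling
    assert f[2] == pytest.approx(-(D + 2 * K) * 0.3)
    assert f[1] == pytest.approx(K * 0.3)
    assert f[3] == pytest.approx(K * 0.3)
    assert f[0] == f[4] == 0.0


def test_force_rejects_wrong_length():
    ff = build_force(UniformHarmonicSpec(n_sites=5, n_reservoir=1))
    with pytest.raises(ValueError):
        ff.forces(np.zeros(4))


def test_phantom_ends_pull_end_sites():
    """End sites are bonded to fixed zero-displacement phantoms."""
    spec = UniformHarmonicSpec(n_sites=3, n_reservoir=1, coupling=2.0, onsite=0.0)
    ff = build_force(spec)
    x = np.array([0.5, 0.0, 0.0])
    # site 1 feels -K x from the phantom bond plus -K x toward site 2
    assert ff.forces(x)[0] == pytest.approx(-2 * 2.0 * 0.5)


def test_region_labels_and_counts():
    spec = UniformHarmonicSpec(n_sites=5, n_reservoir=1)
    assert region_of(1, spec) == "L"
    assert region_of(3, spec) == "F"
    assert region_of(5, spec) == "R"
    big = UniformHarmonicSpec(n_sites=300, n_reservoir=100)
    labels = [region_of(i, big) for i in range(1, 301)]
    assert labels.count("F") == 100
    assert labels.count("L") == labels.count("R") == 100
    with pytest.raises(IndexError):
        region_of(0, spec)
    with pytest.raises(IndexError):
        region_of(6, spec)


@given(n_r=st.integers(1, 5), n_free=st.integers(1, 10))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_region_partition_property(n_r, n_free):
    """L/F/R partition the chain contiguously with the right multiplicities."""
    n = n_free + 2 * n_r
    spec = UniformHarmonicSpec(n_sites=n, n_reservoir=n_r)
    labels = [region_of(i, spec) for i in range(1, n + 1)]
    assert labels == ["L"] * n_r + ["F"] * n_free + ["R"] * n_r


def test_spec_invariants_rejected():
    with pytest.raises(ValueError):
        UniformHarmonicSpec(n_sites=4, n_reservoir=2)     # empty free region
    with pytest.raises(ValueError):
        UniformHarmonicSpec(n_sites=5, n_reservoir=0)
    with pytest.raises(ValueError):
        UniformHarmonicSpec(n_sites=5, n_reservoir=1, coupling=-1.0)
    with pytest.raises(ValueError):
        ReservoirConfig(gamma=-0.1, t_left=1, t_right=1, n_reservoir=1)
    with pytest.raises(ValueError):
        MassDisorderedSpec.sample(n_sites=5, n_reservoir=1, delta=1.2)


def test_pbd_harmonic_limits():
    spec = PBDSpec(n_sites=5, n_reservoir=1)
    hi = pbd_harmonic_limit(spec, "high_T")
    assert hi.onsite == 0.0
    assert hi.coupling == spec.stacking_k
    lo = pbd_harmonic_limit(spec, "low_T")
    assert lo.coupling == pytest.approx(spec.stacking_k * 1.5)
    # rho = 0 switches the stacking amplitude off entirely
    plain = dataclasses.replace(spec, stacking_rho=0.0)
    assert pbd_harmonic_limit(plain, "low_T").coupling == pytest.approx(
        plain.stacking_k)
    # on-site curvature equals the numerical second derivative of the Morse term
    DM, a = spec.morse_depth, spec.morse_range
    h = 1e-5 / a
    morse = lambda x: DM * (np.exp(-a * x) - 1.0) ** 2
    curv = (morse(h) - 2 * morse(0.0) + morse(-h)) / h ** 2
    assert lo.onsite == pytest.approx(curv, rel=1e-8)


def test_disorder_sampling_statistics():
    """Mean mass is m; all draws stay inside m(1 +/- delta)."""
    draws = np.concatenate([
        MassDisorderedSpec.sample(n_sites=100, n_reservoir=1, mass=2.0,
                                  delta=0.3, seed=0, realization=r).site_masses
        for r in range(100)])
    assert len(draws) == 10_000
    assert draws.min() >= 2.0 * 0.7
    assert draws.max() <= 2.0 * 1.3
    assert abs(draws.mean() - 2.0) < 3 * draws.std() / np.sqrt(len(draws))
    again = MassDisorderedSpec.sample(n_sites=100, n_reservoir=1, mass=2.0,
                                      delta=0.3, seed=0, realization=7)
    once = MassDisorderedSpec.sample(n_sites=100, n_reservoir=1, mass=2.0,
                                     delta=0.3, seed=0, realization=7)
    assert np.array_equal(again.site_masses, once.site_masses)


def test_natural_units_scaling_and_round_trip():
    spec = UniformHarmonicSpec(n_sites=8, n_reservoir=1, mass=4.0, coupling=9.0,
                               onsite=9.0)
    res = ReservoirConfig(gamma=3.0, t_left=330.0, t_right=270.0, n_reservoir=1)
    nat_spec, nat_res, scales = to_natural_units(spec, res)
    assert nat_spec.mass == nat_spec.coupling == 1.0
    assert nat_spec.onsite == pytest.approx(1.0)          # D/K preserved
    # gamma in units sqrt(K m) = 6
    assert nat_res.gamma == pytest.approx(3.0 / 6.0)
    back_spec, back_res = from_natural_units(nat_spec, nat_res, scales)
    assert back_spec.mass == pytest.approx(spec.mass, rel=1e-12)
    assert back_spec.onsite == pytest.approx(spec.onsite, rel=1e-12)
    assert back_res.gamma == pytest.approx(res.gamma, rel=1e-12)
    assert back_res.t_left == pytest.approx(res.t_left, rel=1e-12)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_similarity_class_conductance_invariance(seed):
    """Physical chains with equal (D/K, gamma/sqrt(Km), N_r) share one
    natural-unit conductance."""
    rng = np.random.default_rng(seed)
    mass = float(rng.uniform(0.5, 500.0))
    coupling = float(rng.uniform(0.5, 20.0))
    dk = 1.0
    gnat = 0.7
    spec = UniformHarmonicSpec(n_sites=10, n_reservoir=2, mass=mass,
                               coupling=coupling, onsite=dk * coupling)
    res = ReservoirConfig(gamma=gnat * np.sqrt(coupling * mass),
                          t_left=315.0, t_right=285.0, n_reservoir=2)
    sol = exact.solve_steady_state(spec, res, units=PHYSICAL_EV_NM_U)
    _, _, scales = to_natural_units(spec, res)
    sigma_nat = sol.sigma / scales.conductance
    nat_spec = UniformHarmonicSpec(n_sites=10, n_reservoir=2, onsite=dk)
    nat_res = ReservoirConfig(gamma=gnat, t_left=1.05, t_right=0.95, n_reservoir=2)
    ref = exact.solve_steady_state(nat_spec, nat_res, units=NATURAL)
    assert sigma_nat == pytest.approx(ref.sigma, rel=1e-10)


def test_spec_file_round_trip(tmp_path):
    spec = UniformHarmonicSpec(n_sites=8, n_reservoir=2, mass=1.5, coupling=2.0,
                               onsite=3.0)
    res = ReservoirConfig(gamma=0.4, t_left=1.1, t_right=0.9, n_reservoir=2)
    p = tmp_path / "chain.yaml"
    save_spec(p, spec, res)
    spec2, res2, units = load_spec(p)
    assert spec2 == spec
    assert res2 == res
    pbd = PBDSpec(n_sites=30, n_reservoir=5)
    save_spec(tmp_path / "pbd.yaml", pbd)
    pbd2, _, _ = load_spec(tmp_path / "pbd.yaml")
    assert pbd2 == pbd


def test_mass_table_round_trip(tmp_path):
    spec = MassDisorderedSpec.sample(n_sites=9, n_reservoir=2, seed=5)
    p = tmp_path / "masses.csv"
    save_mass_table(p, spec)
    masses = load_mass_table(p)
    assert np.allclose(masses, spec.site_masses)
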