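"""Covariance (Lyapunov) steady-state solver for harmonic chains."""

import dataclasses

import numpy as np
import pytest

import heatchain as hc
from heatchain import exact
from heatchain.exact import (
    assemble_dynamics,
    bond_currents,
    converge_free_length,
    disorder_ensemble,
    solve_steady_state,
    steady_moments,
)
from heatchain.lattices import (
    MassDisorderedSpec,
    ReservoirConfig,
    UniformHarmonicSpec,
)


class TestAssemble:
    def test_damping_only_on_reservoir_sites(self):
        spec = UniformHarmonicSpec(n_sites=3, n_reservoir=1)
        res = ReservoirConfig(gamma=0.5, t_left=1.1, t_right=0.9, n_reservoir=1)
        dyn = assemble_dynamics(spec, res)
        assert np.array_equal(dyn.site_gammas, [0.5, 0.0, 0.5])
        # momentum-block damping rows: -gamma/m on L/R, zero on F
        damp = np.diag(dyn.drift[3:, 3:])
        assert np.allclose(damp, [-0.5, 0.0, -0.5])
        assert np.array_equal(dyn.noise_intensity, [2 * 0.5 * 1.1, 0.0,
                                                    2 * 0.5 * 0.9])

    def test_frictionless_drift_is_energy_conserving(self):
        spec = UniformHarmonicSpec(n_sites=6, n_reservoir=1)
        res = ReservoirConfig(gamma=0.0, t_left=1.0, t_right=1.0, n_reservoir=1)
        dyn = assemble_dynamics(spec, res)
        ev = np.linalg.eigvals(dyn.drift)
        assert np.max(ev.real) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("gamma", [1e-3, 0.5, 50.0])
    def test_damped_drift_is_strictly_stable(self, gamma):
        spec = UniformHarmonicSpec(n_sites=6, n_reservoir=1)
        res = ReservoirConfig(gamma=gamma, t_left=1.0, t_right=1.0, n_reservoir=1)
        ev = np.linalg.eigvals(assemble_dynamics(spec, res).drift)
        assert np.max(ev.real) < 0

    def test_rejects_pbd_and_mismatched_reservoirs(self):
        res = ReservoirConfig(gamma=1.0, t_left=1.0, t_right=1.0, n_reservoir=1)
        with pytest.raises(TypeError):
            assemble_dynamics(hc.PBDSpec(n_sites=5, n_reservoir=1), res)
        spec = UniformHarmonicSpec(n_sites=7, n_reservoir=2)
        with pytest.raises(ValueError):
            assemble_dynamics(spec, res)


class TestSteadyMoments:
    def test_equilibrium_equipartition_and_no_cross_moments(self):
        spec = MassDisorderedSpec.sample(n_sites=7, n_reservoir=2, mass=1.4,
                                         delta=0.3, seed=9)
        res = ReservoirConfig(gamma=0.7, t_left=1.3, t_right=1.3, n_reservoir=2)
        cov = steady_moments(assemble_dynamics(spec, res))
        n = spec.n_sites
        p2 = np.diag(cov[n:, n:])
        assert np.allclose(p2 / spec.site_masses, 1.3, rtol=1e-9)
        xp = np.diag(cov[:n, n:])
        assert np.max(np.abs(xp)) < 1e-10

    def test_gamma_zero_raises(self):
        spec = UniformHarmonicSpec(n_sites=5, n_reservoir=1)
        res = ReservoirConfig(gamma=0.0, t_left=1.0, t_right=1.0, n_reservoir=1)
        with pytest.raises(ValueError):
            steady_moments(assemble_dynamics(spec, res))


class TestBondCurrents:
    def test_equilibrium_currents_vanish(self):
        spec = UniformHarmonicSpec(n_sites=8, n_reservoir=2)
        res = ReservoirConfig(gamma=0.6, t_left=1.0, t_right=1.0, n_reservoir=2)
        sol = solve_steady_state(spec, res)
        assert np.max(np.abs(sol.currents)) < 1e-12
        assert sol.sigma is None

    def test_swapping_temperatures_negates_currents(self):
        spec = UniformHarmonicSpec(n_sites=8, n_reservoir=2)
        hot = ReservoirConfig(gamma=0.6, t_left=1.1, t_right=0.9, n_reservoir=2)
        cold = ReservoirConfig(gamma=0.6, t_left=0.9, t_right=1.1, n_reservoir=2)
        a = solve_steady_state(spec, hot)
        b = solve_steady_state(spec, cold)
        assert np.allclose(a.currents, -b.currents, rtol=1e-8,
                           atol=1e-14 * np.max(np.abs(a.currents)))
        assert a.sigma > 0                    # sign convention, T_L > T_R
        assert b.sigma == pytest.approx(a.sigma, rel=1e-9)

    def test_free_region_current_continuity(self, uniform12):
        spec, res = uniform12
        sol = solve_steady_state(spec, res)
        n_r = res.n_reservoir
        free = sol.currents[n_r:spec.n_sites - n_r - 1]
        jbar = free.mean()
        assert np.max(np.abs(free - jbar)) <= 1e-9 * abs(jbar)

    def test_global_energy_balance(self, uniform12):
        """Power injected at L equals transmitted current equals power
        extracted at R."""
        spec, res = uniform12
        sol = solve_steady_state(spec, res)
        p_left, p_right = sol.thermostat_power()
        assert p_left == pytest.approx(sol.free_mean_current, rel=1e-9)
        assert p_right == pytest.approx(-sol.free_mean_current, rel=1e-9)

    def test_site_temperatures_within_reservoir_bounds(self, uniform12):
        spec, res = uniform12
        sol = solve_steady_state(spec, res)
        eps = 1e-9
        assert np.all(sol.kinetic_temperatures >= res.t_right - eps)
        assert np.all(sol.kinetic_temperatures <= res.t_left + eps)

    def test_sigma_independent_of_delta_t(self):
        """Linear dynamics: the conductance does not depend on the
        applied temperature difference."""
        spec = UniformHarmonicSpec(n_sites=10, n_reservoir=2)
        sigmas = []
        for dT in (0.2, 0.002):
            res = ReservoirConfig(gamma=0.9, t_left=1 + dT / 2,
                                  t_right=1 - dT / 2, n_reservoir=2)
            sigmas.append(solve_steady_state(spec, res).sigma)
        assert sigmas[0] == pytest.approx(sigmas[1], rel=1e-10)

    def test_positive_conductance_vanishing_at_friction_extremes(self):
        spec = UniformHarmonicSpec(n_sites=10, n_reservoir=2)
        gs = np.geomspace(1e-4, 1e4, 9)
        sig = []
        for g in gs:
            res = ReservoirConfig(gamma=g, t_left=1.05, t_right=0.95,
                                  n_reservoir=2)
            sig.append(solve_steady_state(spec, res).sigma)
        sig = np.array(sig)
        assert np.all(sig > 0)
        assert sig[0] < 1e-3 and sig[-1] < 1e-3
        assert sig.max() > 0.05


class TestFreeLengthConvergence:
    def test_uniform_chain_converges_fast(self, band_dk1):
        spec = UniformHarmonicSpec(n_sites=18, n_reservoir=1)
        res = ReservoirConfig(gamma=1.0, t_left=1.05, t_right=0.95, n_reservoir=1)
        conv = converge_free_length(spec, res, tol=1e-6)
        assert conv.converged
        assert len(conv.free_lengths) <= 4
        assert conv.sigma == pytest.approx(
            hc.theory.casher_lebowitz(1.0, band_dk1), rel=1e-6)
        diffs = np.abs(np.diff(conv.sigmas))
        assert np.all(diffs <= 1e-6 * abs(conv.sigma))

    def test_refuses_disordered_family(self):
        spec = MassDisorderedSpec.sample(n_sites=18, n_reservoir=1, seed=1)
        res = ReservoirConfig(gamma=1.0, t_left=1.05, t_right=0.95, n_reservoir=1)
        with pytest.raises(TypeError):
            converge_free_length(spec, res)


class TestDisorderEnsemble:
    def test_zero_disorder_degenerates_to_uniform(self):
        res = ReservoirConfig(gamma=0.8, t_left=1.05, t_right=0.95, n_reservoir=2)
        ens = disorder_ensemble(n_free=6, n_reservoir=2, res=res,
                                n_realizations=4, seed=3, delta=0.0)
        uni = solve_steady_state(
            UniformHarmonicSpec(n_sites=10, n_reservoir=2), res)
        assert ens.sem_sigma == pytest.approx(0.0, abs=1e-12)
        assert ens.mean_sigma == pytest.approx(uni.sigma, rel=1e-10)

    def test_bit_identical_reruns(self):
        res = ReservoirConfig(gamma=0.8, t_left=1.05, t_right=0.95, n_reservoir=2)
        a = disorder_ensemble(n_free=6, n_reservoir=2, res=res,
                              n_realizations=5, seed=11)
        b = disorder_ensemble(n_free=6, n_reservoir=2, res=res,
                              n_realizations=5, seed=11)
        assert a.mean_sigma == b.mean_sigma
        assert np.array_equal(a.sigmas, b.sigmas)
        assert a.sem_sigma > 0

    def test_disorder_suppresses_conductance(self):
        """Small version of the plateau-suppression effect."""
        res = ReservoirConfig(gamma=0.5, t_left=1.05, t_right=0.95,
                              n_reservoir=4)
        ens = disorder_ensemble(n_free=30, n_reservoir=4, res=res,
                                n_realizations=10, seed=2, delta=0.3)
        uni = solve_steady_state(
            UniformHarmonicSpec(n_sites=38, n_reservoir=4), res)
        assert ens.mean_sigma < uni.sigma


def test_solution_tables_and_save(tmp_path, uniform12):
    spec, res = uniform12
    sol = solve_steady_state(spec, res)
    site, bond = exact.solution_tables(sol)
    assert list(site.columns) == ["site", "kinetic_temperature"]
    assert list(bond.columns) == ["bond", "current"]
    assert len(site) == spec.n_sites and len(bond) == spec.n_sites - 1
    exact.save_solution(sol, tmp_path)
    assert (tmp_path / "steady_sites.csv").exists()
    assert (tmp_path / "steady.json").exists()


def test_large_gamma_conductance_independent_of_reservoir_size():
    """In the overdamped regime only the reservoir site adjacent to the
    free lattice matters, so curves for different N_r collapse."""
    sig = {}
    for n_r in (1, 4, 16):
        spec = UniformHarmonicSpec(n_sites=16 + 2 * n_r, n_reservoir=n_r)
        res = ReservoirConfig(gamma=50.0, t_left=1.05, t_right=0.95,
                              n_reservoir=n_r)
        sig[n_r] = solve_steady_state(spec, res).sigma
    vals = np.array(list(sig.values()))
    assert np.max(vals) / np.min(vals) < 1.02
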