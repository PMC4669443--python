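"""Stochastic nonequilibrium Langevin dynamics (NEMD) for all lattice families.

Integrates ``m_n x''_n = F_n(x) - gamma_n x'_n + eta_n`` with the
Brünger-Brooks-Karplus (BBK) scheme and accumulates streaming statistics:
per-bond time-averaged heat currents, per-site kinetic temperatures, block
means and the running cumulative current used for the error bar.

BBK variant used here (documented because the discretisation is not unique):

    v+ = v + (dt/2m) [F(x) - gamma v + R]
    x' = x + dt v+
    v' = [v+ + (dt/2m) (F(x') + R)] / (1 + gamma dt/2m)

with one Gaussian random force R per site and step, of standard deviation
``sqrt(2 gamma k_B T / dt)``, applied in both half-kicks
(fluctuation-dissipation: Var(dt R) = 2 gamma k_B T dt).  At
gamma = 0 the scheme reduces to velocity Verlet.  The placement is
validated by the equilibrium oracles (equipartition, zero mean current)
and by agreement with the exact covariance solver.

The instantaneous bond current uses the same convention as the exact
solver: ``j_n = (v_n + v_{n+1})/2 * f_{n->n+1}`` where ``f_{n->n+1}`` is
the force exerted on site n+1 through bond n (for harmonic bonds
``K (x_n - x_{n+1})``; for PBD the nonlinear stacking force).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import fs_to_internal
from .lattices import (
    LatticeSpec,
    PBDSpec,
    ReservoirConfig,
    UnitSystem,
    NATURAL,
)
from .theory import PhononBand

__all__ = [
    "SimConfig",
    "TrajectoryAccumulator",
    "CurrentStats",
    "noise_amplitude",
    "integrate",
    "current_stats",
    "run_current_stats",
]

_FAMILY_HARMONIC = 0
_FAMILY_PBD = 1

#: dt stability guards: dt * omega_max must stay below these.
DT_GUARD_HARMONIC = 0.05
DT_GUARD_PBD = 0.12


@dataclass(frozen=True)
class SimConfig:
    """Integration parameters.

    ``dt`` is in the units of the lattice spec (natural time for harmonic
    runs; internal t0 for PBD physical runs — see ``dt_fs``).  Burn-in
    discards the leading fraction of the run before accumulation.
    """

    dt: float
    n_steps: int
    seed: int = 0
    burn_in: float = 0.5
    n_blocks: int = 10
    n_checkpoints: int = 400

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0.0 <= self.burn_in <= 0.9:
            raise ValueError("burn-in fraction must lie in [0, 0.9]")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        if self.n_steps < 10:
            raise ValueError("n_steps too small")

    @classmethod
    def from_fs(cls, dt_fs: float = 10.0, **kw) -> "SimConfig":
        """Config with the timestep given in femtoseconds (PBD runs)."""
        return cls(dt=fs_to_internal(dt_fs), **kw)


def noise_amplitude(gamma: float, mass: float, temperature: float,
                    dt: float, kB: float = 1.0) -> float:
    """Per-half-step random-force standard deviation, sqrt(2 gamma k_B T/dt).

    Zero for undamped sites (gamma = 0) and at T = 0 (pure damping);
    consistent with the continuous fluctuation-dissipation relation
    ``<eta(t) eta(t')> = 2 gamma k_B T delta(t - t')``.
    """
    if gamma < 0 or mass <= 0 or temperature < 0 or dt <= 0:
        raise ValueError("invalid noise-amplitude arguments")
    return math.sqrt(2.0 * gamma * kB * temperature / dt)


@njit(cache=True)
def _forces(x, family, p, f):
    n = x.shape[0]
    if family == _FAMILY_HARMONIC:
        D = p[0]
        K = p[1]
        for i in range(n):
            left = x[i - 1] if i > 0 else 0.0
            right = x[i + 1] if i < n - 1 else 0.0
            f[i] = -D * x[i] + K * (left - 2.0 * x[i] + right)
    else:
        DM, a, K, rho, b = p[0], p[1], p[2], p[3], p[4]
        for i in range(n):
            ema = math.exp(-a * x[i])
            f[i] = 2.0 * DM * a * ema * (ema - 1.0)
        for i in range(n + 1):           # bonds (i-1, i) with phantoms
            u = x[i] if i < n else 0.0
            v = x[i - 1] if i > 0 else 0.0
            g = rho * math.exp(-b * (u + v))
            d = u - v
            du = -0.5 * K * b * g * d * d + K * (1.0 + g) * d
            if i < n:
                f[i] -= du
            if i > 0:
                f[i - 1] -= (-0.5 * K * b * g * d * d - K * (1.0 + g) * d)


@njit(cache=True)
def _bond_force(xl, xr, family, p):
    """Force on the right site through the bond (xl, xr)."""
    if family == _FAMILY_HARMONIC:
        return p[1] * (xl - xr)
    g = p[3] * math.exp(-p[4] * (xl + xr))
    d = xr - xl
    return -(-0.5 * p[2] * p[4] * g * d * d + p[2] * (1.0 + g) * d)


@njit(cache=True)
def _bbk(x, v, masses, gammas, amps, family, p, dt, n_steps, burn_steps,
         n_blocks, free_lo, free_hi, checkpoint_stride, seed):
    """BBK loop with streaming accumulation.  Returns
    (bond_sum, v2_sum, n_samples, block_sum, block_count, run_means,
     n_checkpoints, nan_step)."""
    np.random.seed(seed)
    n = x.shape[0]
    f = np.zeros(n)
    f_new = np.zeros(n)
    r = np.zeros(n)
    bond_sum = np.zeros(n - 1)
    v2_sum = np.zeros(n)
    x2_sum = np.zeros(n)
    block_sum = np.zeros(n_blocks)
    block_count = np.zeros(n_blocks, dtype=np.int64)
    max_cp = n_steps // checkpoint_stride + 2
    run_means = np.zeros(max_cp)
    cp_steps = np.zeros(max_cp, dtype=np.int64)
    n_cp = 0
    cum_j = 0.0
    n_samples = 0
    post = n_steps - burn_steps
    _forces(x, family, p, f)
    for step in range(n_steps):
        for i in range(n):
            r[i] = amps[i] * np.random.standard_normal() if amps[i] > 0.0 else 0.0
            hdt = 0.5 * dt / masses[i]
            v[i] = v[i] + hdt * (f[i] - gammas[i] * v[i] + r[i])
        for i in range(n):
            x[i] = x[i] + dt * v[i]
        _forces(x, family, p, f_new)
        for i in range(n):
            hdt = 0.5 * dt / masses[i]
            v[i] = (v[i] + hdt * (f_new[i] + r[i])) / (1.0 + gammas[i] * hdt)
            f[i] = f_new[i]
        if step % 1000 == 0 and not math.isfinite(x[0] + v[0] + x[n - 1]):
            return (bond_sum, v2_sum, x2_sum, n_samples, block_sum,
                    block_count, run_means, cp_steps, n_cp, step)
        if step >= burn_steps:
            jfree = 0.0
            for i in range(n - 1):
                j = 0.5 * (v[i] + v[i + 1]) * _bond_force(x[i], x[i + 1], family, p)
                bond_sum[i] += j
                if free_lo <= i <= free_hi:
                    jfree += j
            jfree /= (free_hi - free_lo + 1)
            cum_j += jfree
            for i in range(n):
                v2_sum[i] += v[i] * v[i]
                x2_sum[i] += x[i] * x[i]
            n_samples += 1
            b = (step - burn_steps) * n_blocks // post
            block_sum[b] += jfree
            block_count[b] += 1
            if step % checkpoint_stride == 0:
                run_means[n_cp] = cum_j / n_samples
                cp_steps[n_cp] = step
                n_cp += 1
    return (bond_sum, v2_sum, x2_sum, n_samples, block_sum, block_count,
            run_means, cp_steps, n_cp, -1)


@dataclass(frozen=True)
class TrajectoryAccumulator:
    """Streaming sums from one NEMD run (no full-trajectory storage)."""

    bond_mean: np.ndarray
    v2_mean: np.ndarray
    x2_mean: np.ndarray
    n_samples: int
    block_means: np.ndarray
    running_means: np.ndarray       # cumulative free-current mean at checkpoints
    checkpoint_steps: np.ndarray
    final_x: np.ndarray
    final_v: np.ndarray
    config: SimConfig
    spec: LatticeSpec
    res: ReservoirConfig
    kB: float


def _family_params(spec: LatticeSpec):
    if isinstance(spec, PBDSpec):
        p = np.array([spec.morse_depth, spec.morse_range, spec.stacking_k,
                      spec.stacking_rho, spec.stacking_b])
        return _FAMILY_PBD, p
    return _FAMILY_HARMONIC, np.array([spec.onsite, spec.coupling, 0.0, 0.0, 0.0])


def _dt_guard(spec: LatticeSpec, dt: float) -> None:
    if isinstance(spec, PBDSpec):
        band = PhononBand(onsite=2 * spec.morse_depth * spec.morse_range ** 2,
                          coupling=spec.stacking_k * (1 + spec.stacking_rho),
                          mass=spec.mass)
        guard = DT_GUARD_PBD
    else:
        band = PhononBand(onsite=spec.onsite, coupling=spec.coupling,
                          mass=float(np.min(spec.masses)))
        guard = DT_GUARD_HARMONIC
    if dt * band.omega_max > guard:
        raise ValueError(
            f"dt {dt:g} violates the stability guard "
            f"dt*omega_max <= {guard} (omega_max = {band.omega_max:g})")


def integrate(spec: LatticeSpec, res: ReservoirConfig, cfg: SimConfig,
              units: UnitSystem = NATURAL,
              x0: np.ndarray | None = None,
              v0: np.ndarray | None = None) -> TrajectoryAccumulator:
    """Run BBK Langevin dynamics and accumulate steady-state statistics.

    Damping and noise act only on the L/R reservoir sites; phantom end
    sites are held at zero through the force field.  Bit-for-bit
    reproducible from (cfg.seed, spec, res).
    """
    _dt_guard(spec, cfg.dt)
    if res.n_reservoir != spec.n_reservoir:
        raise ValueError("reservoir sizes of spec and config disagree")
    n = spec.n_sites
    n_r = res.n_reservoir
    masses = spec.masses.astype(float)
    gammas = np.zeros(n)
    gammas[:n_r] = res.gamma
    gammas[n - n_r:] = res.gamma
    temps = np.zeros(n)
    temps[:n_r] = res.t_left
    temps[n - n_r:] = res.t_right
    amps = np.array([noise_amplitude(gammas[i], masses[i], temps[i],
                                     cfg.dt, units.kB) for i in range(n)])
    family, p = _family_params(spec)
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    v = np.zeros(n) if v0 is None else np.array(v0, dtype=float)
    if x.shape != (n,) or v.shape != (n,):
        raise ValueError("initial state has wrong length")
    burn_steps = int(cfg.burn_in * cfg.n_steps)
    free_lo, free_hi = n_r, n - n_r - 2          # bonds between free sites
    if free_hi < free_lo:                        # single free site
        free_lo, free_hi = n_r - 1, n_r
    stride = max(1, cfg.n_steps // cfg.n_checkpoints)
    (bond_sum, v2_sum, x2_sum, n_samples, block_sum, block_count,
     run_means, cp_steps, n_cp, nan_step) = _bbk(
        x, v, masses, gammas, amps, family, p, cfg.dt, cfg.n_steps,
        burn_steps, cfg.n_blocks, free_lo, free_hi, stride,
        cfg.seed % (2 ** 32))
    if nan_step >= 0:
        raise FloatingPointError(f"state became non-finite at step {nan_step}")
    with np.errstate(invalid="ignore"):
        block_means = np.where(block_count > 0, block_sum / block_count, np.nan)
    return TrajectoryAccumulator(
        bond_mean=bond_sum / max(n_samples, 1),
        v2_mean=v2_sum / max(n_samples, 1),
        x2_mean=x2_sum / max(n_samples, 1),
        n_samples=n_samples,
        block_means=block_means,
        running_means=run_means[:n_cp],
        checkpoint_steps=cp_steps[:n_cp],
        final_x=x, final_v=v, config=cfg, spec=spec, res=res, kB=units.kB)


@dataclass(frozen=True)
class CurrentStats:
    """Steady-state current summary with its uncertainty.

    ``sigma_err`` is the larger of (a) the half-range of the cumulative
    running mean over the final 10% of the run and (b) the standard error
    of the block means, both divided by |delta_T|.
    """

    bond_currents: np.ndarray
    free_mean_current: float
    sigma: float | None
    sigma_err: float | None
    current_err: float
    block_means: np.ndarray
    kinetic_temperatures: np.ndarray
    n_samples: int

    @property
    def free_current_err(self) -> float:
        return self.current_err


def current_stats(acc: TrajectoryAccumulator) -> CurrentStats:
    """Reduce an accumulator to currents, conductance and error bars."""
    if acc.n_samples < acc.config.n_blocks:
        raise ValueError("too few post-burn-in samples for block statistics")
    n = acc.spec.n_sites
    n_r = acc.res.n_reservoir
    jbond = acc.bond_mean
    free = jbond[n_r:n - n_r - 1] if n - 2 * n_r >= 2 else jbond[n_r - 1:n - n_r]
    jbar = float(np.mean(free))
    # final-10% fluctuation of the cumulative mean
    cut = int(math.ceil(0.9 * acc.config.n_steps))
    tail = acc.running_means[acc.checkpoint_steps >= cut]
    if len(tail) >= 2:
        tail_err = 0.5 * (float(np.max(tail)) - float(np.min(tail)))
    else:
        tail_err = 0.0
    blocks = acc.block_means[np.isfinite(acc.block_means)]
    block_err = float(np.std(blocks, ddof=1) / math.sqrt(len(blocks)))
    err = max(tail_err, block_err)
    if err == 0.0:
        err = max(abs(jbar) * 1e-12, 1e-300)   # stochastic runs: never exactly 0
    masses = acc.spec.masses.astype(float)
    kin_t = masses * acc.v2_mean / acc.kB
    dT = acc.res.delta_t
    sigma = None if dT == 0 else jbar / dT
    sigma_err = None if dT == 0 else err / abs(dT)
    return CurrentStats(bond_currents=jbond, free_mean_current=jbar,
                        sigma=sigma, sigma_err=sigma_err, current_err=err,
                        block_means=acc.block_means,
                        kinetic_temperatures=kin_t, n_samples=acc.n_samples)


def run_current_stats(spec: LatticeSpec, res: ReservoirConfig, cfg: SimConfig,
                      units: UnitSystem = NATURAL, **kw) -> CurrentStats:
    """Integrate and reduce in one call."""
    return current_stats(integrate(spec, res, cfg, units, **kw))


def thermalized_state(spec: LatticeSpec, temperature: float, seed: int,
                      kB: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Rough thermal initial condition (harmonic equipartition guess)."""
    rng = np.random.default_rng(seed)
    masses = spec.masses.astype(float)
    if isinstance(spec, PBDSpec):
        k_eff = 2 * spec.morse_depth * spec.morse_range ** 2 + 2 * spec.stacking_k
    else:
        k_eff = spec.onsite + 2 * spec.coupling
    x = rng.normal(0.0, math.sqrt(kB * temperature / k_eff), spec.n_sites)
    v = rng.normal(0.0, np.sqrt(kB * temperature / masses), spec.n_sites)
    return x, v
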