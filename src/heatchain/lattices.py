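"""Lattice families, reservoir configuration and unit conventions.

Three one-dimensional lattice families are supported, all with two phantom
boundary sites held at zero displacement:

* a uniform harmonic chain,
  ``H = sum_n p_n^2/2m + (D/2) x_n^2 + (K/2)(x_n - x_{n-1})^2``,
* a mass-disordered harmonic chain (per-site masses drawn uniformly from
  ``m (1 +/- delta)``, same force field as the uniform chain),
* the Peyrard-Bishop-Dauxois (PBD) coarse-grained DNA model, with a Morse
  on-site potential ``V(x) = D_M (exp(-a x) - 1)^2`` for interstrand base
  pairing and the nonlinear stacking coupling
  ``W(x_n, x_{n-1}) = (K/2)(1 + rho exp(-b (x_n + x_{n-1}))) (x_n - x_{n-1})^2``.

Sites are labelled 1..N externally (phantoms are 0 and N+1); internal array
storage is 0-based.  The first/last ``n_reservoir`` sites form the left (L)
and right (R) extended reservoirs, each site coupled to its own independent
Langevin bath; the middle sites form the free lattice (F).

Friction convention
-------------------
The Langevin equation of motion is ``m_n x''_n = -dH/dx_n - gamma x'_n +
eta_n`` with ``<eta_n(t) eta_n(t')> = 2 gamma k_B T_n delta(t-t')``.  The
friction coefficient multiplies the velocity directly, so ``gamma`` carries
units of mass/time and its natural unit is ``sqrt(K m)``.  This is the
convention under which the dimensionless interface parameter
``gamma*omega/2K`` and the weak-coupling conductance ``k_B*Gamma/2m`` take
their standard forms.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .constants import KB_EV_PER_K

__all__ = [
    "UniformHarmonicSpec",
    "MassDisorderedSpec",
    "PBDSpec",
    "ReservoirConfig",
    "UnitSystem",
    "NaturalScales",
    "NATURAL",
    "PHYSICAL_EV_NM_U",
    "LatticeSpec",
    "ForceField",
    "build_force",
    "region_of",
    "is_thermostatted",
    "pbd_harmonic_limit",
    "to_natural_units",
    "from_natural_units",
    "load_spec",
    "save_spec",
    "load_mass_table",
    "save_mass_table",
]


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformHarmonicSpec:
    """Uniform harmonic chain with fixed (zero) phantom end sites.

    Parameters
    ----------
    n_sites:
        Number of dynamical sites N (phantom sites 0 and N+1 excluded).
    n_reservoir:
        Reservoir size N_r per side; the free region has N - 2 N_r sites.
    mass:
        Oscillator mass m (> 0).
    coupling:
        Nearest-neighbour spring constant K (> 0).
    onsite:
        On-site (confining) spring constant D (>= 0).
    """

    n_sites: int
    n_reservoir: int
    mass: float = 1.0
    coupling: float = 1.0
    onsite: float = 1.0

    def __post_init__(self):
        if self.n_reservoir < 1:
            raise ValueError("n_reservoir must be >= 1")
        if self.n_sites - 2 * self.n_reservoir < 1:
            raise ValueError("free region is empty: require N - 2 N_r >= 1")
        if self.mass <= 0 or self.coupling <= 0 or self.onsite < 0:
            raise ValueError("require m > 0, K > 0, D >= 0")

    @property
    def masses(self) -> np.ndarray:
        return np.full(self.n_sites, self.mass)

    @property
    def n_free(self) -> int:
        return self.n_sites - 2 * self.n_reservoir


@dataclass(frozen=True)
class MassDisorderedSpec:
    """Harmonic chain with quenched uniform mass disorder.

    Per-site masses are sampled i.i.d. from the uniform distribution on
    ``[m(1-delta), m(1+delta)]`` whose mean is the base mass ``m``.
    A realization is fully reproducible from ``(seed, realization)``.
    """

    site_masses: np.ndarray
    mass: float
    delta: float
    seed: int
    n_reservoir: int
    coupling: float = 1.0
    onsite: float = 1.0
    realization: int = 0

    def __post_init__(self):
        masses = np.asarray(self.site_masses, dtype=float)
        object.__setattr__(self, "site_masses", masses)
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must lie in [0, 1)")
        if self.mass <= 0 or self.coupling <= 0 or self.onsite < 0:
            raise ValueError("require m > 0, K > 0, D >= 0")
        lo, hi = self.mass * (1 - self.delta), self.mass * (1 + self.delta)
        if masses.min() < lo - 1e-12 * self.mass or masses.max() > hi + 1e-12 * self.mass:
            raise ValueError("site masses fall outside m(1 +/- delta)")
        if self.n_reservoir < 1 or self.n_sites - 2 * self.n_reservoir < 1:
            raise ValueError("invalid reservoir size")

    @classmethod
    def sample(cls, n_sites: int, n_reservoir: int, mass: float = 1.0,
               delta: float = 0.3, coupling: float = 1.0, onsite: float = 1.0,
               seed: int = 0, realization: int = 0) -> "MassDisorderedSpec":
        """Draw one disorder realization, reproducible from (seed, realization)."""
        rng = np.random.default_rng([int(seed), int(realization)])
        masses = mass * rng.uniform(1 - delta, 1 + delta, size=n_sites)
        return cls(site_masses=masses, mass=mass, delta=delta, seed=seed,
                   n_reservoir=n_reservoir, coupling=coupling, onsite=onsite,
                   realization=realization)

    @property
    def n_sites(self) -> int:
        return len(self.site_masses)

    @property
    def masses(self) -> np.ndarray:
        return self.site_masses

    @property
    def coupling_(self) -> float:
        return self.coupling

    @property
    def n_free(self) -> int:
        return self.n_sites - 2 * self.n_reservoir


@dataclass(frozen=True)
class PBDSpec:
    """Peyrard-Bishop-Dauxois DNA lattice.

    ``x_n`` is the base-to-base separation of the n-th base pair.  Defaults
    are the widely used homogeneous parameter set (eV, nm, u): Morse depth
    0.04 eV, Morse range 44.5 nm^-1, stacking constant 6.0 eV/nm^2,
    stacking amplitude 0.5, stacking range 3.5 nm^-1, mass 300 u.  Every
    run should log the full parameter set alongside its results.
    """

    n_sites: int
    n_reservoir: int
    morse_depth: float = 0.04       # D_M, eV
    morse_range: float = 44.5       # a, 1/nm
    stacking_k: float = 6.0         # K, eV/nm^2
    stacking_rho: float = 0.5       # rho, dimensionless
    stacking_b: float = 3.5         # b, 1/nm
    mass: float = 300.0             # m, u

    def __post_init__(self):
        if self.morse_depth <= 0 or self.morse_range <= 0 or self.stacking_k <= 0:
            raise ValueError("require D_M > 0, a > 0, K > 0")
        if self.stacking_rho < 0 or self.stacking_b < 0 or self.mass <= 0:
            raise ValueError("require rho >= 0, b >= 0, m > 0")
        if self.n_reservoir < 1 or self.n_sites - 2 * self.n_reservoir < 1:
            raise ValueError("invalid reservoir size")

    @property
    def masses(self) -> np.ndarray:
        return np.full(self.n_sites, self.mass)

    @property
    def n_free(self) -> int:
        return self.n_sites - 2 * self.n_reservoir


LatticeSpec = Union[UniformHarmonicSpec, MassDisorderedSpec, PBDSpec]


@dataclass(frozen=True)
class ReservoirConfig:
    """Langevin reservoir parameters.

    ``gamma`` is the per-site friction coefficient (mass/time; force
    ``-gamma x'``), applied to the first/last ``n_reservoir`` sites.  The
    conductance denominator is ``delta_T = T_L - T_R``.
    """

    gamma: float
    t_left: float
    t_right: float
    n_reservoir: int

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.t_left < 0 or self.t_right < 0:
            raise ValueError("temperatures must be >= 0")
        if self.n_reservoir < 1:
            raise ValueError("n_reservoir must be >= 1")

    @property
    def delta_t(self) -> float:
        return self.t_left - self.t_right

    @property
    def cumulative_friction(self) -> float:
        """Gamma = N_r * gamma, the cumulative friction per side."""
        return self.n_reservoir * self.gamma


# --------------------------------------------------------------------------
# Units
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSystem:
    """Unit convention: either natural (k_B = m = K = 1) or physical.

    In natural mode a uniform chain is characterised by the dimensionless
    triple (D/K, gamma/sqrt(K m), N_r); frequencies are in sqrt(K/m),
    friction in sqrt(K m) and conductance in k_B sqrt(K/m).
    """

    mode: str = "natural"            # "natural" | "physical"
    kB: float = 1.0

    def __post_init__(self):
        if self.mode not in ("natural", "physical"):
            raise ValueError("mode must be 'natural' or 'physical'")


NATURAL = UnitSystem(mode="natural", kB=1.0)
PHYSICAL_EV_NM_U = UnitSystem(mode="physical", kB=KB_EV_PER_K)


@dataclass(frozen=True)
class NaturalScales:
    """Scale factors mapping a physical parameterization to natural units.

    ``X_physical = X_natural * scale``.  The temperature scale is arbitrary
    for linear dynamics (only k_B*T enters); it is recorded so that the
    round trip is the identity.
    """

    mass: float
    stiffness: float
    temperature: float
    kB: float

    @property
    def frequency(self) -> float:
        return math.sqrt(self.stiffness / self.mass)

    @property
    def time(self) -> float:
        return 1.0 / self.frequency

    @property
    def friction(self) -> float:
        """gamma scale, sqrt(K m)."""
        return math.sqrt(self.stiffness * self.mass)

    @property
    def conductance(self) -> float:
        """sigma scale, k_B sqrt(K/m)."""
        return self.kB * self.frequency


def to_natural_units(spec: UniformHarmonicSpec, res: ReservoirConfig,
                     units: UnitSystem = PHYSICAL_EV_NM_U,
                     ) -> Tuple[UniformHarmonicSpec, ReservoirConfig, NaturalScales]:
    """Rescale a physical uniform chain to k_B = m = K = 1.

    Preserves the dimensionless triple (D/K, gamma/sqrt(K m), N_r); the
    conductance computed in either system agrees after dividing by the
    conductance scale ``k_B sqrt(K/m)``.
    """
    if spec.mass <= 0 or spec.coupling <= 0:
        raise ValueError("scale factors must be positive")
    t_scale = 0.5 * (res.t_left + res.t_right) or 1.0
    scales = NaturalScales(mass=spec.mass, stiffness=spec.coupling,
                           temperature=t_scale, kB=units.kB)
    nat_spec = dataclasses.replace(spec, mass=1.0, coupling=1.0,
                                   onsite=spec.onsite / spec.coupling)
    nat_res = ReservoirConfig(gamma=res.gamma / scales.friction,
                              t_left=res.t_left / t_scale,
                              t_right=res.t_right / t_scale,
                              n_reservoir=res.n_reservoir)
    return nat_spec, nat_res, scales


def from_natural_units(spec: UniformHarmonicSpec, res: ReservoirConfig,
                       scales: NaturalScales,
                       ) -> Tuple[UniformHarmonicSpec, ReservoirConfig]:
    """Inverse of :func:`to_natural_units` (identity round trip)."""
    phys_spec = dataclasses.replace(spec, mass=scales.mass,
                                    coupling=scales.stiffness,
                                    onsite=spec.onsite * scales.stiffness)
    phys_res = ReservoirConfig(gamma=res.gamma * scales.friction,
                               t_left=res.t_left * scales.temperature,
                               t_right=res.t_right * scales.temperature,
                               n_reservoir=res.n_reservoir)
    return phys_spec, phys_res


# --------------------------------------------------------------------------
# Region bookkeeping
# --------------------------------------------------------------------------

def region_of(site_index: int, spec: LatticeSpec,
              res: ReservoirConfig | None = None) -> str:
    """Region label ('L', 'F' or 'R') of a 1-based site index."""
    n_r = res.n_reservoir if res is not None else spec.n_reservoir
    n = spec.n_sites
    if not 1 <= site_index <= n:
        raise IndexError(f"site index {site_index} outside 1..{n}")
    if site_index <= n_r:
        return "L"
    if site_index > n - n_r:
        return "R"
    return "F"


def is_thermostatted(site_index: int, spec: LatticeSpec,
                     res: ReservoirConfig | None = None) -> bool:
    return region_of(site_index, spec, res) in ("L", "R")


# --------------------------------------------------------------------------
# Force fields
# --------------------------------------------------------------------------

class ForceField:
    """Force/energy evaluator: displacements -> (per-site forces, energy).

    Forces are the exact negative gradient of the Hamiltonian's potential
    part, with the phantom boundary sites x_0 = x_{N+1} = 0 included in
    both end bonds.
    """

    def __init__(self, n_sites: int,
                 energy_fn: Callable[[np.ndarray], float],
                 force_fn: Callable[[np.ndarray], np.ndarray]):
        self.n_sites = n_sites
        self._energy = energy_fn
        self._force = force_fn

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_sites,):
            raise ValueError(
                f"displacement vector has shape {x.shape}, expected ({self.n_sites},)")
        return x

    def energy(self, x: np.ndarray) -> float:
        return self._energy(self._check(x))

    def forces(self, x: np.ndarray) -> np.ndarray:
        return self._force(self._check(x))

    def __call__(self, x: np.ndarray) -> Tuple[np.ndarray, float]:
        x = self._check(x)
        return self._force(x), self._energy(x)


def _harmonic_field(spec) -> ForceField:
    n, K, D = spec.n_sites, spec.coupling, spec.onsite

    def energy(x):
        xe = np.concatenate(([0.0], x, [0.0]))
        return 0.5 * D * np.dot(x, x) + 0.5 * K * np.sum(np.diff(xe) ** 2)

    def force(x):
        xe = np.concatenate(([0.0], x, [0.0]))
        return -D * x + K * (xe[2:] - 2 * x + xe[:-2])

    return ForceField(n, energy, force)


def _pbd_field(spec: PBDSpec) -> ForceField:
    n = spec.n_sites
    DM, a = spec.morse_depth, spec.morse_range
    K, rho, b = spec.stacking_k, spec.stacking_rho, spec.stacking_b

    def energy(x):
        xe = np.concatenate(([0.0], x, [0.0]))
        morse = DM * np.sum((np.exp(-a * x) - 1.0) ** 2)
        s = xe[1:] + xe[:-1]
        d = xe[1:] - xe[:-1]
        stack = 0.5 * K * np.sum((1.0 + rho * np.exp(-b * s)) * d * d)
        return morse + stack

    def force(x):
        xe = np.concatenate(([0.0], x, [0.0]))
        ema = np.exp(-a * x)
        f = 2.0 * DM * a * ema * (ema - 1.0)          # -dV_morse/dx
        s = xe[1:] + xe[:-1]
        d = xe[1:] - xe[:-1]
        g = rho * np.exp(-b * s)
        # dW/d(u) for bond (v=left, u=right): K/2 * (-b g d^2) + K (1+g) d
        du = -0.5 * K * b * g * d * d + K * (1.0 + g) * d
        dv = -0.5 * K * b * g * d * d - K * (1.0 + g) * d
        # site n (1-based) is 'u' of bond n-1 and 'v' of bond n
        f -= du[:-1] + dv[1:]
        return f

    return ForceField(n, energy, force)


def build_force(spec: LatticeSpec) -> ForceField:
    """Build the force/energy evaluator for any lattice family."""
    if isinstance(spec, PBDSpec):
        return _pbd_field(spec)
    if isinstance(spec, (UniformHarmonicSpec, MassDisorderedSpec)):
        return _harmonic_field(spec)
    raise TypeError(f"unknown lattice spec type {type(spec)!r}")


# --------------------------------------------------------------------------
# PBD harmonic limits
# --------------------------------------------------------------------------

def pbd_harmonic_limit(spec: PBDSpec, regime: str) -> UniformHarmonicSpec:
    """Harmonic limit of the PBD lattice.

    ``low_T``: quadratic expansion about x = 0 — on-site curvature
    ``2 D_M a^2`` from the Morse potential, bond coupling ``K (1 + rho)``
    from the stacking factor at zero separation.  ``high_T``: the Morse
    plateau contributes nothing (D = 0) and the stacking factor decays,
    leaving bond coupling ``K``.
    """
    if regime == "low_T":
        onsite = 2.0 * spec.morse_depth * spec.morse_range ** 2
        coupling = spec.stacking_k * (1.0 + spec.stacking_rho)
    elif regime == "high_T":
        onsite = 0.0
        coupling = spec.stacking_k
    else:
        raise ValueError("regime must be 'low_T' or 'high_T'")
    return UniformHarmonicSpec(n_sites=spec.n_sites, n_reservoir=spec.n_reservoir,
                               mass=spec.mass, coupling=coupling, onsite=onsite)


# --------------------------------------------------------------------------
# Config I/O — flat key-value spec files and CSV mass tables
# --------------------------------------------------------------------------

def save_spec(path, spec: LatticeSpec, res: ReservoirConfig | None = None,
              units: str = "natural") -> None:
    """Write a flat key-value spec file (YAML)."""
    d: dict = {"units": units}
    if isinstance(spec, UniformHarmonicSpec):
        d.update(family="uniform", n_sites=spec.n_sites, n_reservoir=spec.n_reservoir,
                 mass=spec.mass, coupling=spec.coupling, onsite=spec.onsite)
    elif isinstance(spec, MassDisorderedSpec):
        d.update(family="disordered", n_sites=spec.n_sites, n_reservoir=spec.n_reservoir,
                 mass=spec.mass, delta=spec.delta, seed=spec.seed,
                 realization=spec.realization, coupling=spec.coupling,
                 onsite=spec.onsite)
    elif isinstance(spec, PBDSpec):
        d.update(family="pbd", n_sites=spec.n_sites, n_reservoir=spec.n_reservoir,
                 morse_depth=spec.morse_depth, morse_range=spec.morse_range,
                 stacking_k=spec.stacking_k, stacking_rho=spec.stacking_rho,
                 stacking_b=spec.stacking_b, mass=spec.mass)
    else:
        raise TypeError(type(spec))
    if res is not None:
        d.update(gamma=res.gamma, t_left=res.t_left, t_right=res.t_right)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_spec(path) -> Tuple[LatticeSpec, ReservoirConfig | None, str]:
    """Read a flat key-value spec file; returns (spec, reservoir, units)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    family = d.pop("family")
    units = d.pop("units", "natural")
    res = None
    if "gamma" in d:
        res = ReservoirConfig(gamma=d.pop("gamma"), t_left=d.pop("t_left"),
                              t_right=d.pop("t_right"),
                              n_reservoir=d["n_reservoir"])
    if family == "uniform":
        spec: LatticeSpec = UniformHarmonicSpec(**d)
    elif family == "disordered":
        n = d.pop("n_sites")
        spec = MassDisorderedSpec.sample(n_sites=n, **d)
    elif family == "pbd":
        spec = PBDSpec(**d)
    else:
        raise ValueError(f"unknown family {family!r}")
    return spec, res, units


def save_mass_table(path, spec: MassDisorderedSpec) -> None:
    """CSV mass table with 1-based site labels (columns: site_index, mass)."""
    pd.DataFrame({"site_index": np.arange(1, spec.n_sites + 1),
                  "mass": spec.site_masses}).to_csv(path, index=False)


def load_mass_table(path) -> np.ndarray:
    df = pd.read_csv(path)
    df = df.sort_values("site_index")
    if not np.array_equal(df["site_index"].to_numpy(),
                          np.arange(1, len(df) + 1)):
        raise ValueError("mass table site_index must be contiguous 1..N")
    return df["mass"].to_numpy(dtype=float)
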