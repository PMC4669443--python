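"""Closed-form and quadrature-based conductance theory for uniform chains.

Dispersion ``omega(q) = sqrt((D + 2K(1 - cos q))/m)`` on q in [0, pi], with
band edges ``omega_min = sqrt(D/m)`` and ``omega_max = sqrt((D+4K)/m)`` and
bandwidth ``Omega = omega_max - omega_min``.

Three conductance theories are provided:

* the intrinsic conductance ``sigma_2 = k_B Omega / 2 pi`` — the ballistic
  ceiling set solely by the phonon bandwidth;
* the Casher-Lebowitz conductance for single-site reservoirs (N_r = 1),
  obtained by combining the absorption coefficient of one damped end site
  with its mirror image incoherently (exact for the infinite uniform
  chain; validated against the covariance solver to ~1e-12);
* the interface-scattering conductance, exact in the limit N_r -> infinity,
  built from the reflection amplitude of a plane wave hitting the boundary
  between the frictionless free lattice and a semi-infinite lattice with
  uniform friction.

Plateau tilt.  The small-gamma expansion of the scattering conductance is
``sigma(gamma) = sigma_2 - gamma k_B/(16 m) + O(gamma^(3/2))``.  The
coefficient is universal (independent of D, K and of which band edge
contributes): each band edge reduces to the Fresnel-type step reflection
``A = (u - sqrt(u^2 + i))/(u + sqrt(u^2 + i))`` whose loss integral is
``int_0^inf u R/(1+R) du = pi/32`` exactly, and the frequency scale of the
edge cancels.  See PLATEAU_TILT_COEFF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PhononBand",
    "InterfaceScattering",
    "dispersion",
    "intrinsic_conductance",
    "casher_lebowitz",
    "weak_coupling_conductance",
    "gamma12",
    "reflection",
    "scattering_conductance",
    "large_gamma_coefficient",
    "gamma23",
    "PLATEAU_TILT_COEFF",
]

#: Universal plateau-tilt coefficient: d sigma/d gamma -> -PLATEAU_TILT_COEFF
#: * k_B/m as gamma -> 0 (N_r -> infinity).  Exact value 1/16, from the
#: band-edge integral int u R/(1+R) du = pi/32 at both edges.
PLATEAU_TILT_COEFF = 1.0 / 16.0

_QUAD_ABS_TOL = 1e-12


@dataclass(frozen=True)
class PhononBand:
    """Acoustic-optical band of the uniform chain."""

    onsite: float = 1.0     # D
    coupling: float = 1.0   # K
    mass: float = 1.0       # m

    def __post_init__(self):
        if self.coupling <= 0 or self.mass <= 0 or self.onsite < 0:
            raise ValueError("require K > 0, m > 0, D >= 0")

    @property
    def omega_min(self) -> float:
        return math.sqrt(self.onsite / self.mass)

    @property
    def omega_max(self) -> float:
        return math.sqrt((self.onsite + 4 * self.coupling) / self.mass)

    @property
    def bandwidth(self) -> float:
        """Omega = omega_max - omega_min."""
        return self.omega_max - self.omega_min


def dispersion(q, band: PhononBand):
    """Phonon frequency and group velocity at wavenumber(s) q in [0, pi]."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > np.pi):
        raise ValueError("q must lie in [0, pi]")
    D, K, m = band.onsite, band.coupling, band.mass
    omega = np.sqrt((D + 2 * K * (1 - np.cos(q))) / m)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(omega > 0, K * np.sin(q) / (m * omega), 0.0)
    if q.ndim == 0:
        return float(omega), float(v)
    return omega, v


def intrinsic_conductance(band: PhononBand, kB: float = 1.0) -> float:
    """sigma_2 = k_B Omega / 2 pi, the ballistic ceiling of the free lattice.

    Equivalently ``k_B <v_q> / 2`` with ``<v_q> = (1/pi) int_0^pi v_q dq``
    the band-averaged group velocity.
    """
    return kB * band.bandwidth / (2 * math.pi)


def mean_group_velocity(band: PhononBand) -> float:
    """Band-averaged group velocity, Omega/pi."""
    return band.bandwidth / math.pi


def _q_of_omega(w: float, band: PhononBand) -> float:
    """cos q at frequency w inside the band."""
    D, K, m = band.onsite, band.coupling, band.mass
    return 1.0 - (m * w * w - D) / (2 * K)


def casher_lebowitz(gamma: float, band: PhononBand, kB: float = 1.0) -> float:
    """Conductance of the infinite uniform chain with single-site reservoirs.

    A damped end site absorbs an incident phonon of wavenumber q with
    probability ``a(q) = 4 K gamma w sin q / (K^2 + gamma^2 w^2
    + 2 K gamma w sin q)``; chaining the two contacts through the ballistic
    interior gives the per-mode transmission ``a/(2 - a) = 2 K gamma w
    sin q / (K^2 + gamma^2 w^2)`` and

        sigma_CL = (k_B/2 pi) int dw 2 K gamma w sin q(w) / (K^2 + gamma^2 w^2).

    Limits: sigma_CL -> k_B gamma/2m as gamma -> 0 and sigma_CL ->
    C3/gamma as gamma -> infinity (same C3 as the scattering theory).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    K = band.coupling

    def integrand(w):
        cq = _q_of_omega(w, band)
        sq = math.sqrt(max(0.0, 1.0 - cq * cq))
        return 2 * K * gamma * w * sq / (K * K + gamma * gamma * w * w)

    val, _ = quad(integrand, band.omega_min, band.omega_max,
                  limit=400, epsabs=_QUAD_ABS_TOL, epsrel=1e-12)
    return kB * val / (2 * math.pi)


def weak_coupling_conductance(cumulative_friction: float, mass: float,
                              kB: float = 1.0) -> float:
    """Quasi-equilibrium law sigma_1 = k_B Gamma / 2m, Gamma = N_r gamma.

    Valid when the reservoirs, not the lattice, limit the current: the
    chain equilibrates at the mean temperature and each side exchanges
    heat with its baths at a rate proportional to the cumulative friction.
    """
    if cumulative_friction < 0:
        raise ValueError("cumulative friction must be >= 0")
    return kB * cumulative_friction / (2 * mass)


def gamma12(sigma2: float, n_reservoir: int, mass: float, kB: float = 1.0) -> float:
    """Crossover friction between the reservoir-limited and plateau regimes.

    gamma_12 = 2 m sigma_2 / (k_B N_r): where k_B N_r gamma / 2m reaches
    the intrinsic conductance.  Scales as 1/N_r.
    """
    if n_reservoir < 1:
        raise ValueError("n_reservoir must be >= 1")
    return 2 * mass * sigma2 / (kB * n_reservoir)


@dataclass(frozen=True)
class InterfaceScattering:
    """Plane-wave scattering data at a free/friction interface."""

    q: float
    gamma: float
    q_transmitted: complex   # q', with Im q' > 0 (decay into the friction region)
    amplitude: complex       # reflection amplitude A
    coefficient: float       # R = |A|^2

    def __post_init__(self):
        if not 0 <= self.coefficient <= 1:
            raise ValueError("reflection coefficient outside [0, 1]")


def reflection(q: float, gamma: float, band: PhononBand) -> InterfaceScattering:
    """Reflection of a free-lattice phonon at a semi-infinite friction region.

    The incident/reflected solution in the free region is
    ``x_n = e^{iqn} + A e^{-iqn}`` (times ``e^{-i w t}``) and the
    transmitted solution ``x_n = B e^{iq'n}``, where the complex
    wavevector obeys ``cos q' = cos q - i gamma w / 2K``; the branch with
    Im q' > 0 makes the transmitted wave decay.  Matching the two
    interface-site equations of motion gives

        A = (e^{iq'} - e^{iq}) / (e^{-iq} - e^{iq'}).

    A -> 0 as gamma -> 0, |A| -> 1 as gamma -> infinity, and
    0 < |A| < 1 at finite gamma, largest near the band edges.
    """
    if not 0 < q < math.pi:
        raise ValueError("q must lie strictly inside (0, pi)")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    w, _ = dispersion(q, band)
    K = band.coupling
    z = math.cos(q) - 1j * gamma * w / (2 * K)
    qp = complex(np.emath.arccos(z))
    if qp.imag < 0:
        qp = -qp
    a = (np.exp(1j * qp) - np.exp(1j * q)) / (np.exp(-1j * q) - np.exp(1j * qp))
    r = float(abs(a) ** 2)
    return InterfaceScattering(q=q, gamma=gamma, q_transmitted=qp,
                               amplitude=complex(a), coefficient=min(r, 1.0))


def scattering_conductance(gamma: float, band: PhononBand, kB: float = 1.0) -> float:
    """Conductance in the limit of semi-infinite reservoirs (N_r -> inf).

    Solves the per-mode balance equations — rightward current = emission
    of the left reservoir + reflected share of the leftward current, and
    mirror image — giving a net current ``k_B v_q dT (1-R)/(1+R)`` per
    mode; the Kapitza factor (1-R)/(1+R) is strictly positive and below 1
    at finite gamma.  Integrated over the band:

        sigma = (k_B/2 pi) int_0^pi v_q (1 - R(q))/(1 + R(q)) dq.

    Equals sigma_2 exactly at gamma = 0 and matches the large-gamma
    asymptote C3/gamma of the single-site theory.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        return intrinsic_conductance(band, kB)

    def integrand(q):
        w, v = dispersion(q, band)
        r = reflection(q, gamma, band).coefficient
        return v * (1 - r) / (1 + r)

    # Reflection varies fastest within delta-omega ~ gamma of the band
    # edges, i.e. within delta-q ~ sqrt(gamma omega_edge / K) in wavenumber;
    # hand quadpack breakpoints at 1x and 5x that scale.
    K = band.coupling
    pts = []
    for s in (1.0, 5.0):
        dq_bot = math.sqrt(s * gamma * max(band.omega_min, 0.01 * band.omega_max) / K)
        dq_top = math.sqrt(s * gamma * band.omega_max / K)
        if dq_bot < math.pi:
            pts.append(dq_bot)
        if dq_top < math.pi:
            pts.append(math.pi - dq_top)
    val, err = quad(integrand, 0.0, math.pi, points=sorted(set(pts)) or None,
                    limit=500, epsabs=_QUAD_ABS_TOL, epsrel=1e-12)
    if err > max(_QUAD_ABS_TOL * 100, 1e-8 * abs(val)):
        raise RuntimeError(f"quadrature error estimate {err:.2e} too large")
    return kB * val / (2 * math.pi)


def large_gamma_coefficient(band: PhononBand, kB: float = 1.0) -> float:
    """Closed form of C3 = lim_{gamma->inf} gamma * sigma(gamma).

    Both the single-site and the scattering theories decay as C3/gamma with
    C3 = (k_B/4) (D + 2K - sqrt(D (D + 4K))).
    """
    D, K = band.onsite, band.coupling
    return 0.25 * kB * (D + 2 * K - math.sqrt(D * (D + 4 * K)))


def gamma23(band: PhononBand, kB: float = 1.0,
            probe: tuple[float, float] = (1e2, 1e4), n_probe: int = 5,
            rtol: float = 1e-3) -> float:
    """Crossover friction between the plateau and the overdamped regime.

    Extracts C3 = lim gamma*sigma numerically from the scattering
    conductance on a log-spaced probe grid (in units sqrt(K m)) and
    returns gamma_23 = C3/sigma_2 — independent of N_r by construction.
    """
    scale = math.sqrt(band.coupling * band.mass)
    gammas = np.geomspace(probe[0] * scale, probe[1] * scale, n_probe)
    products = np.array([g * scattering_conductance(g, band, kB) for g in gammas])
    if abs(products[-1] - products[-2]) > rtol * abs(products[-1]):
        raise RuntimeError(
            "gamma*sigma has not reached its asymptote on the probe grid; "
            "widen the probe range")
    c3 = float(products[-1])
    return c3 / intrinsic_conductance(band, kB)
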