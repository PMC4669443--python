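# Methods

## Model and conventions

All lattices are chains of `N` dynamical sites with two phantom boundary
sites (indices 0 and `N+1`) fixed at zero displacement; site labels are
1-based in all I/O.  The Langevin equation of motion is

    m_n ẍ_n = −∂H/∂x_n − γ_n ẋ_n + η_n,
    ⟨η_n(t) η_m(t′)⟩ = 2 γ_n k_B T_n δ_nm δ(t − t′),

with `γ_n = γ` on the `N_r` leftmost/rightmost sites (temperatures `T_L`,
`T_R`) and zero on the free region.  Note the friction coefficient
multiplies the velocity directly, so `γ` carries units of mass/time and its
natural unit is `√(Km)`.  This convention — rather than a rate `γ̃ = γ/m`
multiplying `m ẋ` — is forced by dimensional consistency of the quantities
the theory produces: the interface parameter `γω/2K` is dimensionless, the
weak-coupling law is `k_B Γ/2m`, and `γ₁₂ = 2mσ₂/k_B N_r` has mass/time
units.  Natural units set `k_B = m = K = 1`; a uniform chain is then fully
characterised by `(D/K, γ/√(Km), N_r)` (the similarity class, verified to
1e−10 in the tests by solving randomly scaled physical parameterizations).
Physical PBD runs use (eV, nm, u, K) with the implied time unit
`t₀ = √(u·nm²/eV) ≈ 101.805 fs` and `k_B = 8.617333262e−5 eV/K`.

Bond-current convention: the literature formula behind the steady-state
current is any bilinear satisfying free-region continuity; we use the
symmetric estimator `J_{n→n+1} = ⟨½(ẋ_n + ẋ_{n+1}) f_{n→n+1}⟩` with
`f_{n→n+1}` the force the bond exerts on site n+1 (`K(x_n − x_{n+1})` for
harmonic bonds, the nonlinear stacking force for PBD).  Sign and
normalisation are pinned by two independent checks: σ > 0 for `T_L > T_R`,
and the net thermostat power entering at L equals the transmitted current
equals the power leaving at R (asserted to 1e−9 relative).

## Exact harmonic steady states

For harmonic (uniform or mass-disordered) chains the dynamics is linear in
`z = (x, p)` and the stationary covariance solves `AC + CAᵀ + Q = 0` with
`Q = diag(0, 2γ_n k_B T_n)`.  We solve it densely (Bartels–Stewart via
`scipy.linalg.solve_continuous_lyapunov`) and require a relative residual
`‖AC + CAᵀ + Q‖ / (2‖A‖‖C‖ + ‖Q‖) ≤ 1e−10`; near-conservative drifts at
very small γ trigger scipy's benign perturbation warning, which we
suppress because the residual check is authoritative.  γ = 0 has no
stationary state and raises.  The dense solve is comfortable to `N ≈ 500`
(state dimension 1000), far beyond what any study here needs.

Free-length extrapolation doubles the free region from 16 (cap 4096) until
successive conductances agree to a relative tolerance.  Empirically the
uniform chain is free-length independent to ~1e−11 at `L ≥ 16` — transport
is ballistic and the two contacts combine without any resonant length
dependence surviving the band integral — so the doubling terminates after
one step.  Disordered chains are refused here (their mean free path makes
σ length-dependent); they are instead ensemble-averaged at fixed length,
with masses drawn uniformly from `m(1 ± δ)`, `δ = 0.3` by default, each
realization reproducible from `(seed, realization)`.

## Closed-form theory

Dispersion `ω(q) = √((D + 2K(1 − cos q))/m)` on `q ∈ [0, π]`; intrinsic
conductance `σ₂ = k_B Ω/2π` with `Ω` the bandwidth — the ballistic ceiling
of the free lattice.

**Single-site reservoirs.**  Plane-wave matching at a damped end site gives
the absorption probability
`a(q) = 4Kγω sin q / (K² + γ²ω² + 2Kγω sin q)`; chaining the two contacts
through the ballistic interior (`T_tot = a/(2 − a)`) and integrating over
the band yields

    σ_CL = (k_B/2π) ∫ dω 2Kγω sin q(ω) / (K² + γ²ω²).

Its small-γ limit is exactly `k_B γ/2m` and its large-γ limit `C₃/γ`.  The
formula agrees with the covariance solver at `N_r = 1` to ~1e−12 across
six decades of γ, i.e. it is exact for the infinite uniform chain, which
is the validation the implementation requires before use.

**Interface scattering (`N_r → ∞`).**  A phonon in the free lattice
hitting a semi-infinite region of uniform friction is reflected with
amplitude `A = (e^{iq′} − e^{iq})/(e^{−iq} − e^{iq′})`, where
`cos q′ = cos q − iγω/2K` and the branch with `Im q′ > 0` makes the
transmitted wave decay.  Per-mode balance equations (emission `(1−R)k_BTv`
per reservoir plus reflected counter-current) give the net current
`k_B v_q ΔT (1−R)/(1+R)`, hence

    σ(γ) = (k_B/2π) ∫₀^π v_q (1 − R)/(1 + R) dq.

Quadrature uses adaptive QUADPACK with breakpoints at the band-edge
layers `|ω − ω_edge| ≲ 5γ` (absolute tolerance 1e−12).  This integral
reproduces the exact `N_r = 100` solver to ~1e−13 relative for
`γ ≳ 0.1 √(Km)` — the two routes are implemented independently, so this
agreement validates both.

**Plateau tilt.**  Expanding near γ = 0, each band edge reduces to the
Fresnel-type step reflection `A = (u − √(u² + i))/(u + √(u² + i))` in the
scaled variable `u = q/√(2ε)`, `ε = γω_edge/2K`.  The loss integral
`∫₀^∞ u·R/(1+R) du = π/32` exactly, the edge frequency cancels, and both
edges contribute equally, giving the universal slope

    dσ/dγ |_{γ→0} = −k_B/16m  (≈ −0.0625 in natural units),

independent of D and K (verified numerically to 0.5% for D/K ∈
{1/4, 1, 4}).  A value of `−πk_B/48m ≈ −0.0654` is often quoted for this
tilt; that number is what an ordinary linear fit over the *finite-γ*
plateau produces (our 29-point plateau fit gives −0.0708, within 10% of
−π/48, because the `O(γ^{3/2})` corrections steepen the fit), but it is
not the γ → 0 derivative of the scattering integral.  The package exposes
the exact coefficient as `theory.PLATEAU_TILT_COEFF = 1/16`; the plateau
*fit* tests compare against −π/48.

**Crossovers.**  `γ₁₂ = 2mσ₂/(k_B N_r)`.  `γ₂₃ = C₃/σ₂`, with `C₃ = lim
γσ(γ)` extracted from a log-spaced probe grid `γ ∈ [10², 10⁴]√(Km)` and
cross-checked against the closed form `C₃ = (k_B/4)(D + 2K − √(D(D+4K)))`
(the large-γ expansions of the single-site and scattering theories
coincide analytically).

## Stochastic integrator

BBK discretisation, one Gaussian random force per site and step
(`sd = √(2γk_BT/dt)`) applied in both half-kicks:

    v⁺ = v + (dt/2m)(F(x) − γv + R);  x′ = x + dt·v⁺;
    v′ = (v⁺ + (dt/2m)(F(x′) + R)) / (1 + γdt/2m).

At γ = 0 this is velocity Verlet (energy drift ≤ 1e−4 over 1e5 steps in
the tests).  The scheme's stationary velocity variance is h-exact for a
free damped particle (`h = γdt/2m`), and equilibrium equipartition and
`⟨x²⟩` match the covariance solver to the few-percent sampling error.
Stability guards: `dt·ω_max ≤ 0.05` for harmonic runs, `≤ 0.12` for PBD
(the conventional 10 fs step at the PBD parameters has `dt·ω_max ≈ 0.08`).
Calibration against the exact solver shows the current estimate acquires a
friction-dependent distortion growing to ~11% at `h = 0.6`; study points
keep `h ≤ 0.5`.

Accumulation is streaming (per-bond current sums, per-site `v²` and `x²`,
block means, cumulative running mean at ~400 checkpoints); no trajectory
is stored.  The error bar is the larger of the block-mean standard error
(10 blocks) and the half-range of the cumulative running mean over the
final 10% of the run.  Near the friction extremes the current correlation
time (`m/γ` at weak coupling; the dwell time of the nearly decoupled free
lattice at strong coupling) exceeds the block length and single-run errors
undershoot by ~2×; multi-seed replicas with seed-spread errors
(`experiments.replicated_nemd_sigma`) are used wherever error bars feed a
quantitative comparison.  Initial states are harmonic-equipartition
thermal draws; cold starts leave the weakly coupled free lattice
un-thermalized for ~1e6 steps at large γ.  Runs are bit-reproducible from
`(SimConfig, seed)`.

## PBD study conditions

PBD defaults are the standard homogeneous parameter set: Morse depth
0.04 eV, Morse range 44.5 nm⁻¹, stacking constant 6.0 eV/nm², stacking
amplitude ρ = 0.5, stacking range 3.5 nm⁻¹, mass 300 u; timestep 10 fs;
reservoir ΔT = 9.3 K.  The Morse depth and stacking constant are the
community-standard companion values to the printed ranges; every run
serialises the full parameter set in its manifest.  Harmonic limits:
low-T `D = 2D_M a², K_eff = K(1+ρ)`; high-T `D = 0, K_eff = K`.

The three-regime crossover study runs at mean temperature 10 K on an
`N = 60, N_r = 20` lattice (the full-scale production curves in the
literature use 0.1–2 ms trajectories, ~10⁷–10⁸ steps, to resolve the
strongly anharmonic regime at ≥ 100 K; at 10 K the signal-to-noise of
CI-scale runs is adequate and the lattice is still genuinely anharmonic).
Regime pairs are theory-anchored: a pilot run at the harmonic plateau
center measures the plateau conductance `σ_pl`, from which
`γ₁₂^eff = 2mσ_pl/(k_B N_r)` locates the weak-coupling crossover (the
crossover tracks the temperature-dependent intrinsic conductance); slopes
are then measured at `{0.015, 0.075}γ₁₂^eff` (regime 1), the plateau
center ×1.4^{±1} (regime 2) and `{8, 16}γ₂₃` (regime 3), with 3–4 seed
replicas per point.  The low-temperature harmonic-limit match runs at
`T̄ = 5 K, ΔT = 4 K` (`k_BT/D_M ≈ 0.01`); by `T̄ ≈ 15 K` the lattice is
measurably anharmonic and the match degrades, which is the physics, not a
solver defect.  The temperature-trend check (plateau conductance rising
across the denaturation region) uses a small `N = 16` lattice at 150, 300
and 450 K, where denaturation-bubble heterogeneity demands multi-seed
averaging.

## What the tests do and do not show

The synthetic studies cover homogeneous and mass-disordered harmonic
chains and the homogeneous PBD model with uncorrelated single-site
reservoirs and white (memoryless) friction.  They do not probe
sequence-dependent PBD parameterizations, bond disorder, correlated or
frequency-dependent (memory-kernel) baths, higher-dimensional lattices, or
the millisecond-scale trajectories needed for converged PBD conductances
deep in the anharmonic/denaturation regime.  Agreement of NEMD with the
exact solver is demonstrated at 3-combined-standard-error level on small
lattices; it bounds integrator correctness, not the statistical quality of
any particular production run.

## Numerical choices

* Lyapunov residual tolerance 1e−10 (relative, backward-error scale);
  site-temperature bounds slack 1e−9.
* Scattering quadrature: QUADPACK, abs. tol. 1e−12, band-edge breakpoints.
* Branch of `q′`: principal `arccos`, negated if `Im q′ < 0`.
* Free-length doubling: start 16, cap 4096, default tolerance 1e−6.
* Regime classification: 5-point windowed log-log slopes; labels switch at
  slope ±1/2 (midpoint crossings); strict plateau `|slope| ≤ 0.15`; grids
  must span ≥ 4 decades.
* Disorder ensembles default to 200 realizations with SEM reporting.
* Burn-in defaults to 50% of a run (25% in the replicated studies, which
  start warm); 10 blocks.

One further discretisation note: the NEMD current estimator carries a
small O(dt) bias for the PBD force field (≈ −2.5% per 5 fs at these
parameters); the low-temperature harmonic-limit comparison therefore runs
at 5 fs, while production PBD scans keep the conventional 10 fs step,
whose bias is negligible against their statistical errors and cancels in
log-log slope pairs.
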