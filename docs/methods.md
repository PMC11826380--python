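# Methods

## Model

The tissue occupies a box Ω = (0, c) × (−a/2, a/2) × (−b/2, b/2) and is a
fluid-saturated porous solid with incompressible constituents, so the
quasi-static Biot system reduces to

    −μₑΔu − (λₑ + μₑ)∇(∇·u) + ∇p = F,
    ∂t(∇·u) − ∇·(k∇p) = S,

with total stress T = 2μₑE(u) + λₑ(∇·u)I − pI and discharge velocity
v = −k∇p.  Inertia is dropped (biological tissues), and the storage term
vanishes because solid and fluid phases are individually incompressible
(c₀ = 0, α = 1): every volume change of the skeleton is fluid exchange.

The circulation surrounding the sample is a lumped RCL hydraulic circuit
with state y = (π, Π₁…Π_nC, Q₁…Q_nL) and dynamics dy/dt = Ay + s(t) + bQ,
b = e₁/C.  The concrete instance used in all presets is the three-state
series circuit R̄ → C₁ → R₁ → L₁ → connecting node, with a grounded
connection capacitor C and a pressure source p̄(t) behind R̄.  Its energy
is ½yᵀUy with U = diag(C, C₁, L₁) and its dissipation the quadratic form
yᵀBy, B = −UA.  For this instance yᵀBy = Π₁²/R̄ + R₁Q₁²; the form is
positive *semi*definite (it vanishes on pure-π states), and the
implementation asserts semidefiniteness, not strict definiteness.

Boundary faces carry one of: traction (Tn = g, v·n = 0), clamped/drained
(u = 0, p = 0), clamped with prescribed discharge (u = 0, v·n = ψ), or
free-slip/impermeable (u·n = 0, zero tangential traction, v·n = 0).  The
interface Σ is always the face x = c, with u = 0 and one of the two
pressure couplings:

* PPC: p ≡ P(t) on Σ, Q = ∫_Σ v·n, Q = (P − π)/R;
* IPC: K v·n = p − π with K = R·mΣ (mΣ = ab), P = Σ-mean of p.

In 1D the two coincide: the Σ-mean of a point is the point.

## Discretization

**Time.** Backward Euler throughout, one linear solve per step.  The
π-ODE of the connection (π' = Q/C) is discretized jointly with the Biot
step, never sub-stepped.  For IPC, eliminating π_{n+1} analytically turns
the interface condition into the Robin-type boundary condition

    K v·n − p + [Δt/(RC+Δt)]·(1/mΣ)∫_Σ p = −[RC/(RC+Δt)]·π_n,

implemented as a Robin boundary term plus a rank-one nonlocal mean term.

**Space.** Equal-order conforming Q1–Q1 trilinear hexahedra on the
structured box grid (P1 elements in 1D, with all integrals carrying the
cross-section factor ab so energies and fluxes match the 3D box exactly).
The decisive property of the tensor-product pair on this geometry: x-only
data produce a *discrete* solution that is exactly one-dimensional, so
the interface-uniformity statements under 1D-conducive forcing hold at
machine precision rather than at O(h²) discretization error.  All element
integrals use 2×2(×2) Gauss quadrature, which is exact for these
polynomial degrees on axis-aligned bricks; smooth forcing data are
interpolated nodally and integrated with consistent mass matrices
(second-order accurate, matching the element order).

Equal-order pairs are not inf-sup stable in the vanishing-Darcy limit
k·Δt → 0; in the regimes treated here (k·Δt ≈ 2·10⁻² and larger) the
pressure-Laplacian block controls the pressure and no stabilization is
needed.  A Brezzi–Pitkäranta-type term is nevertheless available
(`stabilization` parameter, default 0): it adds δ·h² to the effective
permeability, i.e. acts as a consistent permeability perturbation and
preserves every energy identity with k replaced by k + δh².

**Interface enforcement.**

* PPC by static condensation: every Σ pressure unknown is identified with
  the single scalar P (exact constraint, no penalty parameter).  The
  condensed test function is 1 on Σ, so the natural boundary term becomes
  the flux Q, closed by Ohm's law and the BE π-update:
  Q = (P − π_n)/(R + Δt/C).  Interface flatness is exact by construction.
* IPC as a bordered sparse system: one extra unknown P with the defining
  row mΣ·P = ∫_Σ p, the Robin mass matrix (Δt/K)·M_Σ on the pressure
  block, and the rank-one column coupling to P.  Recovery:
  π_{n+1} = (RCπ_n + ΔtP)/(RC + Δt), Q = (P − π_{n+1})/R.

Both variants yield a time-independent reduced matrix per (variant, Δt),
factorized once (sparse LU) and reused across all steps.

**Flux and the Ohm residual.**  The steppers recover Q from Ohm's law.
An independent arithmetic path — summing the residuals of the uncoupled
mass-equation rows over the Σ trace functions (the discretely consistent
boundary flux) — is evaluated every step; the two agree analytically, so
their per-step difference (`ohm_residual` in the time series) measures
pure linear-solver roundoff, observed at ~10⁻¹⁸ m³/s.  The
`interface_statistics` helper additionally offers the direct boundary
quadrature of −k∂p/∂x, which is only first-order accurate and is meant
for reporting, not for the residual check.

## Operator splitting and stability

Each step: (1) Biot + connection (updates u, p, P, Q and π, freezing the
internal circuit states), then (2) the full circuit ODE y' = Ay + s(t)
from the half-updated state, freezing u and p.  No sub-iterations.  Both
substeps dissipate their energies under backward Euler, so the total
discrete energy is non-increasing without forcing *for every Δt* — the
test suite exercises Δt from 10⁻⁴ s to 10 s.  The substep order may be
swapped (circuit first); both orderings are stable and agree to O(Δt).

The Step-1 discrete energy identity is tracked exactly: with the BE
defect terms ½ΔuᵀA_eΔu/Δt and (C/2)(π₁−π₀)²/Δt written out, the substep
satisfies an identity whose residual (`step1_residual`) is pure solver
roundoff (~10⁻¹⁷ in the reference runs).  The whole-scheme audit
(`audit_energy_identity`) uses backward differences matched to the BE
nodes and reports residual = work − ΔE/Δt − ΣD, which is the nonnegative
numerical-dissipation defect: zero on the zero trajectory, O(Δt) under
smooth forcing (halving Δt halves it).

## PQP fixed-point iteration and its pathology

Within each step the partitioned alternative iterates: Dirichlet solve
with the full pressure trace p|_Σ = P_j, consistent flux Q_{j+1}, circuit
BE update driven by Q_{j+1}, then P_{j+1} = π_{j+1} + R·Q_{j+1}.  The map
P_j → P_{j+1} is affine (the problem is linear), so its contraction
factor is a number γ₂(Δt); the driver estimates it from consecutive
increments (γ̂₂) and reports per-step iteration counts, convergence flags
and a blow-up flag (overflow guard 10¹², default tolerance 10⁻¹⁰ on
|ΔP|, max 100 iterations — chosen as ordinary fixed-point practice).
The Dirichlet inner solve uses the full-trace condition for both
variants; applying it to IPC inputs is a diagnostic extension, not the
IPC discretization.

Mechanism of divergence: over one step the flux response of the Biot
solve to the boundary pressure scales like the storage compliance divided
by Δt (the pressure perturbation penetrates a diffusion layer
√(k·H_A·Δt)), so γ₂ ∼ (R + Δt/C)·mΣ·√(k/(H_A·Δt)) grows without bound as
Δt → 0 and proportionally with R.  Empirically, at the reference
parameters γ̂₂ crosses 1 near Δt ≈ 10⁻⁴ s; with R = 100 and k = 10⁻³ the
crossing moves to Δt ≈ 10⁻³ s and the iterates overflow the guard at
Δt = 10⁻⁴ s, while the splitting scheme on the identical problem keeps
the energy bounded.  The demonstrated phenomenon is the loss of
contractivity itself; the exact crossing value depends on the full
parameter vector and is not a portable constant.

## Study presets and what they emulate

* `test71` — 1D-conducive forcing on the reference box: circuit source
  p̄(t) = A·sin(0.2πt), A auto-scaled by linearity (one cheap unit-
  amplitude 1D–0D run) so the peak interface pressure is ≈ 0.1 Pa; no
  traction (g = 0).  The concrete source behind the published magnitude
  is not pinned down, so the preset fixes the scale, which is what the
  uniformity statements are relative to.  Mesh 20×6×6 hexahedra (720
  cells, ~4100 unknowns), Δt = 0.02 s, T = 10 s.
* `test72` — truly 3D forcing: prescribed normal discharge
  ψ = −0.2·cos(10πy)cos(10πz)(1 + 0.5cos(0.2πt)) on x = 0 and
  ψ = 0.2·e^(−1000((x−0.45)²+z²))(1 − 0.5sin(0.3πt)) on y = −0.05, both
  faces clamped; remaining lateral faces free-slip/impermeable; the same
  circuit with p̄ = 0.  Mesh 24×8×8 (1536 cells), chosen so the Gaussian
  spot (σ ≈ 0.02 m) and the transverse cosine are resolved.
* `steady1d` — constant (g, p̄) on the 1D column; the coupled system has
  the closed-form rest state p = π = π₁ = p̄, Q = Q₁ = 0, T = g,
  u(x) = (g+p̄)/H_A·(x−c), which the discrete scheme reproduces exactly
  (constant pressure and linear displacement lie in the FE spaces), so
  time stepping converges to it geometrically.

The reference material split is λₑ = 0.5, μₑ = 0.25 (H_A = λₑ + 2μₑ = 1
Pa).  One-dimensional dynamics depend on λₑ, μₑ only through H_A; the
split affects solely how the elastic energy decomposes, and any split
with H_A = 1 would serve.

These synthetic studies exercise the coupling, not tissue realism: the
domain is a box with a single flat interface, parameters are homogeneous
and isotropic and of unit scale rather than physiological, the circuit
has three states, and the solid is clamped (u = 0) at the interface.
Passing them shows the interface mechanics, energy structure and
stability of the schemes — not predictive accuracy for any organ.

## Numerical choices and tolerances

* Circuit exact solver: variation-of-constants with forcing treated as
  piecewise constant on a uniform micro-grid (default 10⁴ subintervals,
  midpoint sampling), each piece propagated exactly via the augmented
  matrix exponential (valid for singular A).  Oracle error O(h²) sits far
  below the O(Δt) backward Euler errors it referees; the convergence
  study uses T = 2 s, Δt = 0.04 s halved four times.
* Equality-type assertions in the test suite use relative tolerances
  10⁻¹⁰–10⁻¹² (solver roundoff), dissipation nonnegativity allows −10⁻¹⁵
  absolute slack, and passivity −10⁻¹² relative to ‖B‖.
* Degenerate inputs rejected with messages naming the offending field:
  nonpositive moduli/permeability/circuit elements, non-divisible time
  grids, interfaces on faces other than x = c, mismatched connection
  capacitance between circuit and coupling blocks.
* Deterministic throughout — no randomness anywhere in the solvers;
  reruns of the same configuration are bitwise identical.  Test-suite and
  acceptance problem sizes (meshes of 10²–10³ cells, 1D columns of 16–64
  cells, 10–500 steps) are the package's reference sizes; all studies
  run in seconds on one core.

## Limitations

* Box domains with one flat interface only; no unstructured meshes,
  multiple interfaces, or elastic interface conditions other than u = 0.
* Quasi-static, incompressible-constituent regime only (no inertia, no
  c₀ > 0, α fixed at 1), linear constitutive laws, linear time-invariant
  circuit elements; the general circuit topology is accepted as raw
  (A, U, s) data, not compiled from a netlist.
* Equal-order Q1–Q1 requires the pressure block to be controlled by
  k·Δt (or the optional stabilization) — very small k·Δt with δ = 0 can
  produce spurious pressure modes.
* First-order time accuracy by design; no adaptivity.  The closed-form
  contraction coefficients of the PQP map are not computed, only their
  empirical estimate γ̂₂.
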