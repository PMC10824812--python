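# Methods

## Model and assumptions

The simulator realises a measure-valued birth–death–interaction process for
DNA lesions in a bounded convex nucleus Q ⊂ ℝ^d (d = 2 or 3; the default
scenario uses a disk of radius 5 μm).  Lesions carry a mark: X (sub-lethal,
repairable) or Y (lethal, inert).  Four channels act on the configuration:

| channel | stoichiometry | rate |
|---|---|---|
| repair | X → ∅ | r(q, v) per lesion |
| death | X → Y | a(q, v) per lesion |
| pair | X + X → Y (prob. p) or ∅ (prob. 1 − p) | b(q₁, q₂) per unordered pair |
| dose | ∅ → ξ^X X + ξ^Y Y | ḋ events/h on [0, T_irr] |

v = ⟨Γ_q, ν⟩ is a kernel-weighted local count of *other* lesions (the focal
lesion is excluded by default; counting it, and restricting the counted
marks, are configurable).  Assumptions inherited from the underlying
theory: rates are nonnegative and bounded on bounded configurations,
p(q₁, q₂) ∈ [0, 1], pair rates are symmetric, placement measures are
probability measures on Q, and lesion motions are independent reflected
diffusions with Lipschitz (here constant) coefficients.

Y lesions never react; survival is the probability of zero Y.  Lesions of
the same type are exchangeable — the integer ids carried by the
implementation are bookkeeping only and never enter a rate.

## Parameters

All lengths are μm, times hours, doses Gy, rates h⁻¹.

* `r0 = 4`, `a0 = 0.1`, `b0 = 0.1`, `r_d = 0.5 μm`, `p = 1` — the
  reference kinetic set (`preset_carbon_10gy`).  Crowding forms
  `r = r0(1 + 1/(v+1))` ∈ [r0, 2r0] and `a = a0(1 − 1/(v+1))` ∈ [0, a0];
  the `+1` in the denominator also guards the v = 0 case given the
  excluded-focal convention.
* Pair forms: `constant` (distance-independent — the homogeneous reduction
  used in cross-model checks), `step` (b0 inside r_d, strict inequality),
  `gaussian` and `double_gaussian` (amplitudes `pair_b1`, `pair_b2`,
  widths `pair_eps_um`, `pair_eps2_um`; the two-Gaussian sum models an
  enhanced short-range core with a fatter tail).
* Placement: death in place (Dirac) by default, or uniform/bell-shaped in
  a ball of radius ε re-drawn until inside Q (truncation renormalises the
  density); pair-lethal placement on the segment between the reactants —
  midpoint by default, endpoints, discrete α-mixtures, or uniform α.
* Microdosimetry: `D = 10 Gy`, `z_F = 0.04 Gy` (mean traversal count
  D/z_F = 250), yields `κ = 50 Gy⁻¹`, `λ = κ/100`.  f₁ defaults to a
  gamma spectrum of shape 1 (exponential-like) with mean z_F; a delta
  spectrum is used where analytic moments are wanted, and tabulated
  two-column spectra are accepted.
* Amorphous track: `R_c = 0.01 μm`, `R_p = 1 μm` are package defaults for
  low-energy carbon ions — the radial *shape* is all that matters for
  placement, so the core/penumbra amplitudes are fixed by continuity at
  R_c plus unit mass on the R_p disc.  The lesion-offset density is
  ∝ D(ρ)ρ, sampled by inverse CDF (quadratic in the core, logarithmic in
  the penumbra); the analytic core mass is 0.5/(0.5 + ln(R_p/R_c)).
* Protraction: ḋ = D/(T_irr·z_F) events/h; each event is one traversal
  sampled exactly as in the instantaneous generator, making the expected
  total damage κ·D independent of T_irr.
* Diffusion: σ = μ = 0 by default — no diffusion parameters are part of
  the reference scenario, so lesions are static there.

## Numerical scheme

Jumps are scheduled by exponential clocks: channel h fires when its
integrated total ∫h̄ ds crosses an Exp(1) threshold; after any jump all
clocks are redrawn (valid by memorylessness).  Two execution paths:

* **Static** (σ = μ = 0): positions never change between jumps, so channel
  totals are exactly constant there and the event-to-event construction is
  exact — no time discretisation enters the law.  The `dt` parameter is
  then irrelevant, which is precisely what the dt-robustness check
  verifies.  Rate bookkeeping is incremental: neighbour sets within r_d
  are built once with a k-d tree and updated per event in O(degree), so a
  500-lesion reference run costs ~20 ms.  Kernels outside the supported
  family (non-ball kernels, Gaussian pair forms) fall back to a full
  O(N²) recompute per event, which is still exact for static lesions.
* **Diffusive**: reflected Euler–Maruyama steps of length `dt`
  (default 10⁻³ h) with rates frozen over each step and hazards
  accumulated against the thresholds; firing times are located by linear
  interpolation within the step.  First-order in dt, exact when rates are
  position-independent.  Reflection is the radial mirror |q| ↦ 2R − |q|,
  exact for radial overshoot and first-order for general Euler steps.

Event placement uses the step-start (frozen) positions.  The RNG is split
into independent sub-streams for dose sampling, reaction sampling and
diffusion so that enabling snapshots or diffusion cannot perturb the event
stream; identical seed and configuration give bit-identical trajectories.

Pair-counting convention: the simulator sums b over unordered pairs
i₁ < i₂ (total b0·N(N−1)/2 for a constant rate).  The master equation and
mean-field ODEs use the ordered-pair propensity β·x(x−1), so every
cross-model comparison applies β = b0/2 explicitly — never silently inside
a solver.

## Reference models

* **Master equation**: the truncated (y, x) lattice with transitions
  (y,x)→(y,x−1) at rx, →(y+1,x−1) at ax, →(y+1,x−2) at pβx(x−1) and
  →(y,x−2) at (1−p)βx(x−1).  x never grows absent a source, so x_max = x₀
  closes the lattice; y_max = y₀ + x₀ makes it loss-free.  The linear
  system is propagated with Krylov matrix-exponential products
  (`expm_multiply`), conserving mass to ~10⁻¹⁴ — needed for the 10⁻⁸
  survival comparison.  A `survival_collapsed` mode tracks only (x, dead)
  with absorption at ax + pβx(x−1) for large systems.
* **Gillespie chain**: exact SSA of the same propensities; an ensemble
  variant advances all paths in vectorised rounds.
* **Mean-field**: dx̄ = −(a+r)x̄ − 2β x̄² + S_X·1{t ≤ T_irr},
  dȳ = ax̄ + pβ x̄² + S_Y·1{t ≤ T_irr} with S = ḋ·E[ξ]; integrated with
  LSODA at rtol 10⁻¹⁰ in two spans so the source switch-off is a breakpoint,
  not a smoothed kink.  The linear reduction has the closed form
  x̄ = x̄₀e^{−(a+r)t} with ȳ by quadrature.

## Specific-energy numerics

Multi-event distributions are computed on a uniform z grid using *cell
masses* (CDF differences per cell) rather than point-sampled densities, so
discrete means are exact to O(dz²); ν-fold convolutions use FFT convolution
truncated to the grid, and the dose mixture truncates the Poisson ν-sum at
1 − 10⁻⁹ mass.  The ν = 0 no-event atom at z = 0 is reported separately
from the continuous part.  For a delta spectrum the initial-count pmf is
evaluated by the exact double sum over traversal counts (the Neyman-type
law); otherwise by z-grid quadrature.  Truncation deficits are returned
and warned about beyond 10⁻⁶.

## Synthetic data and what the tests show

There is no external data: the study conditions themselves (printed dose,
spectrum, yields, kinetic constants) generate every input.  The generator
emulates a perpendicular, isotropic, uniform radiation field — tracks are
points in the 2-D nucleus plane, track centres outside Q are not modelled,
and `resample` boundary handling preserves per-track counts exactly
(keeping E[N_X] = κD) at the cost of a slight radial bias near the
boundary (`discard` mode offers the unbiased alternative).  Real
microdosimetric spectra, oblique incidence, 3-D track cylinders and
track-structure-code damage patterns are outside what passing tests can
certify; the tests establish internal consistency (spatial ↔ well-mixed ↔
ODE limits, analytic radial and count laws), not agreement with
experimental survival data.

## Design choices

* Amorphous-track placement requires a 2-D disk; the geometry and the
  simulator support 3-D balls, but the damage generator refuses them
  rather than silently projecting.
* Lethal lesions are placed by the same radial sampler as sub-lethal ones
  (nothing distinguishes their spatial law at induction).
* ξ^X and ξ^Y are conditionally independent given z; their correlation
  enters only through the shared specific energy.
* Kernels count both X and Y lesions by default and exclude the focal
  lesion; both are configurable since the crowding forms do not pin them
  down.
* A `constant` pair form (no distance dependence) complements the
  step/Gaussian families: it is the homogeneous reduction that makes the
  non-spatial models exact references.
* The scaling experiment uses deterministic initial counts K·x₀ (the
  rescaled initial measures must converge to a deterministic limit) and
  common SeedSequence-derived replicate streams.

## Problem sizes

Verification runs are sized for a single desktop core: 500-replicate
ensembles for linear-kinetics and dt-robustness checks (t_end = 0.25–0.5 h),
10⁴–2·10⁴ paths for total-variation comparisons (TV noise floor ≈ 0.01–0.02
at these sizes, hence the 0.02/0.03 thresholds), 200 replicates per K in
the fluctuation study, and 10⁵ draws for radial-law statistics.
Statistical assertions use 3-standard-error bands (or KS/χ² at p > 0.001),
so a ~0.3% per-assertion false-alarm rate is accepted.

## Known limitations

* The diffusive path is first-order in dt and freezes rates within a step;
  lesions that diffuse *and* react through steep kernels need small dt.
* No exact-in-law thinning/uniformisation scheme for diffusing reactants.
* The mean-field comparison is available only in its spatially homogeneous
  ODE reduction — the full nonlocal measure-valued limit equation has no
  discretisation here.
* Chemistry-coupled yields and correlated lesion motions are not modelled.
* `counts_series` replays event logs in O(events); logs are kept in memory.
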