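# Methods

## Scope and model

`migrastack` simulates the one-dimensional migration of a dilute solute
through an ordered stack of layers — polymer films and air gaps — optionally
terminated on the contact side by a well-mixed fluid compartment. The model
assumes:

* transport by Fickian diffusion only (no advection or convection in gaps,
  a reasonable assumption for sealed or tightly packed systems);
* constant, concentration-independent `D_j` and `k_j` within each step
  (dilute regime, no swelling);
* linearised Flory–Huggins sorption, `p = k_j·C_j`, with
  `k_j = p_sat·V̄·exp(1+χ_j)` in polymers and `k_j = R·T` in air;
* local thermodynamic equilibrium at interfaces: continuity of partial
  pressure (activity), hence a concentration jump fixed by the ratio of
  Henry coefficients;
* a perfectly mixed fluid, coupled through a Robin (third-kind) boundary
  condition with mass Biot number `Bi = h·l₁/D₁`; "negligible external
  resistance" is represented by `Bi = 1000`;
* an impervious far boundary for symmetric stacks, or a periodic wrap
  (far face in contact with the near face of the next repeat) for set-off
  configurations such as reel storage.

Because every equation is linear in concentration, contributions of several
sources superpose; `superpose()` exploits this, and the same linearity makes
the per-step Henry scale arbitrary — only ratios `k_j/k_i` (partition
coefficients) and `k_j/k₀` matter, which is how migration steps parameterised
by fluid-referenced partition coefficients (`k_F = 1`, `k_j = K_F/j`) are
handled.

### Equilibria

A closed stack relaxes to uniform activity `a`; layer *j* then holds
`C_j = a/k_j` and a share `(l_j/k_j)/Σ_k(l_k/k_k)` of the total amount, the
fluid entering through its equivalent thickness `l₀` (volume per contact
area) and `k₀`. `equilibrium_distribution` evaluates this general split; the
classical two- and three-layer closed forms (residual and transferred
amounts, with and without fluid) are special cases and are cross-checked
against it by property tests on random parameter draws.

Derived quantities: the apparent fluid/material partition coefficient equals
`k_eff/k₀` with `1/k_eff = Σ φ_j/k_j` (volume-fraction harmonic mean), and
the per-layer resistance ratio `R_j = (l_j·k_j/D_j)/(l_ref·k_ref/D_ref)` is
reported against a 0.1 mm air reference, rounded to the nearest integer in
reporting mode.

## Discretisation and integration

The solver works on the activity `a = k·C`. Each layer is divided into equal
cells (default 20 per layer, minimum 3); adjacent cell averages are coupled
by a series conductance `G = 1/[(Δx_j/2)k_j/D_j + (Δx_{j+1}/2)k_{j+1}/D_{j+1}]`,
which reduces to the standard central difference inside a layer and encodes
interface partitioning exactly at material boundaries — the steady state
satisfies `C_j/C_{j+1} = k_{j+1}/k_j` by construction. The fluid adds the
film resistance `k₀/h` in series with the first half-cell. With cell
capacities `c_i = Δx_i/k_i` the semi-discrete system `diag(c)·da/dt = L·a`
has a symmetric negative-semidefinite `L`, so mass is conserved exactly in
space and the scheme is free of spurious oscillations at any contrast.

Time integration uses SciPy's BDF with the constant sparse Jacobian
(`rtol = 1e-8`, absolute tolerance `1e-13` × the initial activity scale by
default). Implicit multistep methods preserve the linear mass invariant to
the accuracy of their Newton solves, giving closed-system residuals of
1e-9 or better over very long horizons, and they absorb the stiffness caused
by air/glassy-polymer diffusivity contrasts up to 10⁸. Negative undershoot
of the normalised activity beyond 1e-9 aborts the run (no clipping); the
threshold is configurable.

Verification: against the plane-sheet series solution (clamped surface) and
against the exact Robin-boundary series, the scheme converges at second
order; at 80 cells the transient is within 0.1 % of the Robin-exact
solution. Note that at `Bi = 1000` the exact solution itself differs from
the clamped-surface series by −0.9 % at `Fo = 0.01` (the film effect), so
comparisons to the clamped series at early times require the discretisation
error to be well below that. Early-time fluid uptake follows the expected
`√t` law (log–log slope 0.5 ± 0.02 over `Fo ∈ [1e-4, 1e-2]`).

`time_to_fraction` reports `t_eq(θ)`: the first time a compartment reaches a
fraction θ (default 0.95) of its equilibrium amount, interpolated in log
time; the criterion is configurable because "time to reach equilibrium" is
otherwise ill-defined.

A quasi-steady gas-film estimate (`short_time_rate`, conductance
`h = D_air/l_air`) provides a fast screening rate for transfer across an air
gap. It matches the transient solver in the deep short-time regime (within
10 % while the depletion is ≲0.2 % for the dimensionless case study) and is
a conservative upper bound beyond, once the polymer-side resistance becomes
comparable to the gas film.

## Scenarios

A scenario is an initial assembly plus ordered steps. Between steps the
engine applies transforms to the carried state: keep profiles, equilibrate a
subset of compartments (flat uniform-activity profiles), remove layers
(their content is logged, never silently dropped; remaining layers are
renumbered contact-first), or attach a fluid. Per-step `k`/`D` overrides
represent temperature changes — profiles are carried unchanged and the new
coefficients apply immediately; no internal Arrhenius model is used because
per-temperature parameters are inputs. The normalisation base (total initial
amount, kg·m⁻²) is set by the first step and preserved, so all steps share
one scale and removal bookkeeping is exact.

`distribute_equilibrium_initial` encodes the standard loading assumption
that a migrant endogenous to a multilayer part is pre-distributed between
its layers according to their capacities `l_j/k_j` (uniform activity).

### Built-in scenarios

* **S1, S2** — dimensionless two-substance case studies (bilayer in contact,
  and source separated by an air gap that is discarded before the fluid
  contact). Reference layer `l₁ = k₁ = D₁ = 1`, so durations are Fourier
  numbers; storage lasts `Fo = 100` and the contact step uses `Bi = 1000`.
* **T1/T2 loading** — a trilayer bag (EVA/EVOH/EVA, 0.3 mm, 53:1:6; or
  PE/EVOH/PE, 0.4 mm, 10.2:1:4.8) facing a PE/PA6/PE overpackaging
  (0.08 mm, 2.3:1:1.3) across an air gap parameterisable from 0 (perfect
  contact; the air layer is omitted) to 50 mm, sealed on both sides, at
  40 °C, for ε-caprolactam and BHT. Initial concentrations sit in the
  overpackaging (PA6 is the caprolactam reservoir; BHT favours the PE
  layers). The tabulated air diffusivities are kept verbatim even where
  they differ between bags for the same solute.
* **T1/T2 migration** — the bag alone in contact with ethanol at 25 °C for
  ten surrogate solutes, parameterised by fluid-referenced partition
  coefficients and the measured wall concentrations; the spiked amount is
  equilibrated across the wall before release. The fluid's equivalent
  thickness is the filled volume divided by the wetted wall area
  (5.4 mm for T1, 3.5 mm for T2). mg·kg⁻¹ loadings are converted with a
  laminate density of 1000 kg·m⁻³ (densities are user inputs; only absolute
  concentrations, not fractions, depend on this choice).
* Two-step loading-then-migration scenarios chain the above
  (`with_migration=True`); without a gap the overpackaging occupies layers
  4–6 of the loading stack and is removed with the (absent) gap before the
  fluid is attached.

## Probabilistic layer

Contact (loading) times are modelled as `t₁ = t̄₁·t₁*`, `t₁*` a unit-scale
Weibull variate with shape `s` (default 3); `shape = inf` is the point-mass
limit used to recover the deterministic pipeline. Since the loading map
`Ω: t₁ ↦ amount transferred` is monotone, the loaded amount's distribution
is a push-forward: `Pr(m ≥ m₀) = 1 − F(Ω⁻¹(m₀))`, evaluated on a monotone
PCHIP interpolant of Ω tabulated on a geometric grid spanning
`[1e-3, 1e2]·t̄₁` (49 points by default); percentile kinetics re-run the
loading step to the exact contact-time quantile and use the resulting
profile as the migration initial condition. This exact-quantile route is
deterministic; Monte-Carlo sampling (inverse transform, seeded) is retained
as an independent oracle in the tests. Because early loading grows as `√t₁`,
a factor of two on the loaded amount covers a factor of four of uncertainty
on the contact time — the basis of the common safety-factor-of-two argument,
which the tests verify on the perfect-contact loading fixture in its
square-root regime.

## Identification of a partition ratio

When a barrier layer cannot be obtained as a free film, its Henry
coefficient is unknown but the total amount in the laminate and the apparent
partitioning with the simulant are measurable. `identify_partition_ratio`
scans candidate ratios `K_barrier/contact = k_contact/k_barrier`; for each
candidate it rebuilds the initial distribution at uniform activity (the
total amount is conserved exactly), simulates the release, and scores the
fraction-released curve by least squares; a golden-section refinement in
log-ratio follows the grid scan. Too-small ratios seal the barrier (release
only from the contact layer); too-large ones free it (early excess, late
deficit) — the objective has an interior minimum. The barrier diffusivity
defaults to `D_contact/30` (the usual dry-EVOH estimate) and is overridable.
The default objective is unweighted, matching common practice when the error
structure is unknown; a `weights` argument supports generalised least
squares.

The identifiability study shipped with the tests recovers
`K_EVOH/PE = 0.2` from 12-point synthetic kinetics with 5 % multiplicative
noise. Its design was chosen by a sensitivity (Fisher-information) analysis
of the forward model: the information about the ratio is concentrated in the
barrier-drain window, so the study uses the PE/EVOH/PE bag with the BHT
parameter set (the strongest barrier signal among the tabulated surrogates),
weekly sampling from day 85 to day 162, and relative (1/Ω²-weighted)
residuals — the maximum-likelihood objective for multiplicative noise. With
that design the recovery rate is ≈95 %; with generic geometric sampling over
1–120 days it drops to ≈60 %, a useful reminder that sampling design, not
the optimiser, limits this identification.

## Synthetic data

`generate_synthetic_kinetics` produces simulator output at chosen times with
optional multiplicative Gaussian noise (seeded). It emulates sampling error
of concentration measurements; it does not emulate systematic effects seen
in real desorption experiments — sampling-volume corrections, evaporative
losses of volatile solutes from the far side of the bag, drift of `D`/`k`
with humidity or swelling. Passing recovery tests therefore demonstrates the
correctness and conditioning of the inference machinery, not robustness to
model misspecification.

## Numerical and design choices

* Concentrations are stored in kg·m⁻³; the dimensionless fields are views.
  Henry coefficients follow the activity convention `p = k·C` (air:
  `k = RT`), under which the tabulated `k/RT` columns are 1 for air.
* Output schedules are geometric in time (default 61 points over 6 decades).
* Grid: equal cells per layer (default 20). Doubling changes the fluid
  kinetics by < 0.5 % in the verification setups; use 80+ cells for
  early-time (`Fo ≤ 0.01`) quantitative work.
* Fuller–Schettler–Giddings gas diffusivities use the classical increment
  set (C 15.9, H 2.31, O 6.11, N 4.54, ring −18.3; air: M 28.96, Σv 19.7)
  and prefactor 1.0e-3 (cm² s⁻¹, atm, g mol⁻¹). For ε-caprolactam at 40 °C
  this gives 8.5e-6 m²·s⁻¹, within 6 % of the tabulated reference value;
  agreement within ~15 % is what different published increment sets allow.
* The loading-map monotonicity check tolerates relative wiggles of 1e-8
  (integrator accuracy at the plateau).
* Long-horizon equilibrium checks run to ≥10 times the slowest relaxation
  time (up to ~10¹¹ s for BHT in glassy PA6); the adaptive integrator takes
  exponentially growing steps there, so cost stays low.

## Known limitations

* One-dimensional, rigid geometry: no edge effects, welded seams, connected
  tubes, or moving boundaries; no thermal convection in gaps.
* Dilute linear sorption only; no concentration-dependent `D` or `k`,
  no swelling.
* χ values, diffusivities and saturation pressures are inputs; the package
  does not estimate them from molecular structure (except gas-phase D via
  Fuller's law).
* The Weibull contact-time model covers variability of exposure time only;
  temperature and composition variability are not propagated.
* Identification handles exactly one unknown ratio; joint multi-parameter or
  Bayesian inference is out of scope.
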