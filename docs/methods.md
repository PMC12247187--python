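# Methods

## Model

The colony is a 1-D column of incompressible bio-fluid on a nutrient
source. Writing the cell content as a volume fraction N(z,t) and imposing
the no-voids constraint N ≡ 1 turns volume continuity into ∂u/∂z = g\*,
with the net volumetric growth rate

    g*(z) = α R(z)/R* − β .

The velocity field is closed by Darcy's law u = −λ ∂p/∂z with no flow into
the substrate (∂p/∂z = 0 at z = 0) and a free roof (p = 0 at z = h), and
the roof moves kinematically, dh/dt = u(z = h). The nutrient obeys
advection–diffusion with linear uptake, a clamped base concentration
R(0) = R\* and a no-flux roof ∂R/∂z(h) = 0.

Nondimensionalising by the advection time 1/α and the initial height h₀
shows the resource equation is controlled by the Péclet number
Pe = αh₀²/D_R. For realistic values (D_R ~ 10⁴ µm²/h, α ~ 1 h⁻¹, h₀ ~ 1 µm)
Pe ≈ 10⁻⁴: diffusion equilibrates the nutrient profile essentially
instantaneously relative to growth, so the time-derivative and advection
terms are dropped (quasi-static approximation) leaving the linear BVP
d²R/dz² = R/L² with L = sqrt(D_R ε R\*/α). Its solution is the cosh
profile; inserting it into g\*, integrating the pressure twice and
evaluating the Darcy velocity at the roof gives the single governing ODE

    dh/dt = α L tanh(h/L) − β h .

The rate is maximised at h\* = L arcsech(√(β/α)) > L, its positive root is
the plateau height (slightly below the piecewise law's αL/β), and its
small- and tall-colony limits are (α−β)h and αL − βh — the two branches of
the piecewise interface model.

Assumptions worth keeping in mind: a single living phase (dead cells are
assumed to lose their volume quickly, so β lumps death + fast breakdown),
linear uptake rather than Monod saturation (stabilised by the base
Dirichlet condition), one spatial dimension, and no sudden height drops
(which would transiently compress R above R\*).

## Parameters

| symbol | meaning | units | typical / default |
| --- | --- | --- | --- |
| α | specific growth rate | 1/h | 0.4–1.5 (e.g. 0.86) |
| β | volume decay rate | 1/h | β/α in 0.03–0.12 (e.g. 0.051) |
| L | nutrient penetration depth | µm | 5–30 (e.g. 13.17) |
| D_R | nutrient diffusivity | µm²/h | ~10⁴ |
| ε | yield (volume per concentration) | — | only εR\*D_R/α = L² is identifiable |
| R\* | base nutrient concentration | conc. | sets the concentration scale |
| λ | Darcy mobility | — | cancels from dh/dt; sets internal pressure scale only |
| h₀ | initial height | µm | 1 (≈ one cell length) |

Only (α, β, L) are estimable from height data; ε and R\* trade off exactly
and λ never appears in observables. `TransportParams.for_length` constructs
a transport split realising a target L for simulation use.

## Numerics

* **Closed forms.** cosh ratios are evaluated as sums of non-positive
  exponentials, so no overflow occurs for arbitrarily tall columns
  (naive cosh overflows near argument 710). arcsech uses the stable
  principal-branch form ln((1+√(1−x²))/x).
* **Resource BVP.** Central differences on the rescaled column z' = z/h
  (uniform grid, Dirichlet base, Neumann roof via a symmetric ghost node;
  the true solution is even about z = h, so the reflection is exact).
  Default `order=2` shows clean second-order convergence (~4× error drop
  per grid doubling). An `order=4` Numerov stencil is provided and used by
  the velocity pipeline, where tall columns (h ~ 20L) amplify the
  second-order truncation error above the 10⁻⁴ agreement demanded of the
  oracle; at 512 nodes the Numerov path agrees with the tanh law to ~10⁻⁷.
* **Pressure/velocity.** Double cumulative Simpson integration of
  p'' = −(h²/λ)g\*; the accumulated gradient is reused for the Darcy
  velocity so no numerical re-differentiation is needed. The roof velocity
  then equals h·∫₀¹g\*dz′ to quadrature accuracy, independent of λ.
* **Anti-circularity.** The simulator's growth field is always computed
  from the *numerically* solved resource profile (g\* = αR/R\* − β), never
  from the closed-form profile, so oracle agreement is a genuine check.
* **Transient resource equation.** Backward-Euler in time (the 1/Pe
  diffusion term is stiff at Pe ~ 10⁻⁴, making explicit stepping
  impractical), central differences in space, optional advection by a
  supplied velocity field. Used to show the transient field relaxes onto
  the quasi-static profile to <1% at Pe = 10⁻⁴, and measurably departs
  from it at Pe = 10 under O(1) advection.
* **Moving boundary.** Handled purely through the z' rescaling: each step
  solves the quasi-static fields on [0,1] at the current h and advances h
  with classical RK4 on dh/dt = u_top(h), halving the step until two
  refinements agree to 10⁻⁶ relative (RK4 rather than first-order Euler:
  the halving loop converges in one or two refinements instead of
  thousands). Heights below half a cell length abort with a diagnostic.
* **Trajectory integration.** DOP853 at rtol 10⁻¹⁰. The interface model's
  kink at h = L is crossed via event detection and restart, and its exact
  piecewise-exponential solution (crossing time t_c = ln(L/h₀)/(α−β), both
  crossing directions handled) serves as the cross-check.
* **Fitting.** Bounded trust-region least squares on heights (unweighted —
  no error model is assumed), first observation fixed as the initial
  condition. Initialisation: early-time log-slope → α−β; height at the
  maximal finite-difference rate, halved → L₀ (the peak sits above L);
  plateau inversion αL/β = h_max closes the triple. Up to 10 seeded
  uniform multistarts within bounds if the first attempt fails; flat
  inputs return `converged=False` rather than raising. Default bounds:
  α ∈ [0.01, 10] h⁻¹, β ∈ [10⁻⁴, 5] h⁻¹, L ∈ [0.1, 1000] µm.
* **Peak analysis.** Heights are smoothed with a centred moving average
  (default window 7 points, implemented as a Savitzky–Golay filter of
  polynomial order 1 so edge samples are handled by local linear fits and
  linear data pass through exactly); the rate is a centred finite
  difference; ties break toward the smaller height and a maximum at the
  first sample is flagged as a boundary peak. The window is a declared
  analysis choice, recorded in every `PeakEstimate`.

## Synthetic data

The generator emulates single-colony interferometric height traces: start
at h₀ = 1 µm, 40 h sampled every 0.5 h, backbone from the exact growth law,
observation noise h·(1+ε_rel) + ε_abs with independent Gaussians
(defaults 1% relative, 0.1 µm additive floor — interferometric height error
plausibly scales with height above an instrument floor; no published noise
model exists, so both knobs are explicit and configurable) and truncation
at 0.01 µm to keep observations positive. Panels draw (α, β/α, L)
uniformly from α ∈ [0.4, 1.5] h⁻¹, β/α ∈ [0.03, 0.12], L ∈ [5, 30] µm —
the narrow rate-ratio region laboratory strains occupy. All randomness
descends from a single integer seed; strain k of a panel is stable under
changes to the panel size.

What the generator does **not** emulate: spatially resolved height maps,
surface roughness, correlated (drift-like) measurement error, sudden
height collapses, or strain-to-strain variation beyond independent uniform
draws. Passing recovery tests therefore demonstrate identifiability and
correctness of the estimation machinery under the declared noise model,
not robustness to every artefact of real interferometry.

## Problem sizes used in the validation suite

Grid studies use 64–512 nodes; oracle-equivalence scans 40 heights spanning
0.1L–20L at 512 nodes; transient relaxation uses 128 nodes and 400–800
implicit steps; the recovery study uses 50 synthetic colonies (81 samples
each) fitted with both models; the surrogate strain panel uses 9 colonies.
These sizes make every check sharp (discretisation errors orders of
magnitude below the asserted tolerances) while the full suite stays fast.

## Known limitations

* One-dimensional: no lateral nutrient supply or colony-edge effects.
* The dead-cell phase is not modelled explicitly; β assumes fast breakdown.
* ε, R\*, D_R and λ are not individually identifiable from height data;
  simulations fix an arbitrary split realising the target L.
* The empirical peak estimator is biased by sampling cadence and smoothing
  near kinks (it localises the interface model's kink only to within a
  couple of samples).
* Fits report point estimates only; no uncertainty quantification is
  attached (residual bootstrap could be layered on, but none is built in).
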