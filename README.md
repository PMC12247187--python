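# vertigrow

Active-fluid modelling of **vertical biofilm growth** — for microbiologists
and biophysicists who measure colony height over time (e.g. by
interferometry) and want mechanistic parameters out of those curves.

## The model

A biofilm colony is treated as a one-dimensional column of incompressible,
growing "bio-fluid" of height *h(t)* above a substrate that supplies a
diffusible nutrient at fixed concentration *R\**. Nutrient diffuses up into
the colony, is consumed in proportion to the local concentration, and
cannot flux out of the colony roof. Because nutrient diffusion is far
faster than growth (Péclet number Pe = αh₀²/D_R ≈ 10⁻⁴), the nutrient
profile is quasi-static:

    R(z) = R* cosh((z − h)/L) / cosh(h/L),   L = sqrt(D_R ε R* / α)

where *L* is the characteristic depth of the metabolically active layer.
Local volume growth g\* = αR/R\* − β (growth rate α, decay rate β) drives a
Darcy flow, and integrating the velocity field up the column collapses the
whole dynamics onto a single smooth ODE for the colony height:

    dh/dt = α L tanh(h/L) − β h

The older piecewise heuristic ("interface model") dh/dt = (α−β)h for h ≤ L,
αL − βh for h ≥ L is the kinked limit of the same law. The two laws fit
height curves almost identically, but they disagree about **where the
growth rate peaks**: the interface model pins the peak at *L*, while the
smooth law predicts

    h* = L arcsech( sqrt(β/α) )  >  L

because the no-flux roof "reflects" nutrient back into short colonies —
at the moment the colony reaches height *L*, the concentration at depth *L*
is ~76% higher than the tall-colony limit R\*e⁻¹. Measured growth-rate
peaks indeed sit above *L*, and `vertigrow` quantifies which law explains
them.

## What's in the box

| module | contents |
| --- | --- |
| `vertigrow.model_core` | every closed form: L, resource profile and coefficients, growth field, both height laws, h\*, steady states, Pe |
| `vertigrow.pde_oracle` | independent finite-difference solvers (resource BVP, transient resource transport, pressure, Darcy velocity, moving-boundary simulation) used to validate the closed forms |
| `vertigrow.trajectories` | high-accuracy h(t) integration; exact piecewise-exponential interface solution |
| `vertigrow.fitting` | bounded least-squares estimation of (α, β, L), empirical peak-height analysis, model comparison |
| `vertigrow.synthetic_data` | seeded generator of interferometry-like height panels |
| `vertigrow.cli_io` | CSV formats and the `vertigrow` command line (`synth`, `simulate`, `fit`, `peak`, `compare`) |

## Worked example

Generate a noisy synthetic colony with known rates (α = 0.86 h⁻¹,
β = 0.051 h⁻¹, L = 13.17 µm — a measured *A. veronii* fit), then recover
the parameters and compare both growth laws against the empirical peak:

```python
import vertigrow as vg

params = vg.GrowthParams(alpha=0.86, beta=0.051, L=13.17)
spec = vg.SyntheticSpec(seed=1)                      # 40 h, every 0.5 h, 1% noise
traj = vg.generate_trajectory(params, spec, model="active", seed=1)

result = vg.compare_models(traj)
fa, fi = result.fit_active, result.fit_interface
print(f"active:    alpha={fa.params.alpha:.3f} /h  beta={fa.params.beta:.4f} /h  L={fa.params.L:.2f} um")
print(f"interface: alpha={fi.params.alpha:.3f} /h  beta={fi.params.beta:.4f} /h  L={fi.params.L:.2f} um")
print(f"h* (active model) = {fa.hstar_model:.1f} um")
print(f"empirical peak    = {result.peak.h_star_empirical:.1f} um")
```

prints

```
active:    alpha=0.854 /h  beta=0.0509 /h  L=13.24 um
interface: alpha=0.774 /h  beta=0.0503 /h  L=14.48 um
h* (active model) = 27.6 um
empirical peak    = 37.1 um
```

Both models recover similar rates from the same curve (they measure the
same growth, decay and depletion scales), but the empirical growth-rate
peak at ~37 µm is far above the interface model's L ≈ 14 µm and much closer
to the active model's h\* ≈ 28 µm — the peak analysis, not the height fit,
is what discriminates the two laws. The same pipeline runs from the shell:

```sh
vertigrow synth --n-strains 9 --seed 1 --out panel/
vertigrow compare panel/ --out comparison/
```

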