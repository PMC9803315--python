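# fibrocontrol

Optimal control of TGF-β in reaction–diffusion models of pulmonary
fibrosis.

In idiopathic pulmonary fibrosis (IPF), TGF-β drives the transformation
of fibroblasts into collagen-depositing myofibroblasts. `fibrocontrol`
models the myofibroblast density m(x, y, t) and fibroblast density
f(x, y, t) on a homogenized 1 cm² tissue square with zero-flux
boundaries, and asks: what TGF-β schedule drives the myofibroblast
density down at least control effort?  It is written for modellers in
mathematical biology and control who want a tested, scriptable
implementation of the full chain: finite-difference assembly →
linear-quadratic synthesis → constrained (KKT) and two-species variants.

## Model

The homogenized myofibroblast equation (volume fraction γ = 127/343,
effective diffusion a = 0.11) is

∂m/∂t − (a/γ) D_m ∇²m = (λ_mfT·U(t) + λ_mfG·G₀/(K_G+G₀))·f₀ − d_m·m,

where U = TGF/(K_TGF + TGF) ∈ [0, 1) is the Hill-saturated control.
Central differences on the (n−1)² interior nodes give the state-space
form ṁ = A m + B U + b.  Minimising ½∫(mᵀm + UᵀU)dt yields the feedback
U* = K m* + ρ with K = −BᵀP from the algebraic Riccati equation
AᵀP + PA − PBBᵀP + I = 0 and ρ from an affine (adjoint) solve absorbing
the constant source b.  Because the unconstrained optimum demands
negative TGF-β, a lower bound U(t) ≥ U(t₀) is enforced through the KKT
multiplier μ (μ > 0 ⇔ TGF held at its homeostatic value), and a coupled
two-species problem runs the same analysis for m and f jointly with a
four-case admissibility screen over (μ_m, μ_f).

All kinetic constants default to the tabulated literature values
(units g, cm, day); see `fibrocontrol.parameters`.

## Worked example

```python
import fibrocontrol as fc

myof, fib, homog = fc.default_parameters()
grid = fc.build_grid(6)                      # 36 interior nodes
settings = fc.SimulationSettings()           # dt = 0.1 day, 300 days

# constrained optimal control: TGF-beta may not fall below homeostasis
run = fc.solve_constrained_model(myof, homog, settings=settings)
print(run.control.TGF.max())                 # 2.51e-12
print(run.trajectory.mean_density[-1])       # 0.034994602012552174

# coupled two-species problem: enumerate the four KKT cases
system = fc.assemble_coupled(myof, fib, homog, grid)
runs = [fc.solve_coupled_case(c, system, myof, fib, settings)
        for c in (1, 2, 3, 4)]
print([r.admissible for r in runs])          # [False, False, False, True]
print(fc.select_admissible_case(runs).case)  # 4
```

The constrained run holds TGF-β exactly at its homeostatic concentration
2.51×10⁻¹² g·cm⁻³ (the bound binds at every node and step: the
unconstrained feedback would go negative), and the coupled analysis
rejects every case that leaves a feedback free — case 4, constant
TGF-β for both species, is the only admissible strategy.  The day-300
mean myofibroblast density 3.50×10⁻² g·cm⁻³ is the attracting state
c/d_m of the clamped dynamics.

A CLI mirrors the library:

```sh
fibrocontrol lqr --nodes 6 --dt 0.1 --tf 300 --out out/
fibrocontrol coupled --case auto --out out/
```

writing trajectory/control CSVs and a JSON run summary.

## Layout

- `fibrocontrol.parameters` — tabulated constants, validation, overrides
- `fibrocontrol.discretization` — grids and state-space assembly
  (`neumann5` zero-flux stencil; `paper_literal` printed block matrices)
- `fibrocontrol.forward_sim` — explicit-Euler simulation of the
  uncontrolled models
- `fibrocontrol.lqr` — Riccati/affine solves, feedback, closed loop
- `fibrocontrol.constrained` — lower-bound KKT branching
- `fibrocontrol.coupled` — two-species four-case analysis
- `fibrocontrol.io_cli` — config, CSV/JSON serialization, CLI

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
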