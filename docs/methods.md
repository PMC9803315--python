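# Methods

## Model and assumptions

The package treats lung tissue as the unit square R = [0, 1]² cm with
the alveolar microstructure homogenized away: the tissue occupies a
volume fraction γ = 127/343 of the domain and diffusion acts through an
effective isotropic tensor with diagonal entry a = 0.11, so a species
with molecular diffusivity D moves with effective diffusivity (a/γ)·D.
Dividing the homeostatic TGF-β concentration by γ converts a
per-tissue-volume concentration to the whole-space value,
2.51×10⁻¹²/γ ≈ 6.78×10⁻¹² g·cm⁻³.

Two cell populations are modelled on R with zero-flux boundaries:

- **Myofibroblasts** m(x, y, t): activated from a fibroblast pool held
  at its homeostatic density f₀ by Hill-saturated TGF-β and PDGF
  signals, and lost to apoptosis at rate d_m.
- **Fibroblasts** f(x, y, t): sourced from alveolar epithelial cells
  (λ_Ef·E₀ plus a TGF-β-driven production term) and drained by
  apoptosis, transformation to myofibroblasts, TGF-β production and
  ECM deposition; the total linear loss rate is
  α = λ_mfG·G₀/(K_G+G₀) + λ_TGFf·E/(E+K_E) + λ_ρf + d_f ≈ 0.1463 day⁻¹.

The control variable is the Hill fraction U = TGF/(K_TGF + TGF) ∈ [0, 1),
with the exact inverse TGF = K_TGF·U/(1−U).  Linearizing around
homeostasis (f, G, E frozen at their initial values) gives, per
species, ṁ = A m + B U + b with B = θ·I (θ_m = λ_mfT·f₀,
θ_f = λ_fE·E/(E+K_E)) and a constant source b.

All constants are carried in the source units (g, cm, day) and default
to the tabulated literature values; `validate()` reports any violated
sign/range invariant, and a flat YAML config can override any field.

## Discretization

Central differences on nodes x_i = i/n, unknowns at the (n−1)² interior
nodes, stacked row-major with the x-index fastest.  Two assemblies:

- **neumann5** (default): the five-point Laplacian with the first-order
  mirror rule at the zero-flux boundary (the boundary node equals its
  interior neighbour).  With the loss rate removed, every row of A sums
  to zero — the discrete statement of mass conservation — and the
  Laplacian block is symmetric.  The stencil weight is
  r = a·D/(γ·dx²), the unique dimensionally consistent reading of the
  printed weight expression (discretizing (a/γ)·D·∇² with spacing dx
  forces it); the formula string is preserved in the run summary.
- **paper_literal**: the printed block matrices, kept for archaeology of
  the published figures: 1-D tridiagonal G blocks (diagonal −2r − loss),
  strictly sub-diagonal L couplings, a B with identity off-diagonal
  blocks, and a b whose per-block edge entries carry the x-boundary
  density frozen at its homeostatic value.  These blocks are not
  mass-conserving and the unit off-diagonal coupling in B persists even
  at D = 0; the default scheme exists because the stated zero-flux
  physics should win over the printed Dirichlet idiom.

The explicit Euler step is stable for dt < 2/(4r + loss); at the
defaults the bound is ≈ 115 days, far above the working dt = 0.1 day.

An optional damage region elevates the initial density tenfold inside a
centred square of side `damage_extent` (how damage enters the equations
is otherwise unspecified; the uniform field is the default).

## Control synthesis

With unit weights on state and control, Pontryagin's principle yields
U* = K m* + ρ, K = −BᵀP.

- **Riccati** (`riccati_mode`): `algebraic` (default) solves the
  stationary CARE with scipy's solver and verifies the Frobenius
  residual against 10⁻⁸·(1+‖P‖_F); `differential` integrates
  Ṗ = −(AᵀP + PA − PBBᵀP + I) backward by Euler from P(tf) = 0.  The
  source material writes the differential form without a terminal
  condition while reporting a stationary solver; both readings are
  provided, with P(tf) = 0 as the documented choice of terminal
  condition.
- **Affine term** (`affine_mode`): `adjoint` (default) decomposes the
  costate as λ = P m + s with ṡ = −(A − BBᵀP)ᵀ s − P b, s(tf) = 0 and
  ρ = −Bᵀs — the unique decomposition consistent with the costate
  equation; `paper_eta` realises the printed matrix recursion
  η̇ + η(A − BᵀPB) = P with ρ = Bᵀηb (stationary or backward-integrated),
  whose printed form is dimensionally ambiguous and kept as an option.

The closed loop integrates ṁ = (A − BBᵀP)m + Bρ + b by explicit Euler,
records U per node and maps it to TGF wherever U < 1.  Negative U
(negative TGF-β) is recorded and flagged, never clamped: with the
tabulated parameters the unconstrained optimum is negative essentially
everywhere, which is the finding that motivates the constrained
problem.  Costs: the running quadrature uses the trapezoid rule on the
stored grid (matching the integrator's first order), and the predicted
optimum is ½·m₀ᵀP(t₀)m₀.

Under the adjoint affine term, the closed-loop mean density settles at a
strictly positive steady state (the control authority θ ≈ 5.7×10⁻⁴
day⁻¹ is too weak to cancel the source c ≈ 5.7×10⁻⁴ g·cm⁻³·day⁻¹ at
quadratic cost), so the published decay-to-zero trajectories are not
reproduced by the equations as given; the run summary reports what the
model actually does.

## Constrained and coupled problems

The lower bound U(t) ≥ U(t₀) is enforced by per-step, per-node KKT
branching: the feedback candidate above the bound is kept (μ = 0),
otherwise the control sits exactly at U(t₀) (μ > 0, complementary
slackness; only μ's sign matters, so it is stored as a boolean).  A
`global_branch` option reproduces the published all-or-nothing reading
(any violation clamps the whole horizon).  At the defaults the bound
binds everywhere and the applied TGF-β is the homeostatic 2.51×10⁻¹²
g·cm⁻³, bit for bit.

The coupled problem penalizes ½∫((m−f)ᵀ(m−f) + U_mᵀU_m + U_fᵀU_f)dt.
Following the source derivation the synthesis decouples into two
independent Riccati/affine pairs with unit state weight; the strict
difference objective (joint stacked state, weight [[I, −I], [−I, I]])
is available behind `strict_cross_term`.  The four KKT cases (which of
μ_m, μ_f is positive) are always all enumerated and recorded; a case is
admissible when both mapped TGF-β trajectories are non-negative, at or
above their initial values and below saturation, and selection takes
the cheapest admissible case with ties broken toward the highest case
label.  With the default parameters every free feedback demands
negative TGF-β, so case 4 (both concentrations constant at
2.51×10⁻¹²) is selected.  The printed two-species optimum
½(m₀ᵀP_m m₀ − f₀ᵀP_f f₀) is reproduced with its minus sign as printed;
it can be negative although the running integrand is not, and the run
summary flags that when it occurs.  The myofibroblast equation keeps
the fibroblast pool frozen at f₀ even in the coupled model, as printed;
`live_coupling` feeds the simulated f(t) through instead.

## Synthetic fixtures

Tests are driven by programmatically built instances: the 1-node system
(grid n = 2, where the Laplacian vanishes and the model is the scalar
ODE ṁ = −d_m m + θU + c — exactly solvable), a 2×2-interior-node grid,
symmetric species pairs, and a seeded family of randomized 1-node
systems for the cost-ordering property.  These exercise every code path
the full grid uses (the assembly is dimension-generic), but they do not
emulate spatial heterogeneity of real tissue: with uniform initial data
and zero-flux boundaries the spatial problem collapses onto the scalar
one, so passing tests validate the kinetics, the synthesis and the
conservation structure, not any claim about spatially resolved fibrosis
in vivo.

## Numerical choices and problem sizes

- Working grid 36 interior nodes (n = 7), dt = 0.1 day, horizon 300
  days — the published working resolution; a 64-node grid (n = 9) is a
  one-argument change.  Tight-tolerance closed-form comparisons use the
  1-node system at dt = 10⁻³.
- "Vanishes" is operationalized as the spatial mean density reaching 1%
  of its initial value (`vanish_fraction`), since no threshold is
  stated in the source material.
- CSV output uses %.17g and round-trip parsing, so written trajectories
  restore the exact binary64 values.
- Ties in the KKT branch (candidate exactly at the bound) count as
  active, matching the weak inequality in the multiplier definition.

## Known limitations

- First-order explicit Euler throughout: expect O(dt) global error
  (≈ 2×10⁻⁶ relative on the 100-day well-mixed benchmark at dt = 10⁻³).
- The uncontrolled fibroblast density *grows* toward c_f/α ≈ 1.37
  g·cm⁻³ with the tabulated source λ_Ef·E₀ ≈ 0.2 g·cm⁻³·day⁻¹, and both
  clamped-control densities settle at positive attracting states; the
  published decaying trajectories are not derivable from the printed
  equations and are therefore reported, never asserted.
- λ_Ef is tabulated in g·cm⁻³ yet acts as a source rate; it is stored
  and used exactly as printed, and the dimensional tension is left
  unresolved.
- No parameter estimation, no 3-D domains, no adaptive stepping, no
  box constraints beyond the single lower bound.
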