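# Methods

## Model and scope

`coyield` simulates a two-strain consortium in three layers.

**Flux layer.** Each strain is a stoichiometric model at steady state
(`S·v = 0`, flux bounds in mmol·gDW⁻¹·h⁻¹).  Two optional constraint
classes shrink the solution space:

* *Enzyme pool*: `Σᵢ vᵢ·MWᵢ/kcatᵢ ≤ pool` over reactions with kinetic
  annotations.  Default pool 0.227 g enzyme·gDW⁻¹ at saturation 1,
  both configurable in `attach_kinetics`.  Fluxes through
  kinetically annotated reactions are assumed non-negative (reversible
  steps are split, see below).
* *Thermodynamics*: every pathway reaction *i* carries
  `Dfᵢ = −(ΔrG'°ᵢ + RT·Σₘ sₘᵢ·ln Cₘ)` over *tracked* metabolites.  A
  binary `zᵢ` couples flux and feasibility: `vᵢ ≤ zᵢ·UBᵢ` and
  `Dfᵢ + (1−zᵢ)·K ≥ Df_min ≥ 0`, with `ln C` boxed per metabolite.
  The pathway MDF `B` obeys `Dfᵢ + (1−zᵢ)·K ≥ B`.  Binaries exist only
  for pathway reactions; the rest of the network is thermodynamically
  unconstrained.

Defaults: R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹, T = 310.15 K (E. coli
culture), K = 1000 kJ/mol, Df_min = 0, concentration box 1 µM–10 mM.
Water and protons are excluded from concentration terms (their
contribution is inside the transformed ΔrG'°); the exclusion list is
configurable and wins over per-file annotations.  Reversible pathway
steps are represented as two irreversible reactions, the backward copy
suffixed `_reverse` with the negated ΔrG'° (enforced at load time).

**Objective ordering.**  The biological objective (growth, or
production under a growth floor) is solved first.  With thermodynamics
enabled a second stage fixes the binaries at their stage-1 values,
pins the biological objective to within `lexicographic_tol` (default
10⁻⁶ relative) and maximizes `B`, so the reported state is as
thermodynamically favorable as the biological optimum permits.
Freezing the binaries makes stage 2 a pure LP — deterministic, fast,
and with bound duals available for shadow prices.  The cost is that a
different binary assignment with equal biological objective but higher
`B` would be missed; on the networks this package targets (binaries
only on designated pathway reactions) we have not observed the case.

**Calibration layer.**  The expression degree `d = (v_nfeg −
v_feg)/v_nfeg` is fitted by scanning `d`, imposing `v_bio ≥
(1−d)·v_nfeg`, maximizing production and comparing
`v_production·duration·density` with the measured titer.  Grid:
coarse 10⁻² pass, then refinement by factors of 10 down to 10⁻⁴
(matching the precision at which degrees are reported), absolute-error
objective, ties toward smaller `d`.  The joint co-culture mode scans
`(d_up, d_down)` pairs against titers at ≥2 inoculum ratios
(relative-error sum by default, absolute optional); per-strain flux
solutions are cached per grid value of `d`, so each candidate pair
costs one integrator run, not two LP solves.

**Consortium layer.**  Mean fluxes map to instantaneous co-culture
fluxes through the scalar `k = Σⱼ kⱼ·icrⱼ` with `kⱼ =
C_initial/C̄ⱼ` (trapezoid time average of the substrate depletion
curve).  Production integrates over `tp` steps of `Δt` (defaults
60 × 0.1 h, a 6-h horizon).  Unit chain: flux (mmol·gDW⁻¹·h⁻¹) ×
biomass density (gDW·L⁻¹, default 1, held constant) × Δt (h) → mM per
step.

## Interpretive decisions in the integrator

These were the genuinely open design points; they are concentrated in
`coculture.simulate_production`:

* **Strain-fraction weighting.**  Each strain's step contribution is
  weighted by its inoculum fraction, constant over the run (no biomass
  dynamics are modeled).  Without this weighting the prediction would
  be independent of the strain ratio, contradicting the observed
  ratio dependence of co-culture titers.
* **Cross-feeding pools.**  Exchanged intermediates are explicit
  pools: producer secretion is credited first within a step, consumer
  uptake is then capped at the pool.  A capped consumer's entire flux
  vector is scaled by `realized/demand` for that step — a
  proportional-slowdown approximation chosen for linearity and mass
  safety; it does not re-solve the consumer's LP at reduced uptake.
  This is the largest modeling approximation in the package.
* **What counts as "the" product.**  The per-step production sums the
  designated production fluxes of both strains, except that a strain
  whose product is an exchanged intermediate contributes through the
  pool rather than to the total (otherwise intermediates would be
  double-counted as product).
* **Exchange ordering.**  Exchanges are processed in the order listed;
  with a single exchanged metabolite (the common case) this is
  immaterial.

Diagnostics: `cap_uptake=False` disables the cap and records the first
step at which a pool would go negative; a substrate-supply cap stops
integration in the step where cumulative consumption reaches it; a
`horizon` inconsistent with `tp·Δt` is warned about, not rejected.

## Shadow prices

The shadow price of a metabolite is the sensitivity of `B` to shifting
its entire log-concentration window, sign convention: positive =
raising the allowed concentration raises `B`.  Default route: bound
duals of the final MDF LP (lower + upper marginal per metabolite).
Cross-check: central finite differences with step 10⁻³ on the ln
bounds — small against the 9.21-wide default window, and exact in the
interior of a linearity region since `B` is piecewise linear in the
bounds.  Where dual and difference disagree by more than 10⁻⁴ kJ/mol
(degenerate optimum, non-unique duals — e.g. a forced-active
reversible pair pinning `B` at 0) the finite-difference value is
reported and the metabolite flagged.

## Numerical choices

* LP/MILP via scipy's HiGHS; feasibility/optimality tolerances
  requested at 10⁻⁹, invariant checks in tests use 10⁻⁶.
* Bottleneck tolerance |Df − B| ≤ 10⁻⁶ kJ/mol.
* `B` is bounded by ±K in the program (no driving force can exceed
  |ΔrG'°| + RT×window anyway); reported `-0.0` is normalized to `0.0`.
* When `required_active` covers all pathway reactions the binaries are
  fixed and the MILP collapses to an LP.
* Big-K insensitivity (×10 changes nothing beyond solver tolerance) is
  asserted in tests.

## Synthetic data: what it emulates, what it does not

The toy strain is a unit-stoichiometry chain with a branch point
feeding biomass and product, so closed forms exist: max growth equals
the uptake bound, and production at degree `d` is exactly
`d·uptake_bound`.  The mono-culture generator forward-simulates at a
known `d`, emits an exponential-to-zero substrate curve on the
integrator's own grid (so trapezoid averages are exact for the
generating process) and perturbs the titer with multiplicative
lognormal noise of a given CV (titers are positive; errors scale with
magnitude); unit-mean correction keeps the noise unbiased.  The
co-culture generator runs the forward integrator at known
`(d_up, d_down)` for each requested ratio.

Study conditions baked into the defaults: uptake bound
10 mmol·gDW⁻¹·h⁻¹, 6-h horizon in 60 steps, initial substrate 10 g/L,
5% measurement CV where noise is used.  Recovery studies use degrees
at the two scales seen in practice: ~10⁻² and below for balanced
pathways (the noisy-recovery study runs at d = 0.005, inside the
0.0005–0.011 range typical of low-burden pathways, where a 5% titer
error propagates to ~1.7×10⁻⁴ in d), and 10⁻¹–1 for conflictual ones.

For the joint co-culture calibration the default test topology gives
the downstream strain a small uptake bound (0.5 vs 10) so that
upstream-rich ratios leave it demand-limited and upstream-poor ratios
supply-limited.  This matters: if the downstream strain is
pool-limited at *every* measured ratio, only the product
`d_up·d_down` is identifiable and the joint fit sits on a ridge.  The
two-regime design is what makes the pair identifiable from two
ratios.

What passing these tests does **not** show about real data: toy
networks have no alternate pathways, cofactor coupling, maintenance
demands or byproduct secretion; the noise model ignores systematic
(non-multiplicative) measurement error; biomass is static, so
late-culture effects (lysis, stationary-phase expression shifts) are
outside the model.

## Known limitations

* Two strains only; the mapping constant is defined for a two-member
  consortium.
* No dynamic FBA: one mean flux solution per strain is scaled by `k`
  throughout the run (a per-step re-solve is deliberately out of
  scope; the single-`k` mapping is the method's point).
* No flux variability or alternate-optima enumeration; degenerate
  optima are only detected where they affect shadow prices.
* ΔrG'° values are taken as given (no group-contribution estimation,
  no uncertainty propagation).
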