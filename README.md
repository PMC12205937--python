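# coyield

Multi-constraint metabolic simulation and yield forecasting for
two-strain microbial consortia.

Engineered co-cultures split a biosynthesis pathway across two strains
— an upstream strain secretes an intermediate, a downstream strain
converts it into the product.  Predicting the consortium's titer is
hard because each strain balances its *biosynthesis task* against its
*growth interest*.  `coyield` models that trade-off explicitly through
the **pathway expression degree**

```
d = (v_nfeg − v_feg) / v_nfeg
```

the fractional growth-rate loss a strain suffers when its product
pathway is forced to express (`v_nfeg`, `v_feg`: maximum growth rates
without / with forced expression, h⁻¹).  The library is for metabolic
engineers and modelers who want to calibrate `d` from a handful of
titer measurements, forecast co-culture production across inoculum
ratios, and rank engineering levers — without dividing and re-merging
genome-scale networks.

## What it computes

1. **Constrained flux solves** (`coyield.optimize`).  Growth or
   production maximization over `S·v = 0` with flux bounds (FBA), an
   optional enzyme-pool cap `Σ vᵢ·MWᵢ/kcatᵢ ≤ pool`, and optional
   thermodynamic constraints: each pathway reaction *i* has a driving
   force `Dfᵢ = −(ΔrG'°ᵢ + RT·Sᵢᵀ ln C)`, a binary `zᵢ` with
   `vᵢ ≤ zᵢ·UBᵢ` and `Dfᵢ + (1−zᵢ)·K ≥ Df_min ≥ 0`, and concentration
   bounds `ln C_min ≤ ln C ≤ ln C_max`.  Objectives are lexicographic:
   biology first, then the pathway **max–min driving force** `B`
   (`Dfᵢ ≥ B` for active pathway reactions) is maximized at pinned
   biological optimum.  Solved with scipy's HiGHS backend.
2. **Pathway MDF reports** (`coyield.mdf`): `B`, bottleneck reactions
   (`Dfᵢ = B` at the optimum), and metabolite shadow prices — the
   sensitivity of `B` to each metabolite's allowed log-concentration,
   duals cross-checked against finite differences.
3. **Expression-degree calibration** (`coyield.calibration`): grid
   search over `d` with the growth floor `v_bio ≥ (1−d)·v_nfeg`,
   matching simulated to measured production; a joint two-degree mode
   fits co-culture titers at ≥2 inoculum ratios when mono-culture data
   are missing.
4. **Co-culture integration** (`coyield.coculture`): mean fluxes map
   to instantaneous fluxes via `k = Σ kⱼ·icrⱼ` with
   `kⱼ = C_initial/C̄` from the substrate depletion curve; production
   is integrated over `tp` steps of `Δt` with explicit pools for
   exchanged intermediates (secretion adds, uptake is capped at
   availability).
5. **Sensitivity ranking** (`coyield.sensitivity`):
   `puf = (C* − C)/(x* − x)` and `Rpuf = puf/C` for perturbed
   expression degrees (IBPE/DBPE) and mapping constants (ICSU).
6. **Fit metrics** (`coyield.metrics`): MRE, R² (`1 − SSres/SStot`),
   and a paired-t similarity P value (larger = more similar).

Models load from COBRA-style JSON or SBML (via cobrapy); ΔrG'° and
kcat/MW annotations attach from TSV tables.  `coyield.fixtures`
generates toy networks and synthetic measurements so everything is
runnable offline.

## Worked example

```python
from coyield import pathway_mdf, calibrate_degree
from coyield.fixtures import ToySpec, toy_model, synth_monoculture

model = toy_model(ToySpec(dG0_list=(-10.0, -10.0)))
report = pathway_mdf(model, ["C1", "C2"])
print(report.B, report.bottlenecks)

spec = ToySpec(true_d=0.25)
data = synth_monoculture(toy_model(spec), spec)
print(calibrate_degree(toy_model(spec), data).d)
```

prints

```
21.87 ['C1', 'C2']
0.25
```

The two-step chain's MDF is `B = −ΔrG'° + RT·ln(C_max/C_min)/2 =
21.87 kJ/mol`: the optimizer equalizes both driving forces, so both
reactions are bottlenecks.  The calibration recovers the generating
expression degree 0.25 exactly from the noise-free synthetic titer
(15 mM over 6 h at a 10 mmol·gDW⁻¹·h⁻¹ uptake).

Narrative scripts in `examples/` walk through each capability
(thermodynamic analysis, calibration, co-culture prediction,
sensitivity ranking); a thin CLI mirrors them
(`coyield demo`, `coyield mdf`, `coyield calibrate`, `coyield
predict`, `coyield sensitivity`).

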