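"""Synthetic toy networks and measurement data.

Everything the pipeline consumes — models, thermodynamic tables,
mono-culture depletion curves with measured titers, co-culture titer
sets — can be generated here, so the whole package is exercisable with
no external downloads.  Generators are bit-reproducible given the spec
and its seed.

The toy strain is a linear chain with a branch point::

    (uptake) → S → M1 → … → node ─→ biomass        (R_bio)
                               └──→ P → (export)   (R_prod, EX_prod)

with unit stoichiometry throughout.  Closed forms used by the tests:

* max growth = ``uptake_bound`` (the uptake is the only bottleneck);
* max production at growth floor g = ``uptake_bound − g``, so at
  expression degree d the production flux is exactly ``d·uptake_bound``;
* with an embedded reversible pair forced active the pathway MDF is 0
  (the two driving forces are exact negatives pinned at the minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import CocultureObservation, MonoCultureData
from .coculture import (CocultureSpec, Exchange, mapping_constant,
                        simulate_production, strain_state)
from .model import MetabolicModel, Metabolite, Reaction, ThermoConfig
from .optimize import SolveOptions

__all__ = ["ToySpec", "toy_model", "toy_pair", "synth_monoculture",
           "synth_coculture", "butanol_like_pathway_model"]


@dataclass
class ToySpec:
    """Parameters of one toy strain and its synthetic measurements."""

    n_chain: int = 2
    dG0_list: tuple[float, ...] | None = None  # kJ/mol per chain reaction
    kcat_list: tuple[float, ...] | None = None  # h⁻¹·g⁻¹ per chain reaction
    enzyme_pool: float | None = None  # g·gDW⁻¹
    uptake_bound: float = 10.0  # mmol·gDW⁻¹·h⁻¹
    include_reverse_pair: bool = False
    reverse_dG0: float = 5.0  # ΔrG'° of the forward member of the pair
    true_d: float | None = None  # generating expression degree
    noise_cv: float = 0.0  # multiplicative lognormal CV on titers
    seed: int = 0
    initial_substrate: float = 10.0  # g/L
    culture_duration: float = 6.0  # h
    tp: int = 60  # integrator steps over the horizon

    def __post_init__(self) -> None:
        if self.n_chain < 1:
            raise ValueError("n_chain must be ≥ 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for name in ("dG0_list", "kcat_list"):
            vals = getattr(self, name)
            if vals is not None and len(vals) != self.n_chain:
                raise ValueError(f"{name} must have n_chain={self.n_chain} entries")


def toy_model(spec: ToySpec, strain_id: str = "toy", *,
              substrate_met: str = "glc", product_met: str = "prod",
              ) -> MetabolicModel:
    """Build the chain toy strain described in the module docstring."""
    chain_mets = [substrate_met] + [f"m{i}" for i in range(1, spec.n_chain)] + ["node"]
    mets = [Metabolite(id=m) for m in chain_mets]
    mets.append(Metabolite(id=product_met))

    rxns = [Reaction(id="R_uptake", stoich={substrate_met: 1.0},
                     flux_ub=spec.uptake_bound, role="exchange")]
    for i in range(spec.n_chain):
        rxns.append(Reaction(
            id=f"C{i + 1}",
            stoich={chain_mets[i]: -1.0, chain_mets[i + 1]: 1.0},
            dG0_prime=None if spec.dG0_list is None else float(spec.dG0_list[i]),
            in_pathway=spec.dG0_list is not None,
            kcat=None if spec.kcat_list is None else float(spec.kcat_list[i]),
            mw=None if spec.kcat_list is None else 1.0,
        ))
    rxns.append(Reaction(id="R_bio", stoich={"node": -1.0}, role="biomass"))
    rxns.append(Reaction(id="R_prod", stoich={"node": -1.0, product_met: 1.0},
                         role="production"))
    rxns.append(Reaction(id=f"EX_{product_met}", stoich={product_met: -1.0},
                         role="exchange"))

    if spec.include_reverse_pair:
        mets.append(Metabolite(id="w"))
        rxns.append(Reaction(id="Rpair", stoich={"node": -1.0, "w": 1.0},
                             dG0_prime=spec.reverse_dG0, in_pathway=True))
        rxns.append(Reaction(id="Rpair_reverse",
                             stoich={"w": -1.0, "node": 1.0},
                             dG0_prime=-spec.reverse_dG0, in_pathway=True))
        rxns.append(Reaction(id="EX_w", stoich={"w": -1.0}, role="exchange"))

    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           strain_id=strain_id, enzyme_pool=spec.enzyme_pool)
    return model


def toy_pair(spec_up: ToySpec, spec_down: ToySpec, *,
             exchanged_met: str = "emet",
             substrate_met: str = "glc",
             product_met: str = "prod",
             ) -> tuple[MetabolicModel, MetabolicModel, list[Exchange]]:
    """Upstream/downstream pair cross-feeding one intermediate.

    The upstream strain's product *is* the exchanged metabolite; the
    downstream strain's carbon source is the exchanged metabolite and
    its product is the consortium product.
    """
    up = toy_model(spec_up, strain_id="up", substrate_met=substrate_met,
                   product_met=exchanged_met)
    down = toy_model(spec_down, strain_id="down", substrate_met=exchanged_met,
                     product_met=product_met)
    return up, down, [Exchange(producer=0, metabolite=exchanged_met, consumer=1)]


# ---------------------------------------------------------------------------
# synthetic measurements
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def _substrate_curve(spec: ToySpec) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-to-zero depletion on the integrator's time grid."""
    t = np.linspace(0.0, spec.culture_duration, spec.tp + 1)
    tau = spec.culture_duration / 3.0
    raw = np.exp(-t / tau)
    curve = spec.initial_substrate * (raw - raw[-1]) / (1.0 - raw[-1])
    return t, curve


def synth_monoculture(model: MetabolicModel, spec: ToySpec,
                      options: SolveOptions | None = None,
                      config: ThermoConfig | None = None,
                      biomass_density: float = 1.0) -> MonoCultureData:
    """Forward-simulate a mono-culture at ``spec.true_d``.

    Emits the substrate depletion curve on the integrator grid and a
    measured production with multiplicative lognormal noise of CV
    ``spec.noise_cv`` (deterministic under ``spec.seed``).
    """
    if spec.true_d is None:
        raise ValueError("spec.true_d must be set to generate measurements")
    rng = np.random.default_rng(spec.seed)
    state = strain_state(model, spec.true_d, options or SolveOptions(),
                         config or ThermoConfig())
    production = (state.production_flux * spec.culture_duration
                  * biomass_density * _lognormal_factor(rng, spec.noise_cv))
    times, conc = _substrate_curve(spec)
    return MonoCultureData(times=times, substrate_conc=conc,
                           measured_production=production)


def synth_coculture(model_up: MetabolicModel, model_down: MetabolicModel,
                    true_d: tuple[float, float],
                    ratios: list[tuple[float, float]],
                    exchange_map: list[Exchange],
                    k_per_strain: tuple[float, float] = (1.0, 1.0),
                    dt: float = 0.1, tp: int = 60,
                    noise_cv: float = 0.0, seed: int = 0,
                    options: SolveOptions | None = None,
                    config: ThermoConfig | None = None,
                    biomass_density: float = 1.0,
                    ) -> list[CocultureObservation]:
    """Emit measured co-culture titers at each inoculum ratio.

    Runs the forward pipeline at the known ``(d_up, d_down)`` so the
    datasets support joint-recovery tests of ``calibrate_from_coculture``.
    """
    rng = np.random.default_rng(seed)
    options = options or SolveOptions()
    config = config or ThermoConfig()
    s_up = strain_state(model_up, true_d[0], options, config)
    s_down = strain_state(model_down, true_d[1], options, config)
    out = []
    for icr in ratios:
        spec = CocultureSpec(strains=(s_up, s_down), icr=icr, dt=dt, tp=tp,
                             exchange_map=exchange_map,
                             biomass_density=biomass_density)
        total = simulate_production(
            spec, mapping_constant(k_per_strain, icr)).total
        out.append(CocultureObservation(
            icr=icr,
            measured_production=total * _lognormal_factor(rng, noise_cv),
            dt=dt, tp=tp, k_per_strain=k_per_strain))
    return out


# ---------------------------------------------------------------------------
# scenario-shaped pathway fixture
# ---------------------------------------------------------------------------

def butanol_like_pathway_model(pair_dG0: float = 15.0) -> tuple[MetabolicModel, list[str]]:
    """Synthetic stand-in for a combined butyrate + n-butanol pathway.

    A condensed acetyl-CoA chain (glucose → PEP → pyruvate → acetyl-CoA
    → acetoacetyl-CoA → 3-hydroxybutyryl-CoA → crotonyl-CoA →
    butyryl-CoA → butyrate / n-butanol) in which the CoA-transferase
    step ``atoDA`` appears together with its explicit reverse reaction,
    both carrying flux.  The ΔrG'° values are synthetic placeholders
    (each reaction individually feasible inside the default
    concentration box); the pathway MDF with both directions of the
    transferase forced active is 0 regardless of the value assigned to
    the pair.  Returns the model and the ordered pathway reaction ids.
    """
    chain = [
        ("glycolysis_1", "glc", "pep", -20.0),
        ("glycolysis_2", "pep", "pyr", -25.0),
        ("pdh", "pyr", "accoa", -30.0),
        ("phaA", "accoa", "aacoa", 10.0),
        ("hbd", "aacoa", "hbcoa", -15.0),
        ("crt", "hbcoa", "b2coa", -5.0),
        ("ter", "b2coa", "btcoa", -50.0),
        ("adhE2", "btcoa", "btoh", -20.0),
    ]
    met_ids = ["glc", "pep", "pyr", "accoa", "aacoa", "hbcoa", "b2coa",
               "btcoa", "btoh", "but"]
    mets = [Metabolite(id=m) for m in met_ids]
    rxns = [Reaction(id="EX_glc", stoich={"glc": 1.0}, flux_ub=10.0,
                     role="exchange")]
    for rid, sub, prod, dg in chain:
        rxns.append(Reaction(id=rid, stoich={sub: -1.0, prod: 1.0},
                             dG0_prime=dg, in_pathway=True))
    # CoA transferase and its explicit reverse: butyryl-CoA ↔ butyrate
    rxns.append(Reaction(id="atoDA", stoich={"btcoa": -1.0, "but": 1.0},
                         dG0_prime=pair_dG0, in_pathway=True))
    rxns.append(Reaction(id="atoDA_reverse", stoich={"but": -1.0, "btcoa": 1.0},
                         dG0_prime=-pair_dG0, in_pathway=True))
    rxns.append(Reaction(id="EX_btoh", stoich={"btoh": -1.0}, role="production"))
    rxns.append(Reaction(id="EX_but", stoich={"but": -1.0}, role="exchange"))
    rxns.append(Reaction(id="R_bio", stoich={"accoa": -1.0}, role="biomass"))

    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           strain_id="butanol_like_synthetic")
    pathway = [rid for rid, *_ in chain] + ["atoDA", "atoDA_reverse"]
    return model, pathway
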