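"""Pathway-level thermodynamic reporting.

``pathway_mdf`` computes the max–min driving force (MDF) of an ordered
set of reactions: the largest B such that every pathway reaction can
sustain a driving force of at least B within the metabolite
concentration box.  Reactions whose driving force equals B at the
optimum are the thermodynamic bottlenecks.

``shadow_prices`` reports the sensitivity of B to each metabolite's
allowed log-concentration window: a positive value means raising the
metabolite's admissible concentration raises the pathway MDF (typical
for bottleneck substrates), a negative value the opposite (bottleneck
products).  Duals of the concentration-bound constraints are used by
default and cross-checked against central finite differences on the
bounds; where the two disagree (degenerate optimum, non-unique duals)
the finite-difference value is reported and the metabolite flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .model import MetabolicModel, ThermoConfig
from .optimize import FluxSolution, SolveOptions, solve_mdf

__all__ = ["MdfReport", "InfeasiblePathway", "pathway_mdf", "shadow_prices"]

BOTTLENECK_TOL = 1e-6  # kJ/mol
FD_STEP = 1e-3  # ln-concentration step for finite differences
DUAL_FD_TOL = 1e-4  # kJ/mol agreement required before trusting duals


class InfeasiblePathway(RuntimeError):
    """The pathway admits no concentration assignment satisfying the
    minimum-driving-force requirement."""


@dataclass
class MdfReport:
    B: float
    driving_forces: dict[str, float]
    bottlenecks: list[str]
    shadow_prices: dict[str, float] = field(default_factory=dict)
    degenerate: set[str] = field(default_factory=set)
    solution: FluxSolution | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "B": self.B,
                "driving_forces": self.driving_forces,
                "bottlenecks": self.bottlenecks,
                "shadow_prices": self.shadow_prices,
                "degenerate": sorted(self.degenerate),
            }, fh, indent=1)

    def to_tsv(self, reactions_path, metabolites_path) -> None:
        import pandas as pd

        pd.DataFrame([
            {"reaction_id": rid, "driving_force": df,
             "bottleneck": rid in self.bottlenecks}
            for rid, df in self.driving_forces.items()
        ]).to_csv(reactions_path, sep="\t", index=False)
        pd.DataFrame([
            {"metabolite_id": m, "shadow_price": sp,
             "degenerate": m in self.degenerate}
            for m, sp in self.shadow_prices.items()
        ]).to_csv(metabolites_path, sep="\t", index=False)


def _prepare(model: MetabolicModel, pathway: list[str]) -> MetabolicModel:
    model = model.copy()
    for rid in pathway:
        rxn = model.reaction(rid)
        if rxn.dG0_prime is None:
            raise ValueError(f"pathway reaction {rid!r} has no dG0_prime")
        rxn.in_pathway = True
    return model


def _solve_B(model: MetabolicModel, pathway: list[str],
             config: ThermoConfig) -> FluxSolution:
    options = SolveOptions(use_thermo=True, objective="max_B")
    sol = solve_mdf(model, frozenset(pathway), options, config)
    if not sol.ok:
        raise InfeasiblePathway(
            f"MDF program {sol.status} for pathway {list(pathway)}")
    return sol


def pathway_mdf(model: MetabolicModel, pathway: list[str],
                config: ThermoConfig | None = None, *,
                bottleneck_tol: float = BOTTLENECK_TOL,
                with_shadow_prices: bool = True) -> MdfReport:
    """MDF, per-reaction driving forces and bottlenecks of a pathway.

    All ``pathway`` reactions are forced thermodynamically active; the
    result does not depend on their ordering.
    """
    config = config or ThermoConfig()
    work = _prepare(model, pathway)
    sol = _solve_B(work, pathway, config)
    dfs = {rid: sol.driving_forces[rid] for rid in pathway}
    bottlenecks = [rid for rid in pathway if abs(dfs[rid] - sol.B) <= bottleneck_tol]
    report = MdfReport(B=sol.B, driving_forces=dfs, bottlenecks=bottlenecks,
                       solution=sol)
    if with_shadow_prices:
        report.shadow_prices, report.degenerate = _shadow_prices_checked(
            work, pathway, config, sol)
    return report


def _fd_shadow_price(model: MetabolicModel, pathway: list[str],
                     config: ThermoConfig, met_id: str,
                     step: float = FD_STEP) -> float:
    """Central difference of B w.r.t. shifting both ln-conc bounds."""
    vals = []
    for sign in (+1.0, -1.0):
        shifted = model.copy()
        met = shifted.metabolite(met_id)
        met.ln_conc_lb += sign * step
        met.ln_conc_ub += sign * step
        vals.append(_solve_B(shifted, pathway, config).B)
    return (vals[0] - vals[1]) / (2 * step)


def _shadow_prices_checked(model: MetabolicModel, pathway: list[str],
                           config: ThermoConfig, sol: FluxSolution,
                           ) -> tuple[dict[str, float], set[str]]:
    duals = sol.ln_conc_duals or {}
    participating = set()
    for rid in pathway:
        for met_id in model.reaction(rid).stoich:
            if model.metabolite(met_id).thermo_tracked:
                participating.add(met_id)

    prices: dict[str, float] = {}
    degenerate: set[str] = set()
    for met in model.metabolites:
        if not met.thermo_tracked:
            continue
        if met.id not in participating:
            prices[met.id] = 0.0
            continue
        fd = _fd_shadow_price(model, pathway, config, met.id)
        dual = duals.get(met.id)
        if dual is None or abs(dual - fd) > DUAL_FD_TOL:
            prices[met.id] = fd
            degenerate.add(met.id)
        else:
            prices[met.id] = dual
    return prices, degenerate


def shadow_prices(model: MetabolicModel, pathway: list[str],
                  config: ThermoConfig | None = None,
                  method: str = "auto") -> dict[str, float]:
    """Shadow price of each tracked metabolite's concentration window.

    ``method``: ``"dual"`` (bound duals of the MDF LP), ``"fd"``
    (central finite differences on the bounds) or ``"auto"`` (duals
    cross-checked by finite differences; the finite-difference value is
    reported where they disagree).
    """
    config = config or ThermoConfig()
    work = _prepare(model, pathway)
    sol = _solve_B(work, pathway, config)
    if method == "auto":
        prices, _ = _shadow_prices_checked(work, pathway, config, sol)
        return prices
    participating = {
        met_id
        for rid in pathway
        for met_id in work.reaction(rid).stoich
        if work.metabolite(met_id).thermo_tracked
    }
    prices = {}
    for met in work.metabolites:
        if not met.thermo_tracked:
            continue
        if met.id not in participating:
            prices[met.id] = 0.0
        elif method == "fd":
            prices[met.id] = _fd_shadow_price(work, pathway, config, met.id)
        elif method == "dual":
            prices[met.id] = (sol.ln_conc_duals or {}).get(met.id, 0.0)
        else:
            raise ValueError(f"unknown method {method!r}")
    return prices
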