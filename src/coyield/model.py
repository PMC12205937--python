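"""Metabolic network representation and annotation I/O.

A :class:`MetabolicModel` holds the stoichiometry, flux bounds and the
thermodynamic / kinetic annotations of a single strain.  Models are read
from SBML (via cobrapy/libsbml) or from COBRA-style JSON; per-reaction
standard transformed Gibbs energies (ΔrG'°, kJ/mol) and enzyme
parameters (kcat, molecular weight) are attached from TSV tables.

Conventions
-----------
* Fluxes are in mmol·gDW⁻¹·h⁻¹, Gibbs energies in kJ/mol, metabolite
  concentrations as natural logs of molar values.
* Water and protons are excluded from all concentration terms: their
  contribution is already absorbed into the transformed standard Gibbs
  energy.  They are flagged ``thermo_tracked=False``.
* Reversible reactions that take part in a thermodynamically
  constrained pathway are split into two irreversible reactions; the
  backward copy carries a ``_reverse`` id suffix and the negated ΔrG'°.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ThermoConfig",
    "ModelFormatError",
    "ModelConfigError",
    "load_model",
    "save_model",
    "attach_thermo",
    "attach_kinetics",
    "DEFAULT_EXCLUDED_SPECIES",
]

#: metabolite base ids (compartment suffix stripped) that never contribute
#: concentration terms to a driving-force expression
DEFAULT_EXCLUDED_SPECIES = frozenset({"h2o", "h"})

#: default concentration window, 1 µM – 10 mM (standard MDF convention)
DEFAULT_LN_CONC_LB = math.log(1e-6)
DEFAULT_LN_CONC_UB = math.log(1e-2)

REVERSE_SUFFIX = "_reverse"

_BIOMASS_PATTERN = re.compile(r"biomass|_bio\b|^bio$", re.IGNORECASE)


class ModelFormatError(ValueError):
    """A model file does not parse under its declared standard."""


class ModelConfigError(ValueError):
    """A model is structurally valid but mis-configured for a task."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    ln_conc_lb: float = DEFAULT_LN_CONC_LB
    ln_conc_ub: float = DEFAULT_LN_CONC_UB
    thermo_tracked: bool = True

    def __post_init__(self) -> None:
        if self.ln_conc_lb > self.ln_conc_ub:
            raise ValueError(
                f"metabolite {self.id!r}: ln_conc_lb > ln_conc_ub "
                f"({self.ln_conc_lb} > {self.ln_conc_ub})"
            )


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    flux_lb: float = 0.0
    flux_ub: float = 1000.0
    dG0_prime: float | None = None
    kcat: float | None = None
    mw: float | None = None
    in_pathway: bool = False
    role: str = "internal"  # internal | exchange | biomass | production

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        if self.flux_lb > self.flux_ub:
            raise ValueError(
                f"reaction {self.id!r}: flux_lb > flux_ub "
                f"({self.flux_lb} > {self.flux_ub})"
            )
        if self.role not in {"internal", "exchange", "biomass", "production"}:
            raise ValueError(f"reaction {self.id!r}: unknown role {self.role!r}")


@dataclass
class MetabolicModel:
    """One strain: metabolites, reactions and per-reaction annotations."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    strain_id: str = "strain"
    enzyme_pool: float | None = None  # g enzyme · gDW⁻¹ for the kinetic cap

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def biomass_reaction(self) -> Reaction:
        for r in self.reactions:
            if r.role == "biomass":
                return r
        raise ModelConfigError(
            f"model {self.strain_id!r} has no biomass reaction designated"
        )

    def production_reaction(self) -> Reaction:
        for r in self.reactions:
            if r.role == "production":
                return r
        raise ModelConfigError(
            f"model {self.strain_id!r} has no production reaction designated"
        )

    def pathway_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.in_pathway]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ValueError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ValueError(
                    f"reaction {r.id!r} references undefined metabolites "
                    f"{sorted(missing)}"
                )
        n_bio = sum(1 for r in self.reactions if r.role == "biomass")
        if n_bio > 1:
            raise ValueError(f"model {self.strain_id!r} has {n_bio} biomass reactions")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[Metabolite(**asdict(m)) for m in self.metabolites],
            reactions=[
                Reaction(**{**asdict(r), "stoich": dict(r.stoich)})
                for r in self.reactions
            ],
            strain_id=self.strain_id,
            enzyme_pool=self.enzyme_pool,
        )


@dataclass(frozen=True)
class ThermoConfig:
    """Physical constants and tolerances of the thermodynamic constraint.

    ``big_K`` is the big-M constant that deactivates the minimum
    driving-force constraint for pathway reactions carrying no flux;
    ``df_min`` is the minimum driving force (kJ/mol) every *active*
    pathway reaction must achieve (≥ 0 by construction).
    """

    R: float = 8.314e-3  # kJ·mol⁻¹·K⁻¹
    T: float = 310.15  # K, E. coli culture temperature
    big_K: float = 1000.0  # kJ/mol
    df_min: float = 0.0  # kJ/mol
    default_ln_conc_lb: float = DEFAULT_LN_CONC_LB
    default_ln_conc_ub: float = DEFAULT_LN_CONC_UB

    def __post_init__(self) -> None:
        if self.big_K <= 0:
            raise ValueError("big_K must be positive")
        if self.df_min < 0:
            raise ValueError("df_min must be non-negative")
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def _base_species(met_id: str, compartment: str) -> str:
    base = met_id
    for suffix in (f"_{compartment}", f"[{compartment}]"):
        if compartment and base.endswith(suffix):
            base = base[: -len(suffix)]
    return base.lower()


def _detect_biomass(reactions: list[Reaction], objective_id: str | None,
                    biomass_id: str | None) -> None:
    if biomass_id is not None:
        for r in reactions:
            if r.id == biomass_id:
                r.role = "biomass"
                return
        raise ModelConfigError(f"designated biomass reaction {biomass_id!r} not found")
    if objective_id is not None:
        for r in reactions:
            if r.id == objective_id:
                r.role = "biomass"
                return
    for r in reactions:
        if _BIOMASS_PATTERN.search(r.id):
            r.role = "biomass"
            return
    raise ModelConfigError(
        "no biomass reaction: none designated, no objective, no id matching "
        "'biomass'"
    )


def load_model(path: str | Path, format: str | None = None, *,
               biomass_id: str | None = None,
               production_id: str | None = None,
               excluded_species: Iterable[str] = DEFAULT_EXCLUDED_SPECIES,
               ) -> MetabolicModel:
    """Read a metabolic model from SBML or COBRA-style JSON.

    The biomass reaction is taken from the model objective or an id
    matching ``biomass`` unless ``biomass_id`` overrides it.  Species
    in ``excluded_species`` (compartment suffix stripped; default water
    and protons) are marked ``thermo_tracked=False``.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        return _load_json(path, biomass_id, production_id, excluded_species)
    if format == "sbml":
        return _load_sbml(path, biomass_id, production_id, excluded_species)
    raise ValueError(f"unknown model format {format!r}")


def _load_json(path: Path, biomass_id, production_id, excluded) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level {key!r} array")

    ann = doc.get("coyield", {})
    met_ann: Mapping[str, dict] = ann.get("metabolites", {})
    rxn_ann: Mapping[str, dict] = ann.get("reactions", {})
    excluded = set(excluded)

    mets = []
    for m in doc["metabolites"]:
        try:
            mid, comp = m["id"], m.get("compartment", "c")
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"{path}: malformed metabolite entry {m!r}") from exc
        extra = met_ann.get(mid, {})
        # the excluded list wins over annotations: water/proton terms are
        # already absorbed into the transformed standard Gibbs energies
        tracked = (_base_species(mid, comp) not in excluded and
                   extra.get("thermo_tracked", True))
        mets.append(Metabolite(
            id=mid,
            name=m.get("name", ""),
            compartment=comp,
            ln_conc_lb=extra.get("ln_conc_lb", DEFAULT_LN_CONC_LB),
            ln_conc_ub=extra.get("ln_conc_ub", DEFAULT_LN_CONC_UB),
            thermo_tracked=tracked,
        ))

    objective_id = None
    rxns = []
    for r in doc["reactions"]:
        try:
            rid = r["id"]
            stoich = {k: float(v) for k, v in r["metabolites"].items()}
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"{path}: malformed reaction entry {r!r}") from exc
        if r.get("objective_coefficient", 0):
            objective_id = rid
        extra = rxn_ann.get(rid, {})
        role = extra.get("role", "internal")
        rxns.append(Reaction(
            id=rid,
            stoich=stoich,
            flux_lb=float(r.get("lower_bound", 0.0)),
            flux_ub=float(r.get("upper_bound", 1000.0)),
            dG0_prime=extra.get("dG0_prime"),
            kcat=extra.get("kcat"),
            mw=extra.get("mw"),
            in_pathway=extra.get("in_pathway", False),
            role=role,
        ))

    try:
        model = MetabolicModel(
            metabolites=mets, reactions=rxns,
            strain_id=doc.get("id", path.stem),
            enzyme_pool=ann.get("enzyme_pool"),
        )
    except ValueError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    if not any(r.role == "biomass" for r in model.reactions):
        _detect_biomass(model.reactions, objective_id, biomass_id)
    elif biomass_id is not None:
        for r in model.reactions:
            r.role = "biomass" if r.id == biomass_id else (
                "internal" if r.role == "biomass" else r.role)
    if production_id is not None:
        model.reaction(production_id).role = "production"
    return model


def _load_sbml(path: Path, biomass_id, production_id, excluded) -> MetabolicModel:
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises heterogeneous errors
        raise ModelFormatError(f"{path}: SBML parse failure ({exc})") from exc

    excluded = set(excluded)
    mets = [Metabolite(
        id=m.id, name=m.name or "", compartment=m.compartment or "c",
        thermo_tracked=_base_species(m.id, m.compartment or "") not in excluded,
    ) for m in cmodel.metabolites]

    objective_id = None
    try:
        expr = cmodel.objective.expression
        for rxn in cmodel.reactions:
            if expr.has(rxn.forward_variable) or expr.has(rxn.reverse_variable):
                objective_id = rxn.id
                break
    except Exception:
        pass

    rxns = [Reaction(
        id=r.id,
        stoich={m.id: coef for m, coef in r.metabolites.items()},
        flux_lb=r.lower_bound,
        flux_ub=r.upper_bound,
        role="exchange" if r.id.startswith("EX_") or r.boundary else "internal",
    ) for r in cmodel.reactions]

    model = MetabolicModel(metabolites=mets, reactions=rxns, strain_id=cmodel.id or path.stem)
    _detect_biomass(model.reactions, objective_id, biomass_id)
    if production_id is not None:
        model.reaction(production_id).role = "production"
    return model


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write COBRA-style JSON with a ``coyield`` annotation block.

    ``load_model(save_model(m))`` is the identity on every field of the
    internal representation.
    """
    doc = {
        "id": model.strain_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.stoich,
                "lower_bound": r.flux_lb,
                "upper_bound": r.flux_ub,
                "objective_coefficient": 1 if r.role == "biomass" else 0,
            }
            for r in model.reactions
        ],
        "coyield": {
            "enzyme_pool": model.enzyme_pool,
            "metabolites": {
                m.id: {
                    "ln_conc_lb": m.ln_conc_lb,
                    "ln_conc_ub": m.ln_conc_ub,
                    "thermo_tracked": m.thermo_tracked,
                }
                for m in model.metabolites
            },
            "reactions": {
                r.id: {
                    "dG0_prime": r.dG0_prime,
                    "kcat": r.kcat,
                    "mw": r.mw,
                    "in_pathway": r.in_pathway,
                    "role": r.role,
                }
                for r in model.reactions
            },
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def attach_thermo(model: MetabolicModel, table: str | Path | pd.DataFrame, *,
                  reverse_suffix: str = REVERSE_SUFFIX,
                  mark_in_pathway: bool = True,
                  atol: float = 1e-9) -> MetabolicModel:
    """Attach standard transformed Gibbs energies from a TSV table.

    Expected columns: ``reaction_id``, ``dG0_prime_kJ_mol`` and an
    optional boolean ``in_pathway``.  Listed reactions default to
    ``in_pathway=True``.  A reaction id ending in ``reverse_suffix``
    must carry the exact negation of its forward partner's ΔrG'°.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"reaction_id", "dG0_prime_kJ_mol"}
    if not required <= set(table.columns):
        raise ValueError(f"thermo table must have columns {sorted(required)}")

    model = model.copy()
    for row in table.itertuples(index=False):
        rid = str(row.reaction_id)
        try:
            rxn = model.reaction(rid)
        except KeyError:
            raise KeyError(f"thermo table references unknown reaction {rid!r}") from None
        rxn.dG0_prime = float(row.dG0_prime_kJ_mol)
        rxn.in_pathway = bool(getattr(row, "in_pathway", mark_in_pathway))

    for rxn in model.reactions:
        if not rxn.id.endswith(reverse_suffix) or rxn.dG0_prime is None:
            continue
        fwd_id = rxn.id[: -len(reverse_suffix)]
        try:
            fwd = model.reaction(fwd_id)
        except KeyError:
            continue
        if fwd.dG0_prime is None:
            continue
        if abs(fwd.dG0_prime + rxn.dG0_prime) > atol:
            raise ValueError(
                f"reverse pair {fwd_id!r}/{rxn.id!r}: ΔrG'° not negated "
                f"({fwd.dG0_prime} vs {rxn.dG0_prime})"
            )
    return model


def attach_kinetics(model: MetabolicModel, table: str | Path | pd.DataFrame,
                    enzyme_pool: float = 0.227,
                    saturation: float = 1.0) -> MetabolicModel:
    """Attach enzyme turnover numbers and molecular weights from TSV.

    Expected columns: ``reaction_id``, ``kcat_per_h_per_g``,
    ``mw_g_per_mmol``.  The enzyme-pool bound used by the kinetic
    constraint Σ v·MW/kcat ≤ pool·saturation is recorded on the model
    (default 0.227 g·gDW⁻¹ at full saturation).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"reaction_id", "kcat_per_h_per_g", "mw_g_per_mmol"}
    if not required <= set(table.columns):
        raise ValueError(f"kinetics table must have columns {sorted(required)}")

    model = model.copy()
    for row in table.itertuples(index=False):
        rid = str(row.reaction_id)
        kcat = float(row.kcat_per_h_per_g)
        mw = float(row.mw_g_per_mmol)
        if kcat <= 0 or mw <= 0:
            raise ValueError(
                f"reaction {rid!r}: kcat and mw must be positive "
                f"(got kcat={kcat}, mw={mw})"
            )
        rxn = model.reaction(rid)
        rxn.kcat = kcat
        rxn.mw = mw
    model.enzyme_pool = enzyme_pool * saturation
    return model
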