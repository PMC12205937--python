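"""Constrained flux optimization: FBA, enzyme-pool kinetics and the
max–min driving force (MDF) thermodynamic MILP.

The solution space of a strain is

* steady state ``S·v = 0`` with flux bounds (FBA),
* optionally an enzyme-pool cap ``Σ v_i·MW_i/kcat_i ≤ pool``,
* optionally the thermodynamic constraints: for every pathway reaction
  *i* a driving force ``Df_i = −(ΔrG'°_i + RT·Σ_m s_mi·ln C_m)`` over
  tracked metabolites, a binary ``z_i`` with ``v_i ≤ z_i·UB_i`` and
  ``Df_i + (1−z_i)·K ≥ Df_min ≥ 0``, and concentration bounds
  ``ln C_min ≤ ln C ≤ ln C_max``.  The pathway MDF ``B`` satisfies
  ``Df_i ≥ B`` for every active pathway reaction.

Objectives are handled lexicographically: the biological objective
(growth or production) is optimized first; with thermodynamics enabled
the binaries are then fixed, the objective is pinned to within
``lexicographic_tol`` and ``B`` is maximized, so the flux state is as
thermodynamically favorable as the biological optimum admits.

All solves run on scipy's HiGHS backend (``linprog`` for LPs, which
also yields the duals used for shadow prices, ``milp`` when binaries
are free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import MetabolicModel, ModelConfigError, ThermoConfig

__all__ = [
    "FluxSolution",
    "SolveOptions",
    "build_driving_forces",
    "fba_max_growth",
    "max_production",
    "solve_mdf",
]

_LP_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "failed"}


@dataclass
class SolveOptions:
    """Which constraint classes to apply and how to order objectives."""

    use_kinetic: bool = False
    use_thermo: bool = False
    objective: str = "max_growth"  # max_growth | max_production | max_B
    growth_lb: float | None = None
    lexicographic_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 <= self.lexicographic_tol < 1:
            raise ValueError("lexicographic_tol must be in [0, 1)")
        if self.objective not in {"max_growth", "max_production", "max_B"}:
            raise ValueError(f"unknown objective {self.objective!r}")

    @property
    def constraint_set(self) -> str:
        tag = "fba"
        if self.use_kinetic:
            tag += "+kin"
        if self.use_thermo:
            tag += "+thermo"
        return tag


@dataclass
class FluxSolution:
    """Optimum of one solve: mean fluxes, concentrations, driving forces."""

    fluxes: dict[str, float] = field(default_factory=dict)
    ln_conc: dict[str, float] = field(default_factory=dict)
    driving_forces: dict[str, float] = field(default_factory=dict)
    B: float | None = None
    z: dict[str, int] = field(default_factory=dict)
    objective_value: float = math.nan
    status: str = "failed"
    #: duals of the ln-concentration bounds at a B-maximizing LP optimum
    #: (met id -> dB/d ln_conc_lb + dB/d ln_conc_ub); None unless the final
    #: stage was an LP over concentrations
    ln_conc_duals: dict[str, float] | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {
                "reaction_id": rid,
                "flux": v,
                "driving_force": self.driving_forces.get(rid, ""),
                "z": self.z.get(rid, ""),
            }
            for rid, v in self.fluxes.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "objective": None if math.isnan(self.objective_value) else self.objective_value,
            "B": self.B,
            "status": self.status,
        }


def build_driving_forces(model: MetabolicModel, config: ThermoConfig,
                         ) -> dict[str, tuple[float, dict[str, float]]]:
    """Affine driving-force expressions ``Df_i = a_i + Σ_m b_im·ln C_m``.

    Returns ``{reaction_id: (a, {met_id: b})}`` with
    ``a = −ΔrG'°`` and ``b_m = −RT·s_mi`` over tracked metabolites only.
    """
    out = {}
    for rxn in model.reactions:
        if not rxn.in_pathway:
            continue
        if rxn.dG0_prime is None:
            raise ModelConfigError(
                f"pathway reaction {rxn.id!r} has no dG0_prime annotation")
        coefs = {
            met_id: -config.RT * s
            for met_id, s in rxn.stoich.items()
            if model.metabolite(met_id).thermo_tracked
        }
        out[rxn.id] = (-rxn.dG0_prime, coefs)
    return out


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

class _Program:
    """Incrementally assembled LP/MILP in ``A_eq x = b_eq, A_ub x ≤ b_ub``."""

    def __init__(self, model: MetabolicModel, options: SolveOptions,
                 config: ThermoConfig, required_active: frozenset[str],
                 include_B: bool, fixed_z: dict[str, int] | None = None):
        self.model = model
        self.options = options
        self.config = config

        self.rxn_ids = model.reaction_ids
        self.nv = len(self.rxn_ids)
        self.vidx = {rid: i for i, rid in enumerate(self.rxn_ids)}

        self.tracked: list[str] = []
        self.pathway: list[str] = []
        if options.use_thermo:
            self.pathway = [r.id for r in model.pathway_reactions()]
            used = set()
            for rid in self.pathway:
                for met_id in model.reaction(rid).stoich:
                    if model.metabolite(met_id).thermo_tracked:
                        used.add(met_id)
            self.tracked = [m for m in model.metabolite_ids if m in used]
        self.cidx = {m: self.nv + j for j, m in enumerate(self.tracked)}
        self.include_B = include_B and options.use_thermo and bool(self.pathway)
        self.bidx = self.nv + len(self.tracked) if self.include_B else None

        # binary bookkeeping: fixed (1 for required-active, or carried over
        # from a previous stage) vs free
        self.zfix: dict[str, int] = {}
        self.zfree: list[str] = []
        for rid in self.pathway:
            if fixed_z is not None:
                self.zfix[rid] = fixed_z.get(rid, 1)
            elif rid in required_active:
                self.zfix[rid] = 1
            else:
                self.zfree.append(rid)
        base = (self.bidx + 1) if self.bidx is not None else self.nv + len(self.tracked)
        self.zidx = {rid: base + k for k, rid in enumerate(self.zfree)}
        self.n = base + len(self.zfree)

        self.eq_rows: list[dict[int, float]] = []
        self.eq_b: list[float] = []
        self.ub_rows: list[dict[int, float]] = []
        self.ub_b: list[float] = []

        self.lb = np.full(self.n, -np.inf)
        self.ub = np.full(self.n, np.inf)
        self._flux_bounds()
        self._mass_balance()
        if options.use_kinetic:
            self._enzyme_pool()
        if options.use_thermo and self.pathway:
            self.df_expr = build_driving_forces(model, config)
            self._thermo_constraints()

    # -- constraint blocks ----------------------------------------------
    def _flux_bounds(self) -> None:
        for rid in self.rxn_ids:
            rxn = self.model.reaction(rid)
            i = self.vidx[rid]
            self.lb[i], self.ub[i] = rxn.flux_lb, rxn.flux_ub
        for m in self.tracked:
            met = self.model.metabolite(m)
            j = self.cidx[m]
            self.lb[j], self.ub[j] = met.ln_conc_lb, met.ln_conc_ub
        if self.bidx is not None:
            self.lb[self.bidx] = -self.config.big_K
            self.ub[self.bidx] = self.config.big_K
        for rid in self.zfree:
            k = self.zidx[rid]
            self.lb[k], self.ub[k] = 0.0, 1.0

    def _mass_balance(self) -> None:
        rows: dict[str, dict[int, float]] = {m: {} for m in self.model.metabolite_ids}
        for rid in self.rxn_ids:
            i = self.vidx[rid]
            for met_id, s in self.model.reaction(rid).stoich.items():
                rows[met_id][i] = rows[met_id].get(i, 0.0) + s
        for met_id, row in rows.items():
            if row:
                self.eq_rows.append(row)
                self.eq_b.append(0.0)

    def _enzyme_pool(self) -> None:
        row = {}
        for rid in self.rxn_ids:
            rxn = self.model.reaction(rid)
            if rxn.kcat is not None and rxn.mw is not None:
                row[self.vidx[rid]] = rxn.mw / rxn.kcat
        if not row:
            return
        pool = self.model.enzyme_pool
        if pool is None:
            raise ModelConfigError(
                "kinetic constraint requested but no enzyme pool recorded "
                "(use attach_kinetics)")
        self.ub_rows.append(row)
        self.ub_b.append(pool)

    def _z_coef(self, rid: str) -> tuple[float, int | None]:
        """Return (fixed value, None) or (nan, column) for reaction's z."""
        if rid in self.zfix:
            return float(self.zfix[rid]), None
        return math.nan, self.zidx[rid]

    def _thermo_constraints(self) -> None:
        K, df_min = self.config.big_K, self.config.df_min
        for rid in self.pathway:
            rxn = self.model.reaction(rid)
            a, coefs = self.df_expr[rid]
            i = self.vidx[rid]
            zval, zcol = self._z_coef(rid)

            # flux–binary coupling: v ≤ z·UB (and v ≥ z·LB when LB < 0)
            if zcol is None:
                self.ub_rows.append({i: 1.0})
                self.ub_b.append(zval * rxn.flux_ub)
                if rxn.flux_lb < 0:
                    self.ub_rows.append({i: -1.0})
                    self.ub_b.append(-zval * rxn.flux_lb)
            else:
                self.ub_rows.append({i: 1.0, zcol: -rxn.flux_ub})
                self.ub_b.append(0.0)
                if rxn.flux_lb < 0:
                    self.ub_rows.append({i: -1.0, zcol: rxn.flux_lb})
                    self.ub_b.append(0.0)

            # minimum driving force: Df + (1−z)·K ≥ df_min
            row = {self.cidx[m]: -b for m, b in coefs.items()}
            if zcol is None:
                self.ub_rows.append(dict(row))
                self.ub_b.append(a + K * (1.0 - zval) - df_min)
            else:
                row2 = dict(row)
                row2[zcol] = K
                self.ub_rows.append(row2)
                self.ub_b.append(a + K - df_min)

            # pathway MDF: Df + (1−z)·K ≥ B
            if self.bidx is not None:
                rowb = {self.cidx[m]: -b for m, b in coefs.items()}
                rowb[self.bidx] = 1.0
                if zcol is None:
                    self.ub_rows.append(rowb)
                    self.ub_b.append(a + K * (1.0 - zval))
                else:
                    rowb[zcol] = K
                    self.ub_rows.append(rowb)
                    self.ub_b.append(a + K)

    # -- extra rows ------------------------------------------------------
    def add_lower_bound(self, rid: str, value: float) -> None:
        self.ub_rows.append({self.vidx[rid]: -1.0})
        self.ub_b.append(-value)

    def add_objective_floor(self, c: np.ndarray, floor: float) -> None:
        row = {j: -c[j] for j in range(len(c)) if c[j] != 0.0}
        self.ub_rows.append(row)
        self.ub_b.append(-floor)

    # -- solve -----------------------------------------------------------
    def _matrices(self):
        def to_sparse(rows):
            data, ri, ci = [], [], []
            for r, row in enumerate(rows):
                for c, val in row.items():
                    ri.append(r)
                    ci.append(c)
                    data.append(val)
            return sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), self.n))

        return to_sparse(self.eq_rows), np.asarray(self.eq_b), \
            to_sparse(self.ub_rows), np.asarray(self.ub_b)

    def solve(self, c_max: np.ndarray):
        """Maximize ``c_max·x``; returns (status, x, objective, duals)."""
        A_eq, b_eq, A_ub, b_ub = self._matrices()
        if self.zfree:
            constraints = []
            if A_eq.shape[0]:
                constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
            if A_ub.shape[0]:
                constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))
            integrality = np.zeros(self.n)
            for rid in self.zfree:
                integrality[self.zidx[rid]] = 1
            res = milp(
                c=-c_max,
                constraints=constraints,
                bounds=Bounds(self.lb, self.ub),
                integrality=integrality,
            )
            status = _STATUS.get(res.status, "failed")
            if res.status == 0:
                return "optimal", res.x, float(c_max @ res.x), None
            return status, None, math.nan, None

        res = linprog(
            c=-c_max,
            A_ub=A_ub if A_ub.shape[0] else None,
            b_ub=b_ub if A_ub.shape[0] else None,
            A_eq=A_eq if A_eq.shape[0] else None,
            b_eq=b_eq if A_eq.shape[0] else None,
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
            options=dict(_LP_OPTIONS),
        )
        status = _STATUS.get(res.status, "failed")
        if res.status == 0:
            duals = None
            if res.lower is not None and res.upper is not None:
                # linprog minimizes -c·x: marginals are d(-obj)/d(bound)
                duals = (-np.asarray(res.lower.marginals),
                         -np.asarray(res.upper.marginals))
            return "optimal", res.x, float(c_max @ res.x), duals
        return status, None, math.nan, None

    # -- extraction ------------------------------------------------------
    def extract(self, x: np.ndarray, objective: float, status: str,
                duals=None) -> FluxSolution:
        sol = FluxSolution(status=status)
        if x is None:
            sol.status = status
            return sol
        sol.objective_value = objective
        sol.fluxes = {rid: float(x[self.vidx[rid]]) for rid in self.rxn_ids}
        sol.ln_conc = {m: float(x[self.cidx[m]]) for m in self.tracked}
        if self.options.use_thermo and self.pathway:
            for rid in self.pathway:
                a, coefs = self.df_expr[rid]
                sol.driving_forces[rid] = a + sum(
                    b * sol.ln_conc[m] for m, b in coefs.items())
            sol.z = dict(self.zfix)
            for rid in self.zfree:
                sol.z[rid] = int(round(x[self.zidx[rid]]))
        if self.bidx is not None:
            sol.B = float(x[self.bidx]) + 0.0  # normalize -0.0
        if duals is not None:
            lo, up = duals
            sol.ln_conc_duals = {
                m: float(lo[self.cidx[m]] + up[self.cidx[m]]) for m in self.tracked
            }
        return sol


def _objective_vector(prog: _Program, kind: str, rid: str | None = None) -> np.ndarray:
    c = np.zeros(prog.n)
    if kind == "B":
        if prog.bidx is None:
            raise ModelConfigError(
                "MDF objective requires thermodynamic constraints and a "
                "non-empty pathway")
        c[prog.bidx] = 1.0
    else:
        c[prog.vidx[rid]] = 1.0
    return c


def _lexicographic(model: MetabolicModel, options: SolveOptions,
                   config: ThermoConfig, primary_rid: str,
                   required_active: frozenset[str] = frozenset(),
                   growth_lb: float | None = None) -> FluxSolution:
    """Primary biological objective, then B with the objective pinned."""
    prog = _Program(model, options, config, required_active, include_B=False)
    if growth_lb is not None:
        prog.add_lower_bound(model.biomass_reaction().id, growth_lb)
    c1 = _objective_vector(prog, "flux", primary_rid)
    status, x, obj, _ = prog.solve(c1)
    if status != "optimal":
        sol = FluxSolution(status=status)
        return sol
    sol1 = prog.extract(x, obj, status)

    if not (options.use_thermo and model.pathway_reactions()):
        return sol1

    # stage 2: binaries frozen at stage-1 values, objective pinned, max B
    prog2 = _Program(model, options, config, required_active,
                     include_B=True, fixed_z=sol1.z)
    if growth_lb is not None:
        prog2.add_lower_bound(model.biomass_reaction().id, growth_lb)
    c1b = _objective_vector(prog2, "flux", primary_rid)
    floor = obj - options.lexicographic_tol * max(abs(obj), 1.0)
    prog2.add_objective_floor(c1b, floor)
    cB = _objective_vector(prog2, "B")
    status2, x2, objB, duals = prog2.solve(cB)
    if status2 != "optimal":  # numerically pinched pin: keep stage-1 answer
        return sol1
    sol2 = prog2.extract(x2, objB, status2, duals)
    sol2.objective_value = float(c1b @ x2)
    return sol2


# ---------------------------------------------------------------------------
# public solves
# ---------------------------------------------------------------------------

def fba_max_growth(model: MetabolicModel, options: SolveOptions | None = None,
                   config: ThermoConfig | None = None) -> FluxSolution:
    """Maximize growth under the selected constraint classes.

    With thermodynamics enabled the binaries are chosen by the MILP and
    a second LP stage maximizes the pathway MDF ``B`` at (essentially)
    unchanged growth.
    """
    options = options or SolveOptions()
    config = config or ThermoConfig()
    bio = model.biomass_reaction()
    return _lexicographic(model, options, config, bio.id)


def max_production(model: MetabolicModel, growth_lb: float,
                   options: SolveOptions | None = None,
                   config: ThermoConfig | None = None) -> FluxSolution:
    """Maximize the production flux subject to ``v_bio ≥ growth_lb``."""
    if growth_lb < 0:
        raise ValueError("growth_lb must be non-negative")
    options = options or SolveOptions()
    config = config or ThermoConfig()
    prod = model.production_reaction()
    return _lexicographic(model, options, config, prod.id, growth_lb=growth_lb)


def solve_mdf(model: MetabolicModel, required_active: set[str] | frozenset[str],
              options: SolveOptions | None = None,
              config: ThermoConfig | None = None) -> FluxSolution:
    """Maximize the pathway max–min driving force ``B``.

    ``required_active`` reactions are forced on (``z=1``); remaining
    pathway binaries are left to the solver.  When every pathway
    reaction is forced the problem reduces to a pure LP over the
    log-concentrations, whose bound duals are reported for shadow-price
    analysis.  With ``options.objective`` set to ``max_growth`` or
    ``max_production`` the solve is lexicographic instead.
    """
    options = options or SolveOptions(use_thermo=True, objective="max_B")
    config = config or ThermoConfig()
    required_active = frozenset(required_active)
    for rid in required_active:
        rxn = model.reaction(rid)
        if not rxn.in_pathway or rxn.dG0_prime is None:
            raise ModelConfigError(
                f"required-active reaction {rid!r} is not a thermodynamically "
                "annotated pathway reaction")
    if not options.use_thermo:
        options = SolveOptions(**{**options.__dict__, "use_thermo": True})

    if options.objective in {"max_growth", "max_production"}:
        rid = (model.biomass_reaction() if options.objective == "max_growth"
               else model.production_reaction()).id
        return _lexicographic(model, options, config, rid,
                              required_active=required_active,
                              growth_lb=options.growth_lb)

    prog = _Program(model, options, config, required_active, include_B=True)
    cB = _objective_vector(prog, "B")
    status, x, obj, duals = prog.solve(cB)
    return prog.extract(x, obj, status, duals)
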