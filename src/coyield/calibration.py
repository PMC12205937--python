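"""Calibration of biosynthesis-pathway expression degrees.

The expression degree ``d`` quantifies the growth penalty of forcing a
biosynthesis pathway to express:

    d = (v_nfeg − v_feg) / v_nfeg,

where ``v_nfeg`` is the unconstrained (wild) maximum growth rate and
``v_feg`` the growth rate with forced expression.  Calibration runs
the mono-culture pipeline in reverse: scan ``d`` over a grid, impose
the growth floor ``v_bio ≥ (1−d)·v_nfeg``, maximize production, and
keep the ``d`` whose simulated culture production best matches the
measured titer.  When mono-culture data are unavailable the two
degrees of a consortium are fitted jointly against co-culture titers
measured at two or more inoculum ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .coculture import (CocultureSpec, Exchange, mapping_constant,
                        simulate_production, strain_state)
from .model import MetabolicModel, ThermoConfig
from .optimize import SolveOptions, fba_max_growth, max_production

__all__ = [
    "ExpressionDegree",
    "MonoCultureData",
    "CocultureObservation",
    "CalibrationError",
    "compute_degree",
    "calibrate_degree",
    "calibrate_from_coculture",
]

COARSE_STEP = 1e-2
GRID_STEP = 1e-4


class CalibrationError(RuntimeError):
    """No grid point produced a feasible simulation."""


@dataclass
class ExpressionDegree:
    d: float
    v_nfeg: float
    v_feg: float
    constraint_set: str = "fba"
    residual: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0 + 1e-12:
            raise ValueError(f"expression degree {self.d} outside [0, 1]")

    @property
    def v_dec(self) -> float:
        return self.v_nfeg - self.v_feg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "d": self.d, "v_nfeg": self.v_nfeg, "v_feg": self.v_feg,
                "v_dec": self.v_dec, "constraint_set": self.constraint_set,
                "residual": self.residual,
            }, fh, indent=1)


@dataclass
class MonoCultureData:
    """Measured mono-culture inputs: substrate curve and product titer."""

    times: np.ndarray  # h
    substrate_conc: np.ndarray  # g/L
    measured_production: float  # concentration units of the product
    initial_substrate: float | None = None
    culture_duration: float | None = None
    production_unit: str = "mM"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        if self.times.shape != self.substrate_conc.shape:
            raise ValueError("times and substrate_conc must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.substrate_conc < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if self.initial_substrate is None:
            self.initial_substrate = float(self.substrate_conc[0])
        elif abs(self.initial_substrate - self.substrate_conc[0]) > 1e-9:
            raise ValueError(
                "initial_substrate must equal the substrate concentration "
                "at time 0")
        if self.culture_duration is None:
            self.culture_duration = float(self.times[-1] - self.times[0])

    @classmethod
    def from_tsv(cls, path, measured_production: float, **kw) -> "MonoCultureData":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(times=df["time"].to_numpy(),
                   substrate_conc=df["substrate_conc"].to_numpy(),
                   measured_production=measured_production, **kw)


def compute_degree(v_nfeg: float, v_feg: float,
                   constraint_set: str = "fba") -> ExpressionDegree:
    """``d = (v_nfeg − v_feg)/v_nfeg`` for directly measured growth rates."""
    if v_nfeg <= 0:
        raise ValueError("v_nfeg must be positive")
    if v_feg < 0 or v_feg > v_nfeg:
        raise ValueError(
            "v_feg must lie in [0, v_nfeg]: growth gain under forced "
            "expression is outside the model")
    d = (v_nfeg - v_feg) / v_nfeg
    return ExpressionDegree(d=d, v_nfeg=v_nfeg, v_feg=v_feg,
                            constraint_set=constraint_set)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.clip(np.round(lo + step * np.arange(n + 1), 12), 0.0, 1.0)


def _refinement_steps(coarse: float, fine: float) -> list[float]:
    steps = [coarse]
    while steps[-1] > fine * (1 + 1e-9):
        steps.append(max(fine, steps[-1] / 10.0))
    return steps


def calibrate_degree(model: MetabolicModel, data: MonoCultureData,
                     options: SolveOptions | None = None,
                     config: ThermoConfig | None = None,
                     grid_step: float = GRID_STEP,
                     coarse_step: float = COARSE_STEP,
                     biomass_density: float = 1.0) -> ExpressionDegree:
    """Fit the expression degree to a measured mono-culture titer.

    The scan is coarse-to-fine (default 10⁻² then 10⁻⁴ around the best
    coarse point); ties break toward the smaller ``d``.  Simulated
    production is ``v_production·duration·density`` at the growth floor
    ``(1−d)·v_nfeg``.
    """
    options = options or SolveOptions()
    config = config or ThermoConfig()
    base = fba_max_growth(model, options, config)
    if not base.ok:
        raise CalibrationError(f"growth solve {base.status}")
    v_nfeg = base.objective_value
    prod_id = model.production_reaction().id
    duration = data.culture_duration

    cache: dict[float, float | None] = {}

    def simulated(d: float) -> float | None:
        if d not in cache:
            sol = max_production(model, (1.0 - d) * v_nfeg, options, config)
            cache[d] = (sol.fluxes[prod_id] * duration * biomass_density
                        if sol.ok else None)
        return cache[d]

    best_d, best_res = None, math.inf
    lo, hi = 0.0, 1.0
    for step in _refinement_steps(coarse_step, grid_step):
        for d in _grid(lo, hi, step):
            sim = simulated(float(d))
            if sim is None:
                continue
            res = abs(sim - data.measured_production)
            if res < best_res - 1e-15 or best_d is None:
                best_d, best_res = float(d), res
        if best_d is None:
            raise CalibrationError("every grid point was infeasible")
        lo, hi = max(0.0, best_d - step), min(1.0, best_d + step)

    return ExpressionDegree(
        d=best_d, v_nfeg=v_nfeg, v_feg=(1.0 - best_d) * v_nfeg,
        constraint_set=options.constraint_set, residual=best_res)


# ---------------------------------------------------------------------------
# co-culture-only regime
# ---------------------------------------------------------------------------

@dataclass
class CocultureObservation:
    """One co-culture experiment: ratio, time grid and measured titer."""

    icr: tuple[float, float]
    measured_production: float
    dt: float
    tp: int
    k_per_strain: tuple[float, float] = (1.0, 1.0)
    substrate_supply: float | None = None


def calibrate_from_coculture(model_up: MetabolicModel,
                             model_down: MetabolicModel,
                             datasets: list[CocultureObservation],
                             options: SolveOptions | None = None,
                             config: ThermoConfig | None = None,
                             grid_step: float = GRID_STEP,
                             coarse_step: float = COARSE_STEP,
                             exchange_map: list[Exchange] | None = None,
                             substrate_mets: tuple[str | None, str | None] = (None, None),
                             biomass_density: float = 1.0,
                             objective: str = "relative",
                             ) -> tuple[ExpressionDegree, ExpressionDegree]:
    """Jointly fit (d_up, d_down) to titers at several inoculum ratios.

    Minimizes the sum over datasets of the relative (default) or
    absolute error between simulated and measured production; ties
    break lexicographically toward the smaller pair.  Per-strain flux
    solves are cached per grid value of ``d``, so the joint scan costs
    one cheap integration per candidate pair.
    """
    if len(datasets) < 2:
        raise ValueError(
            "joint calibration needs at least two co-culture datasets "
            "(distinct inoculum ratios); the problem is underdetermined")
    if len({obs.icr for obs in datasets}) < 2:
        raise ValueError("datasets must have distinct inoculum ratios")
    if objective not in {"relative", "absolute"}:
        raise ValueError(f"unknown objective {objective!r}")

    options = options or SolveOptions()
    config = config or ThermoConfig()
    exchange_map = exchange_map or []
    models = (model_up, model_down)
    v_nfeg = []
    for m in models:
        sol = fba_max_growth(m, options, config)
        if not sol.ok:
            raise CalibrationError(f"growth solve {sol.status} for {m.strain_id!r}")
        v_nfeg.append(sol.objective_value)

    caches: list[dict[float, object]] = [{}, {}]

    def state(j: int, d: float):
        if d not in caches[j]:
            try:
                caches[j][d] = strain_state(
                    models[j], d, options, config,
                    substrate_met=substrate_mets[j], v_nfeg=v_nfeg[j])
            except RuntimeError:
                caches[j][d] = None
        return caches[j][d]

    def loss(d_up: float, d_down: float) -> float | None:
        s_up, s_down = state(0, d_up), state(1, d_down)
        if s_up is None or s_down is None:
            return None
        total = 0.0
        for obs in datasets:
            spec = CocultureSpec(
                strains=(s_up, s_down), icr=obs.icr, dt=obs.dt, tp=obs.tp,
                exchange_map=exchange_map,
                substrate_supply=obs.substrate_supply,
                biomass_density=biomass_density)
            sim = simulate_production(
                spec, mapping_constant(obs.k_per_strain, obs.icr)).total
            err = abs(sim - obs.measured_production)
            if objective == "relative":
                err /= max(abs(obs.measured_production), 1e-12)
            total += err
        return total

    best, best_loss = None, math.inf
    lo = [0.0, 0.0]
    hi = [1.0, 1.0]
    for step in _refinement_steps(coarse_step, grid_step):
        for du in _grid(lo[0], hi[0], step):
            for dd in _grid(lo[1], hi[1], step):
                val = loss(float(du), float(dd))
                if val is None:
                    continue
                if val < best_loss - 1e-15 or best is None:
                    best, best_loss = (float(du), float(dd)), val
        if best is None:
            raise CalibrationError("every grid point was infeasible")
        lo = [max(0.0, best[0] - step), max(0.0, best[1] - step)]
        hi = [min(1.0, best[0] + step), min(1.0, best[1] + step)]

    degs = []
    for j, d in enumerate(best):
        degs.append(ExpressionDegree(
            d=d, v_nfeg=v_nfeg[j], v_feg=(1.0 - d) * v_nfeg[j],
            constraint_set=options.constraint_set, residual=best_loss))
    return degs[0], degs[1]
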