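"""Two-strain co-culture production prediction by discrete-time flux
integration.

Mean fluxes obtained from a calibrated mono-culture solve are mapped
to instantaneous co-culture fluxes by a scalar mapping constant
``k = Σ_j k_j·icr_j`` where ``k_j`` is the ratio of the initial to the
time-averaged carbon-source concentration of strain *j* and ``icr_j``
its inoculum fraction.  Production is then integrated over ``tp``
steps of width ``Δt``: at each step every strain contributes its
instantaneous production flux, weighted by its inoculum fraction, and
exchanged intermediates are tracked as explicit pools — producer
secretion adds to the pool, consumer uptake is capped at what the pool
holds, and a capped consumer's fluxes are scaled down proportionally
in that step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, ThermoConfig
from .optimize import FluxSolution, SolveOptions, fba_max_growth, max_production

__all__ = [
    "MappingConstant",
    "StrainState",
    "Exchange",
    "CocultureSpec",
    "ProductionPrediction",
    "mapping_multiplier",
    "mapping_constant",
    "strain_state",
    "simulate_production",
]

_ICR_TOL = 1e-9


@dataclass(frozen=True)
class MappingConstant:
    """Mean-to-instantaneous flux mapping: ``k = Σ_j k_j·icr_j``."""

    k_per_strain: tuple[float, ...]
    icr: tuple[float, ...]
    k: float


def mapping_multiplier(initial: float, times, conc) -> float:
    """Multiplicity ``k_j`` = initial / time-averaged substrate concentration.

    The time average is the trapezoid integral of the measured
    concentration series divided by the horizon.
    """
    if initial <= 0:
        raise ValueError("initial substrate concentration must be positive")
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.shape != conc.shape or times.size < 2:
        raise ValueError("times and concentrations must be equal-length series (n ≥ 2)")
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("time series must span a positive duration")
    mean_conc = float(np.trapezoid(conc, times)) / span
    if mean_conc <= 0:
        raise ValueError(
            "time-averaged substrate concentration is zero; the depletion "
            "record is degenerate — apply a small concentration floor")
    return initial / mean_conc


def mapping_constant(k_per_strain, icr, *, normalize: bool = False) -> MappingConstant:
    """Combine per-strain multiplicities with inoculum fractions."""
    k_per_strain = tuple(float(x) for x in k_per_strain)
    icr = tuple(float(x) for x in icr)
    if len(k_per_strain) != len(icr):
        raise ValueError("k_per_strain and icr must have equal length")
    total = sum(icr)
    if abs(total - 1.0) > _ICR_TOL:
        if not normalize:
            raise ValueError(
                f"inoculum fractions sum to {total}, not 1; pass "
                "normalize=True to rescale them")
        icr = tuple(x / total for x in icr)
    k = sum(kj * fj for kj, fj in zip(k_per_strain, icr))
    return MappingConstant(k_per_strain=k_per_strain, icr=icr, k=k)


@dataclass
class StrainState:
    """A strain with its calibrated expression degree and mean fluxes."""

    model: MetabolicModel
    d: float
    v_nfeg: float
    solution: FluxSolution
    substrate_met: str | None = None  # environment carbon source id

    @property
    def production_flux(self) -> float:
        return self.solution.fluxes[self.model.production_reaction().id]

    def env_rate(self, met_id: str) -> float:
        """Net release rate of ``met_id`` to the environment
        (mmol·gDW⁻¹·h⁻¹; negative = uptake), summed over exchange
        reactions."""
        rate = 0.0
        for rxn in self.model.reactions:
            if rxn.role != "exchange":
                continue
            s = rxn.stoich.get(met_id)
            if s is not None:
                rate -= s * self.solution.fluxes[rxn.id]
        return rate


def strain_state(model: MetabolicModel, d: float,
                 options: SolveOptions | None = None,
                 config: ThermoConfig | None = None,
                 substrate_met: str | None = None,
                 v_nfeg: float | None = None) -> StrainState:
    """Solve a strain's mean fluxes at expression degree ``d``.

    Growth without forced expression is maximized first; production is
    then maximized with the growth floor ``(1−d)·v_nfeg``.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("expression degree must lie in [0, 1]")
    options = options or SolveOptions()
    config = config or ThermoConfig()
    if v_nfeg is None:
        base = fba_max_growth(model, options, config)
        if not base.ok:
            raise RuntimeError(f"growth solve {base.status} for {model.strain_id!r}")
        v_nfeg = base.objective_value
    sol = max_production(model, (1.0 - d) * v_nfeg, options, config)
    if not sol.ok:
        raise RuntimeError(f"production solve {sol.status} for {model.strain_id!r}")
    return StrainState(model=model, d=d, v_nfeg=v_nfeg, solution=sol,
                       substrate_met=substrate_met)


@dataclass(frozen=True)
class Exchange:
    producer: int  # strain index secreting the metabolite
    metabolite: str
    consumer: int  # strain index taking it up


@dataclass
class CocultureSpec:
    """Two strains, a time grid and the cross-feeding topology."""

    strains: tuple[StrainState, StrainState]
    icr: tuple[float, float]
    dt: float
    tp: int
    exchange_map: list[Exchange] = field(default_factory=list)
    substrate_supply: float | None = None  # mM cap on total substrate use
    biomass_density: float = 1.0  # gDW·L⁻¹, converts fluxes to mM/h
    horizon: float | None = None  # calibrated culture duration, for checking

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tp < 1:
            raise ValueError("tp must be at least 1")
        if abs(sum(self.icr) - 1.0) > _ICR_TOL:
            raise ValueError("inoculum fractions must sum to 1")
        for ex in self.exchange_map:
            if ex.producer not in (0, 1) or ex.consumer not in (0, 1):
                raise ValueError("exchange strain indices must be 0 or 1")


@dataclass
class ProductionPrediction:
    per_step: list[float]
    total: float
    exchange_pools: dict[str, list[float]]
    substrate_consumed: float
    steps_run: int
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "total": self.total,
                "steps_run": self.steps_run,
                "substrate_consumed": self.substrate_consumed,
                "warnings": self.warnings,
            }, fh, indent=1)

    def to_tsv(self, path, dt: float) -> None:
        import pandas as pd

        rows = []
        for t, cp in enumerate(self.per_step):
            row = {"step": t + 1, "time": (t + 1) * dt, "step_production": cp}
            for met, series in self.exchange_pools.items():
                row[f"pool_{met}"] = series[t]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _product_strains(spec: CocultureSpec) -> list[int]:
    """Strains whose designated product is not an exchanged intermediate.

    A strain whose production reaction makes a metabolite it passes to
    the partner contributes to the consortium total through the pool,
    not directly.
    """
    fed = {(ex.producer, ex.metabolite) for ex in spec.exchange_map}
    out = []
    for j, strain in enumerate(spec.strains):
        prod = strain.model.production_reaction()
        made = {m for m, s in prod.stoich.items() if s > 0}
        if any((j, m) in fed for m in made):
            continue
        out.append(j)
    return out


def simulate_production(spec: CocultureSpec, k: MappingConstant | float,
                        *, cap_uptake: bool = True) -> ProductionPrediction:
    """Integrate consortium production over the co-culture horizon.

    Instantaneous fluxes are ``k`` times the mean fluxes; each strain's
    step contribution is weighted by its inoculum fraction and
    converted to concentration units by the biomass density.  With
    ``cap_uptake`` disabled the pools may go negative and the first
    violating step is recorded in ``warnings`` (diagnostic mode).
    """
    kval = k.k if isinstance(k, MappingConstant) else float(k)
    if kval <= 0:
        raise ValueError("mapping constant must be positive")
    dens = spec.biomass_density
    warnings: list[str] = []
    if spec.horizon is not None and abs(spec.dt * spec.tp - spec.horizon) > 1e-9:
        warnings.append(
            f"tp*dt = {spec.dt * spec.tp} h differs from the calibrated "
            f"horizon {spec.horizon} h")

    product_idx = _product_strains(spec)
    pools = {ex.metabolite: 0.0 for ex in spec.exchange_map}
    pool_series: dict[str, list[float]] = {m: [] for m in pools}
    per_step: list[float] = []
    substrate_used = 0.0
    first_violation: int | None = None

    # per-strain static rates (mmol·gDW⁻¹·h⁻¹)
    prod_flux = [s.production_flux for s in spec.strains]
    sub_flux = [
        max(0.0, -s.env_rate(s.substrate_met)) if s.substrate_met else 0.0
        for s in spec.strains
    ]

    steps_run = 0
    for t in range(spec.tp):
        scale = [1.0, 1.0]
        for ex in spec.exchange_map:
            p, c = ex.producer, ex.consumer
            sec = max(0.0, spec.strains[p].env_rate(ex.metabolite))
            dem = max(0.0, -spec.strains[c].env_rate(ex.metabolite))
            pools[ex.metabolite] += kval * sec * spec.icr[p] * dens * scale[p] * spec.dt
            demand = kval * dem * spec.icr[c] * dens * scale[c] * spec.dt
            if demand > 0:
                if cap_uptake:
                    realized = min(demand, pools[ex.metabolite])
                    scale[c] *= realized / demand
                else:
                    realized = demand
                    if pools[ex.metabolite] - realized < -1e-12 and first_violation is None:
                        first_violation = t + 1
                pools[ex.metabolite] -= realized

        step_prod = sum(
            kval * prod_flux[j] * spec.icr[j] * dens * scale[j] * spec.dt
            for j in product_idx
        )
        step_sub = sum(
            kval * sub_flux[j] * spec.icr[j] * dens * scale[j] * spec.dt
            for j in (0, 1)
        )

        if spec.substrate_supply is not None and step_sub > 0 and \
                substrate_used + step_sub >= spec.substrate_supply - 1e-12:
            frac = max(0.0, spec.substrate_supply - substrate_used) / step_sub
            per_step.append(step_prod * frac)
            substrate_used = spec.substrate_supply
            for m in pools:
                pool_series[m].append(pools[m])
            steps_run = t + 1
            warnings.append(
                f"substrate supply exhausted at step {t + 1} of {spec.tp}")
            break

        substrate_used += step_sub
        per_step.append(step_prod)
        for m in pools:
            pool_series[m].append(pools[m])
        steps_run = t + 1

    if first_violation is not None:
        warnings.append(
            f"exchange pool first went negative at step {first_violation} "
            "(uptake capping disabled)")

    return ProductionPrediction(
        per_step=per_step,
        total=float(sum(per_step)),
        exchange_pools=pool_series,
        substrate_consumed=substrate_used,
        steps_run=steps_run,
        warnings=warnings,
    )
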