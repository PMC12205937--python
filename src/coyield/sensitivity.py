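"""Sensitivity-based ranking of metabolic-engineering levers.

For a feature ``x`` (a strain's pathway expression degree or a
mean-to-instantaneous flux mapping multiplier) perturbed to ``x*``,
the production response is summarized by

    puf  = (C* − C)/(x* − x)          (production units per feature unit)
    Rpuf = puf / C                    (per-unit relative change multiple)

Features follow the field's shorthand: IBPE/DBPE = increasing /
decreasing a strain's biosynthesis-pathway expression degree, ICSU =
increasing carbon-source utilization (raising a strain's mapping
multiplier).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

from .coculture import (CocultureSpec, MappingConstant, mapping_constant,
                        simulate_production, strain_state)
from .model import ThermoConfig
from .optimize import SolveOptions

__all__ = ["SensitivityResult", "FEATURES", "evaluate_feature", "rank_strategies"]

#: recognized feature ids: perturb a strain's expression degree up/down,
#: the global mapping constant, or one strain's mapping multiplier
FEATURES = ("d_up+", "d_up-", "d_down+", "d_down-", "k+", "k_up+", "k_down+")

_LABELS = {
    "d_up+": "IBPE(up)", "d_down+": "IBPE(down)",
    "d_up-": "DBPE(up)", "d_down-": "DBPE(down)",
    "k+": "ICSU", "k_up+": "ICSU(up)", "k_down+": "ICSU(down)",
}


@dataclass
class SensitivityResult:
    feature: str
    x: float
    x_star: float
    C: float
    C_star: float
    puf: float
    Rpuf: float
    status: str = "ok"  # ok | infeasible

    @property
    def label(self) -> str:
        return _LABELS.get(self.feature, self.feature)


def _perturbed_spec(spec: CocultureSpec, j: int, d_star: float,
                    options: SolveOptions, config: ThermoConfig) -> CocultureSpec:
    old = spec.strains[j]
    new = strain_state(old.model, d_star, options, config,
                       substrate_met=old.substrate_met, v_nfeg=old.v_nfeg)
    strains = (new, spec.strains[1]) if j == 0 else (spec.strains[0], new)
    return replace(spec, strains=strains)


def evaluate_feature(spec: CocultureSpec, k: MappingConstant, feature: str,
                     delta: float = 0.1,
                     options: SolveOptions | None = None,
                     config: ThermoConfig | None = None) -> SensitivityResult:
    """Forward-difference production sensitivity of one feature.

    ``delta`` is the relative perturbation (``x* = x·(1 ± δ)``); the
    full pipeline is re-run at the perturbed value — the strain's flux
    LP for degree features, the integrator alone for mapping features.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    if delta == 0:
        raise ValueError("delta must be nonzero (zero denominator in puf)")
    options = options or SolveOptions()
    config = config or ThermoConfig()

    C = simulate_production(spec, k).total

    if feature.startswith("d_"):
        j = 0 if feature.startswith("d_up") else 1
        sign = 1.0 if feature.endswith("+") else -1.0
        x = spec.strains[j].d
        x_star = x * (1.0 + sign * delta)
        if not 0.0 <= x_star <= 1.0:
            raise ValueError(
                f"perturbed degree {x_star} outside [0, 1] for {feature!r}")
        try:
            spec_star = _perturbed_spec(spec, j, x_star, options, config)
        except RuntimeError:
            return SensitivityResult(feature, x, x_star, C, math.nan,
                                     math.nan, math.nan, status="infeasible")
        C_star = simulate_production(spec_star, k).total
    elif feature == "k+":
        x = k.k
        x_star = x * (1.0 + delta)
        C_star = simulate_production(spec, x_star).total
    else:  # k_up+ / k_down+: one strain's multiplier, k recombined
        j = 0 if feature == "k_up+" else 1
        x = k.k_per_strain[j]
        x_star = x * (1.0 + delta)
        kps = list(k.k_per_strain)
        kps[j] = x_star
        C_star = simulate_production(spec, mapping_constant(kps, k.icr)).total

    puf = (C_star - C) / (x_star - x)
    if C != 0:
        rpuf = puf / C
    elif puf == 0:
        rpuf = 0.0
    else:
        rpuf = math.copysign(math.inf, puf)
    return SensitivityResult(feature=feature, x=x, x_star=x_star,
                             C=C, C_star=C_star, puf=puf, Rpuf=rpuf)


def rank_strategies(spec: CocultureSpec, k: MappingConstant,
                    features: list[str] | None = None, delta: float = 0.1,
                    options: SolveOptions | None = None,
                    config: ThermoConfig | None = None,
                    ) -> list[SensitivityResult]:
    """Evaluate features at one strain ratio, sorted by descending Rpuf."""
    features = list(features) if features is not None else \
        ["d_up+", "d_up-", "d_down+", "d_down-", "k+"]
    if not features:
        raise ValueError("at least one feature is required")
    results = [evaluate_feature(spec, k, f, delta, options, config)
               for f in features]

    def key(r: SensitivityResult):
        return (1, 0.0) if math.isnan(r.Rpuf) else (0, -r.Rpuf)

    return sorted(results, key=key)


def write_ranking(results: list[SensitivityResult], tsv_path, json_path=None) -> None:
    import pandas as pd

    df = pd.DataFrame([
        {"feature": r.label, "x": r.x, "x_star": r.x_star, "C": r.C,
         "C_star": r.C_star, "puf": r.puf, "Rpuf": r.Rpuf, "status": r.status}
        for r in results
    ])
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
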