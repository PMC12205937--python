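"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's LP machinery: the pathway MDF
is recomputed by dense grid search over the metabolite concentration
box, and toy-network optima come from closed forms derived by hand.
"""

from __future__ import annotations

import itertools

import numpy as np

from coyield.model import MetabolicModel, ThermoConfig


def grid_mdf(model: MetabolicModel, pathway: list[str],
             config: ThermoConfig, points: int = 41,
             ) -> tuple[float, float]:
    """Max over a dense ln-concentration grid of the min driving force.

    Returns ``(B_grid, resolution)`` where ``resolution`` bounds the
    discretization error: the optimum lies within half a grid step per
    dimension, and each driving force moves by at most RT per unit of
    any single ln-concentration (unit stoichiometry toys).
    """
    tracked = sorted({
        met_id
        for rid in pathway
        for met_id in model.reaction(rid).stoich
        if model.metabolite(met_id).thermo_tracked
    })
    axes = []
    max_step = 0.0
    for m in tracked:
        met = model.metabolite(m)
        axes.append(np.linspace(met.ln_conc_lb, met.ln_conc_ub, points))
        max_step = max(max_step, (met.ln_conc_ub - met.ln_conc_lb) / (points - 1))

    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    conc = dict(zip(tracked, grids))
    min_df = None
    max_degree = 0
    for rid in pathway:
        rxn = model.reaction(rid)
        df = -rxn.dG0_prime
        n_terms = 0
        for met_id, s in rxn.stoich.items():
            if met_id in conc:
                df = df - config.RT * s * conc[met_id]
                n_terms += 1
        max_degree = max(max_degree, n_terms)
        df = np.broadcast_to(df, tuple(len(a) for a in axes)) \
            if np.ndim(df) == 0 else df
        min_df = df if min_df is None else np.minimum(min_df, df)

    resolution = config.RT * max_step * max_degree
    return float(np.max(min_df)), resolution


def enumerate_pairs_loss(loss, values):
    """Exhaustive argmin over a 2-D grid, lexicographic tie-break."""
    best, best_val = None, np.inf
    for du, dd in itertools.product(values, values):
        val = loss(du, dd)
        if val is not None and val < best_val - 1e-15:
            best, best_val = (du, dd), val
    return best, best_val
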