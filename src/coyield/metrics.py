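"""Fit metrics between simulated and experimental titers.

MRE is the mean relative error; R² the coefficient of determination in
its ``1 − SSres/SStot`` form (can be negative for fits worse than the
mean, undefined when the experimental values have no variance); the
similarity P is a paired two-sided t-test of the per-pair differences
against zero, so *larger* P means the simulation is statistically
indistinguishable from the measurements.  An optional TOST
(two-one-sided-tests) equivalence P is available for callers who want
a formal equivalence margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FitMetrics", "fit_metrics"]


@dataclass(frozen=True)
class FitMetrics:
    mre: float
    r2: float | None  # None when experimental variance is zero
    p_similar: float


def fit_metrics(simulated, experimental, *, method: str = "ttest",
                equivalence_margin: float | None = None) -> FitMetrics:
    """MRE, R² and a similarity P value between paired series.

    ``method="ttest"`` (default): paired two-sided t-test, P = 1 by
    convention when all differences are identically zero.
    ``method="tost"``: equivalence P from two one-sided t-tests against
    ``±equivalence_margin`` (required); *smaller* P there means
    stronger evidence of equivalence — note the reversed convention.
    """
    sim = np.asarray(simulated, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if sim.shape != exp.shape or sim.ndim != 1 or sim.size < 2:
        raise ValueError("need two equal-length 1-D series with n ≥ 2")
    if np.any(exp == 0):
        raise ValueError("MRE undefined: experimental values must be nonzero")

    mre = float(np.mean(np.abs(sim - exp) / np.abs(exp)))

    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum((exp - sim) ** 2)) / ss_tot

    diff = sim - exp
    if method == "ttest":
        if np.allclose(diff, 0.0, atol=1e-12):
            p = 1.0
        else:
            p = float(stats.ttest_rel(sim, exp).pvalue)
            if np.isnan(p):  # constant nonzero differences
                p = 0.0
    elif method == "tost":
        if equivalence_margin is None or equivalence_margin <= 0:
            raise ValueError("tost requires a positive equivalence_margin")
        n = diff.size
        se = diff.std(ddof=1) / np.sqrt(n)
        if se == 0:
            p = 0.0 if np.abs(diff.mean()) < equivalence_margin else 1.0
        else:
            t_lo = (diff.mean() + equivalence_margin) / se
            t_hi = (diff.mean() - equivalence_margin) / se
            p_lo = float(stats.t.sf(t_lo, n - 1))
            p_hi = float(stats.t.cdf(t_hi, n - 1))
            p = max(p_lo, p_hi)
    else:
        raise ValueError(f"unknown method {method!r}")

    return FitMetrics(mre=mre, r2=r2, p_similar=p)
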