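"""Serial-coalescent log density of a time tree under a demographic model.

The density is the product over inter-event intervals of
exp(-k(k-1)/2 * integral of dt / (Ne(t)*generation_time)) times
1 / (Ne(t_c)*generation_time) at each coalescence, where k is the number
of active lineages (tips activate at their sampling ages).
"""

from __future__ import annotations

import numpy as np

from mitoclock.errors import NumericalError
from mitoclock.simulate import DemographicModel
from mitoclock.tree import TimeTree


def _intensity_integral(t0: float, t1: float, demography: DemographicModel) -> float:
    """Integral of 1/(Ne(t)*gen) dt over (t0, t1); analytic for exp growth."""
    g = demography.growth_rate
    pace = demography.N0 * demography.generation_time
    if g == 0:
        return (t1 - t0) / pace
    if g * t1 > 700:
        raise NumericalError(f"intensity integral overflow at t={t1:.3g}")
    return (np.exp(g * t1) - np.exp(g * t0)) / (g * pace)


def coalescent_log_density(tree: TimeTree, demography: DemographicModel) -> float:
    n = tree.n_tips
    ages = tree.age
    g = demography.growth_rate
    pace = demography.N0 * demography.generation_time
    # +1 at tip activation, -1 at coalescence; activations first on ties
    kind = np.concatenate([np.ones(n), -np.ones(n - 1)])
    order = np.lexsort((-kind, ages))
    t = ages[order]
    k = np.cumsum(kind[order])  # lineages active after each event
    if np.any((kind[order] < 0) & (k < 1)):
        raise NumericalError("coalescence with fewer than 2 active lineages")
    kk = k[:-1]
    pair_rate = kk * (kk - 1) / 2.0
    t0, t1 = t[:-1], t[1:]
    if g == 0:
        integrals = (t1 - t0) / pace
    else:
        if g * t[-1] > 700:
            # the cumulative intensity overflows: such a deep tree has
            # essentially zero density under this growth rate
            return -np.inf
        e = np.exp(g * t)
        integrals = (e[1:] - e[:-1]) / (g * pace)
    logp = -float(np.dot(pair_rate, integrals))
    coal_times = ages[n : 2 * n - 1]
    logp += float(np.sum(g * coal_times) - (n - 1) * np.log(pace))
    if np.isnan(logp):
        raise NumericalError("non-finite coalescent log density")
    return logp
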