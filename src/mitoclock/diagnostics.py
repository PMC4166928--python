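"""Posterior diagnostics: HPD intervals, effective sample size, summaries."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mitoclock.errors import ValidationError

ESS_CONVERGENCE_THRESHOLD = 200.0


def hpd_interval(samples, level: float = 0.95):
    """Shortest contiguous interval containing ceil(level*n) sorted samples.

    Ties between equally short windows break to the lowest start.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValidationError(f"need at least 20 samples for an HPD, got {n}")
    m = math.ceil(level * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    k = int(np.argmin(widths))  # argmin returns the first (lowest-start) tie
    return float(x[k]), float(x[k + m - 1])


def effective_sample_size(samples) -> float:
    """ESS = n / (1 + 2*sum(rho_k)), autocorrelations truncated at the
    first non-positive estimate (initial-positive-sequence rule), capped
    at n.  A zero-variance chain reports n with a degeneracy warning."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValidationError(f"need at least 10 samples for an ESS, got {n}")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        warnings.warn("zero-variance chain: ESS reported as n (degenerate)")
        return float(n)
    # autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(min(n, n / (1.0 + 2.0 * s)))


@dataclass
class ParameterSummary:
    name: str
    mean: float
    median: float
    hpd_lower: float
    hpd_upper: float
    ess: float


class PosteriorSummary:
    """Per-parameter summaries over pooled (and optionally per-chain) samples."""

    def __init__(self, chains: dict, level: float = 0.95):
        """``chains`` maps parameter name -> list of per-chain 1-D arrays
        (a single array is treated as one chain)."""
        self.level = level
        self.samples = {}
        self.per_chain_ess = {}
        self.params = {}
        for name, arrs in chains.items():
            if isinstance(arrs, np.ndarray) and arrs.ndim == 1:
                arrs = [arrs]
            arrs = [np.asarray(a, dtype=float) for a in arrs]
            pooled = np.concatenate(arrs)
            self.samples[name] = pooled
            self.per_chain_ess[name] = [effective_sample_size(a) for a in arrs]
            lo, hi = hpd_interval(pooled, level)
            self.params[name] = ParameterSummary(
                name,
                float(pooled.mean()),
                float(np.median(pooled)),
                lo,
                hi,
                float(sum(self.per_chain_ess[name])),
            )

    def __getitem__(self, name: str) -> ParameterSummary:
        return self.params[name]

    def __contains__(self, name: str) -> bool:
        return name in self.params

    @property
    def converged(self) -> bool:
        """True iff every parameter's pooled ESS reaches 200."""
        return all(p.ess >= ESS_CONVERGENCE_THRESHOLD for p in self.params.values())

    def low_ess_parameters(self) -> list:
        return [p.name for p in self.params.values()
                if p.ess < ESS_CONVERGENCE_THRESHOLD]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": p.name,
                    "mean": p.mean,
                    "median": p.median,
                    "hpd_lower": p.hpd_lower,
                    "hpd_upper": p.hpd_upper,
                    "ess": p.ess,
                }
                for p in self.params.values()
            ]
        )
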