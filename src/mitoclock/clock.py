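"""Molecular clock models: strict and uncorrelated-lognormal (UCLN) relaxed.

A clock maps branch durations (years) to expected substitutions/site.
Under the strict clock every branch uses the same rate; under UCLN each
branch carries an independent multiplier drawn from a lognormal with
real-space mean 1 and log-space standard deviation ``ucld_stdev`` (the
clock-likeness diagnostic: values near 0 mean clock-like data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mitoclock.errors import ValidationError


@dataclass
class ClockModel:
    variant: str = "strict"  # "strict" | "UCLN"
    mean_rate: float = 2.143e-8  # subs/site/year
    ucld_stdev: float = 0.0
    branch_rates: np.ndarray | None = None  # per-node multipliers (UCLN)

    def __post_init__(self):
        if self.variant not in ("strict", "UCLN"):
            raise ValidationError(f"unknown clock variant {self.variant!r}")
        if self.mean_rate <= 0:
            raise ValidationError("clock rate must be > 0")
        if self.ucld_stdev < 0:
            raise ValidationError("ucld_stdev must be >= 0")
        if self.branch_rates is not None:
            self.branch_rates = np.asarray(self.branch_rates, dtype=float)
            if np.any(self.branch_rates <= 0):
                raise ValidationError("branch rate multipliers must be > 0")

    def multipliers(self, n_nodes: int) -> np.ndarray:
        if self.variant == "strict" or self.branch_rates is None:
            return np.ones(n_nodes)
        if self.branch_rates.shape != (n_nodes,):
            raise ValidationError("branch_rates length does not match the tree")
        return self.branch_rates

    def branch_substitutions(self, durations: np.ndarray) -> np.ndarray:
        """Expected subs/site on each parent branch (durations in years)."""
        return self.mean_rate * durations * self.multipliers(len(durations))

    def sample_branch_rates(self, n_nodes: int, rng) -> np.ndarray:
        """Draw UCLN multipliers: lognormal with real-space mean 1."""
        s = self.ucld_stdev
        if self.variant == "strict" or s == 0:
            return np.ones(n_nodes)
        return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n_nodes)

    def branch_rate_log_prior(self) -> float:
        """Log density of the current multipliers under the UCLN prior."""
        if self.variant == "strict" or self.branch_rates is None:
            return 0.0
        s = self.ucld_stdev
        if s == 0:
            # degenerate prior: multipliers must all be 1
            return 0.0 if np.allclose(self.branch_rates, 1.0) else -np.inf
        x = self.branch_rates
        mu = -0.5 * s * s
        z = (np.log(x) - mu) / s
        return float(np.sum(-np.log(x * s * np.sqrt(2 * np.pi)) - 0.5 * z * z))
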