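"""Calibration priors: tips, internal nodes, root, and flat bounds.

Three calibration sources are supported, matching the strategies being
compared:

* **tip priors** — normal(age_mean, age_sd) on a sampled tip's age, the
  standard deviation equal to the standard error of the radiocarbon date
  (a plain float means a fixed point age, contributing no density);
* **node priors** — normal(mean, sd) on the age of the MRCA of a tip set,
  with sd defaulting to 20% of the mean (soft: the prior attaches to the
  MRCA whatever the current topology);
* **root prior** — offset lognormal on the root age, by default offset
  5 My with real-space mean 6 My and 97.5% quantile 7.5 My (the lognormal
  sigma is solved numerically from those two constraints).

All other internal node ages get a flat prior on (0.0645, 50) My and
clock rates a flat prior on (1e-10, 1e-5) subs/site/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from mitoclock.errors import ValidationError
from mitoclock.tree import TimeTree

DEFAULT_NODE_AGE_BOUNDS = (64_500.0, 50e6)  # years
DEFAULT_RATE_BOUNDS = (1e-10, 1e-5)  # subs/site/year


@dataclass(frozen=True)
class NodeCalibration:
    tips: frozenset
    mean: float
    sd: float | None = None  # None -> 20% of mean

    def __post_init__(self):
        object.__setattr__(self, "tips", frozenset(self.tips))
        if self.mean <= 0:
            raise ValidationError("node calibration mean must be > 0")
        if self.sd is None:
            object.__setattr__(self, "sd", 0.2 * self.mean)
        elif self.sd <= 0:
            raise ValidationError("node calibration sd must be > 0")


@dataclass(frozen=True)
class RootCalibration:
    """Offset-lognormal root-age prior; all values in years."""

    offset: float = 5e6
    mean: float = 6e6
    q975: float = 7.5e6

    def __post_init__(self):
        if not (self.offset < self.mean < self.q975):
            raise ValidationError("need offset < mean < q975")
        object.__setattr__(self, "_params", _solve_offset_lognormal(
            self.offset, self.mean, self.q975))

    @property
    def log_mu_sigma(self):
        return self._params

    def log_density(self, age: float) -> float:
        m, s = self._params
        x = age - self.offset
        if x <= 0:
            return -np.inf
        z = (np.log(x) - m) / s
        return float(-np.log(x * s * np.sqrt(2 * np.pi)) - 0.5 * z * z)

    def sample(self, rng, size=None):
        m, s = self._params
        return self.offset + rng.lognormal(m, s, size=size)


def _solve_offset_lognormal(offset, mean, q975, tol=1e-10):
    """Solve (log-mu, sigma) so the offset lognormal has the requested
    real-space mean and 97.5% quantile.

    The constraints give m = ln(mean-offset) - s^2/2 and
    m + z_{.975} s = ln(q975-offset); the smaller sigma root is taken
    (the larger one puts nearly all mass at the offset).
    """
    z = norm.ppf(0.975)
    a = np.log(mean - offset)
    b = np.log(q975 - offset)

    def f(s):
        return a - 0.5 * s * s + z * s - b

    # f(0) = a - b < 0; f rises to a maximum at s = z then falls
    if f(z) < 0:
        raise ValidationError("no lognormal satisfies the mean/quantile pair")
    s = brentq(f, 1e-12, z, xtol=tol)
    return a - 0.5 * s * s, s


@dataclass
class CalibrationSpec:
    """Which calibrations are active for one analysis scenario.

    ``tip_priors`` maps sample id to (mean, sd) for a normal tip-age prior
    or to a plain float for a fixed point age; tips absent from the map
    keep their recorded age fixed.
    """

    tip_priors: dict = field(default_factory=dict)
    node_priors: list = field(default_factory=list)
    root_prior: RootCalibration | None = None
    node_age_bounds: tuple = DEFAULT_NODE_AGE_BOUNDS
    rate_bounds: tuple = DEFAULT_RATE_BOUNDS
    bound_all_internal_nodes: bool = True

    def __post_init__(self):
        if not (self.tip_priors or self.node_priors or self.root_prior):
            raise ValidationError("at least one calibration source is required")

    def sampled_tips(self) -> list:
        """Ids whose ages are free parameters (interval-calibrated tips)."""
        return [sid for sid, p in self.tip_priors.items()
                if not np.isscalar(p)]


class PreparedCalibration:
    """Calibration prior with tip-label lookups resolved once.

    Valid for any tree sharing the tip indexing of the tree it was
    prepared on (topology changes are fine: tips are never renumbered).
    """

    def __init__(self, spec: CalibrationSpec, tree: TimeTree):
        self.spec = spec
        self.tips = [(tree.tip_index(sid), float(p[0]), float(p[1]))
                     for sid, p in spec.tip_priors.items() if not np.isscalar(p)]
        self.nodes = [([tree.tip_index(t) for t in nc.tips], nc.mean, nc.sd)
                      for nc in spec.node_priors]
        self._rate_const = -np.log(spec.rate_bounds[1] - spec.rate_bounds[0])
        lo, hi = spec.node_age_bounds
        self._node_const = -np.log(hi - lo)

    def __call__(self, tree: TimeTree, rates=None) -> float:
        spec = self.spec
        logp = 0.0
        for i, mean, sd in self.tips:
            age = tree.age[i]
            if age < 0:
                return -np.inf
            z = (age - mean) / sd
            logp += -np.log(sd * 2.5066282746310002) - 0.5 * z * z
        calibrated = set()
        for idx, mean, sd in self.nodes:
            v = tree.mrca_indices(idx)
            calibrated.add(v)
            z = (tree.age[v] - mean) / sd
            logp += -np.log(sd * 2.5066282746310002) - 0.5 * z * z
        root = tree.root
        if spec.root_prior is not None:
            lp = spec.root_prior.log_density(tree.age[root])
            if not np.isfinite(lp):
                return -np.inf
            logp += lp
            calibrated.add(root)
        lo, hi = spec.node_age_bounds
        if spec.bound_all_internal_nodes:
            for v in tree.postorder():
                if v in calibrated:
                    continue
                if not (lo <= tree.age[v] <= hi):
                    return -np.inf
                logp += self._node_const
        elif root not in calibrated:
            if not (lo <= tree.age[root] <= hi):
                return -np.inf
            logp += self._node_const
        if rates is not None:
            rlo, rhi = spec.rate_bounds
            for r in rates:
                if not (rlo <= r <= rhi):
                    return -np.inf
                logp += self._rate_const
        return float(logp)


def calibration_log_prior(tree: TimeTree, spec: CalibrationSpec,
                          rates=None) -> float:
    """Log prior of node/tip ages and clock rates under a calibration spec.

    Returns -inf when any bounded quantity falls outside its flat prior:
    that is a valid rejection signal, not an error.
    """
    rates = None if rates is None else np.atleast_1d(rates)
    return PreparedCalibration(spec, tree)(tree, rates=rates)
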