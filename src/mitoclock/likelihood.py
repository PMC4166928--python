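"""Partitioned phylogenetic likelihood via Felsenstein pruning.

Each partition carries its own substitution model, clock and rate; the
topology is shared.  Site patterns are compressed, discrete-gamma rate
categories are summed with equal weights, and per-pattern scaling keeps
partial likelihoods in range on large trees.  Ancient tips may carry a
postmortem-damage (PMD) correction: with q = 1 - exp(-delta * age), an
observed T also admits a true C with weight q (and an observed A a true
G), because deamination can create, but never destroy, the observed T/A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitoclock.errors import NumericalError, ValidationError
from mitoclock.io import Alignment, SiteAnnotation, A, C, G, T
from mitoclock.clock import ClockModel
from mitoclock.simulate import DemographicModel, PMDModel
from mitoclock.substitution import SubstitutionModelSpec, transition_matrices
from mitoclock.tree import TimeTree

_SCALE_FLOOR = 1e-280

try:  # numba accelerates the inner pruning loop; numpy path is equivalent
    from numba import njit

    @njit(cache=True)
    def _prune_kernel(nodes, left, right, P, part, slog, floor):
        n_nodes = nodes.shape[0]
        C = part.shape[1]
        npat = part.shape[3]
        for k in range(n_nodes):
            v = nodes[k]
            l = left[v]
            r = right[v]
            for c in range(C):
                for p in range(npat):
                    for i in range(4):
                        sl = 0.0
                        sr = 0.0
                        for j in range(4):
                            sl += P[2 * k, c, i, j] * part[l, c, j, p]
                            sr += P[2 * k + 1, c, i, j] * part[r, c, j, p]
                        part[v, c, i, p] = sl * sr
            for p in range(npat):
                m = floor
                for c in range(C):
                    for i in range(4):
                        if part[v, c, i, p] > m:
                            m = part[v, c, i, p]
                for c in range(C):
                    for i in range(4):
                        part[v, c, i, p] /= m
                slog[v, p] = slog[l, p] + slog[r, p] + np.log(m)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def pmd_tip_partials(observed_base, tip_age: float, pmd: PMDModel) -> np.ndarray:
    """Length-4 partial-likelihood vector for one observed tip base.

    ``observed_base`` is a code in {A=0, C=1, G=2, T=3, N=4, -=5}; N and
    gap give all-ones.  With q = 1 - exp(-delta*age): observed T ->
    (A 0, C q, G 0, T 1); observed A -> (A 1, C 0, G q, T 0); C and G
    observations keep their one-hot vector (damage only creates T/A).
    delta = 0 or age = 0 reproduce plain one-hot vectors.
    """
    if tip_age < 0:
        raise ValidationError("tip age must be >= 0")
    v = np.zeros(4)
    if observed_base >= 4:  # ambiguous
        return np.ones(4)
    v[observed_base] = 1.0
    q = pmd.damage_probability(tip_age)
    if q > 0:
        if observed_base == T:
            v[C] = q
        elif observed_base == A:
            v[G] = q
    return v


def compress_patterns(codes: np.ndarray):
    """Unique site patterns and their counts; codes is (n_tips, n_sites)."""
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return patterns, weights.astype(float)


class PartitionLikelihood:
    """Pruning likelihood for one partition on a fixed tip set.

    The topology and branch lengths are supplied per call, so the same
    object serves every MCMC state; per-node partials are cached and only
    the requested dirty nodes (plus the root summation) are recomputed.
    """

    def __init__(self, patterns, weights, spec: SubstitutionModelSpec,
                 tip_ages=None, pmd: PMDModel | None = None):
        self.patterns = np.asarray(patterns, dtype=np.uint8)
        self.weights = np.asarray(weights, dtype=float)
        self.spec = spec
        self.n_tips, self.n_patterns = self.patterns.shape
        self.eig = spec.eigensystem()
        self.cat_rates, self.cat_weights = spec.category_rates()
        self.pi = np.asarray(spec.pi)
        self.tip_ages = np.zeros(self.n_tips) if tip_ages is None else np.asarray(tip_ages, float)
        n_nodes = 2 * self.n_tips - 1
        C_ = len(self.cat_rates)
        self.partials = np.zeros((n_nodes, C_, 4, self.n_patterns))
        self.slog = np.zeros((n_nodes, self.n_patterns))
        self.set_pmd(pmd or PMDModel(0.0))

    def set_pmd(self, pmd: PMDModel) -> None:
        self.pmd = pmd
        tp = np.zeros((self.n_tips, 4, self.n_patterns))
        for i in range(self.n_tips):
            for code in np.unique(self.patterns[i]):
                cols = self.patterns[i] == code
                tp[i, :, cols] = pmd_tip_partials(int(code), self.tip_ages[i], pmd)
        self.partials[: self.n_tips] = tp[:, None, :, :]

    def set_tip_age(self, tip_index: int, age: float) -> None:
        if age != self.tip_ages[tip_index]:
            self.tip_ages[tip_index] = age
            if self.pmd.delta > 0:
                for code in np.unique(self.patterns[tip_index]):
                    cols = self.patterns[tip_index] == code
                    self.partials[tip_index, :, :, cols] = pmd_tip_partials(
                        int(code), age, self.pmd)

    def compute(self, tree: TimeTree, branch_subs: np.ndarray,
                dirty=None) -> float:
        """Log likelihood; ``branch_subs[v]`` is the expected subs/site on
        the branch from v to its parent.  ``dirty=None`` recomputes every
        internal node; otherwise only the given internal nodes, which must
        include every ancestor of any changed edge."""
        post = tree.postorder()
        if dirty is None:
            nodes = post
        else:
            dirty = set(dirty)
            nodes = [v for v in post if v in dirty]
        part = self.partials
        slog = self.slog
        left, right = tree.left, tree.right
        # all needed edge matrices in one batched exponential
        kids = np.empty(2 * len(nodes), dtype=np.int64)
        kids[0::2] = left[nodes]
        kids[1::2] = right[nodes]
        d = np.multiply.outer(branch_subs[kids], self.cat_rates)  # (E, C)
        P = transition_matrices(self.eig, d)  # (E, C, 4, 4)
        if _HAVE_NUMBA:
            _prune_kernel(np.asarray(nodes, dtype=np.int64), left, right,
                          np.ascontiguousarray(P), part, slog, _SCALE_FLOOR)
        else:
            for k, v in enumerate(nodes):
                l, r = left[v], right[v]
                p = (P[2 * k] @ part[l]) * (P[2 * k + 1] @ part[r])
                m = p.reshape(-1, self.n_patterns).max(axis=0)
                m = np.maximum(m, _SCALE_FLOOR)
                part[v] = p / m
                slog[v] = slog[l] + slog[r] + np.log(m)
        root = tree.root
        site_l = np.einsum("c,i,cip->p", self.cat_weights, self.pi, part[root])
        if np.any(site_l <= 0) or not np.all(np.isfinite(site_l)):
            bad = int(np.argmin(site_l))
            raise NumericalError(f"non-positive site likelihood at pattern {bad}")
        return float(np.dot(self.weights, np.log(site_l) + slog[root]))


# ------------------------------------------------------------------- states


@dataclass
class PartitionState:
    """Per-partition model: substitution spec + clock (rate lives on the clock)."""

    spec: SubstitutionModelSpec
    clock: ClockModel


@dataclass
class ModelState:
    """The full parameter vector of one analysis.

    Partitions share the topology; substitution and clock models are
    unlinked across partitions.
    """

    tree: TimeTree
    partitions: dict  # name -> PartitionState
    demography: DemographicModel = field(default_factory=DemographicModel)
    pmd: PMDModel = field(default_factory=lambda: PMDModel(0.0))


def build_partition_likelihoods(alignment: Alignment, annotation: SiteAnnotation,
                                tree: TimeTree, partitions: dict,
                                pmd: PMDModel | None = None) -> dict:
    """PartitionLikelihood per partition, rows ordered like the tree tips."""
    if set(alignment.ids) < set(tree.tip_ids):
        raise ValidationError("alignment is missing tree tips")
    aln = alignment.subset_sequences(tree.tip_ids)
    tip_ages = tree.age[: tree.n_tips]
    out = {}
    for name in partitions:
        cols = annotation.sites_of("all" if name == "all" else name.split("+"))
        if cols.size == 0:
            continue
        patterns, weights = compress_patterns(aln.codes[:, cols])
        out[name] = PartitionLikelihood(
            patterns, weights, partitions[name].spec, tip_ages=tip_ages, pmd=pmd
        )
    return out


def tree_log_likelihood(state: ModelState, alignment: Alignment,
                        annotation: SiteAnnotation) -> float:
    """Total log likelihood, summed over partitions."""
    engines = build_partition_likelihoods(
        alignment, annotation, state.tree, state.partitions, pmd=state.pmd
    )
    durations = state.tree.branch_durations()
    total = 0.0
    for name, engine in engines.items():
        clock = state.partitions[name].clock
        total += engine.compute(state.tree, clock.branch_substitutions(durations))
    return total
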