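"""Metropolis-Hastings sampler for tip/node/root-calibrated dating.

The sampler works on a :class:`ModelState`: per-partition clock rates
(strict or UCLN), node ages, calibrated tip ages, demographic parameters
(N0, growth rate), and optionally the postmortem-damage rate delta and
the topology (narrow subtree exchange, off by default — the comparisons
this package exists for concern rates and ages on a fixed topology).

Operators are scale moves on positive scalars, uniform slides on node
ages within their parent/children bounds, a scale move on the root
branch, Gaussian moves on calibrated tip ages, and an occasional
independence draw of each rate from its flat prior (which also makes
prior-only runs mix instantly).  Proposal widths self-tune during
burn-in and are frozen afterwards.  Runs are bit-reproducible for a
given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from mitoclock.calibration import CalibrationSpec, PreparedCalibration
from mitoclock.clock import ClockModel
from mitoclock.coalescent import coalescent_log_density
from mitoclock.diagnostics import PosteriorSummary
from mitoclock.errors import MitoclockError, ValidationError
from mitoclock.io import Alignment, SiteAnnotation
from mitoclock.likelihood import (
    ModelState,
    PartitionState,
    build_partition_likelihoods,
)
from mitoclock.simulate import DemographicModel, PMDModel
from mitoclock.substitution import SubstitutionModelSpec
from mitoclock.tree import TimeTree

# hyperpriors for nuisance parameters (documented in the methods note)
_N0_BOUNDS = (1e1, 1e8)  # log-uniform
_GROWTH_PRIOR_MEAN = 1e-4  # exponential, per year
_DELTA_BOUNDS = (1e-15, 1e-6)  # log-uniform
_UCLD_PRIOR_MEAN = 1.0 / 3.0  # exponential


@dataclass
class MCMCSettings:
    steps: int = 50_000
    burn_in: int | None = None  # default: 10% of steps
    thin: int = 25
    n_chains: int = 1
    seed: int | None = None
    estimate_demography: bool = True
    estimate_growth: bool = True  # sample g as well as N0
    estimate_pmd: bool = False
    fix_topology: bool = True
    sample_from_prior: bool = False
    beta: float = 1.0  # power-posterior exponent on the likelihood
    store_trees: bool = True
    tree_thin: int | None = None  # default: 10 * thin
    adapt: bool = True

    def resolved_burn_in(self) -> int:
        return self.steps // 10 if self.burn_in is None else self.burn_in


@dataclass
class MCMCResult:
    summary: PosteriorSummary
    traces: dict  # name -> list of per-chain arrays
    trees: list  # thinned TimeTree samples, pooled over chains
    loglik_trace: list  # per-chain arrays (power-posterior workhorse)
    settings: MCMCSettings
    warnings: list


def default_partitions(rate: float = 2.143e-8, clock: str = "strict",
                       spec: SubstitutionModelSpec | None = None) -> dict:
    """Single whole-molecule partition with an HKY+G4 model."""
    spec = spec or SubstitutionModelSpec(
        model="HKY", kappa=22.0, pi=(0.309, 0.313, 0.131, 0.247),
        alpha=0.5, n_categories=4,
    )
    return {"all": PartitionState(spec, ClockModel(clock, rate))}


# ------------------------------------------------------------------ helpers


def resolve_tip_ages(samples, calibration: CalibrationSpec) -> dict:
    """Initial tip ages: point priors pin the age, interval priors start at
    their mean, uncalibrated tips sit at their recorded age."""
    ages = {s.sample_id: s.age_mean for s in samples}
    for sid, p in calibration.tip_priors.items():
        ages[sid] = float(p) if np.isscalar(p) else float(p[0])
    return ages


def heuristic_start_tree(alignment: Alignment, samples, rate_guess: float,
                         seed=None) -> TimeTree:
    """Serial UPGMA: cluster on JC-corrected distances converted to node
    ages via t_uv = (d_uv/rate + age_u + age_v)/2, clamped to valid order."""
    ids = [s.sample_id for s in samples]
    aln = alignment.subset_sequences(ids)
    codes = aln.codes
    n = len(ids)
    ages0 = np.array([s.age_mean for s in samples], float)
    # pairwise JC distances
    D = np.zeros((n, n))
    ok = codes < 4
    for i in range(n):
        for j in range(i + 1, n):
            m = ok[i] & ok[j]
            p = np.mean(codes[i][m] != codes[j][m]) if m.any() else 0.0
            p = min(p, 0.749)
            d = -0.75 * math.log1p(-4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    left = np.full(2 * n - 1, -1, dtype=np.int64)
    right = np.full(2 * n - 1, -1, dtype=np.int64)
    age = np.zeros(2 * n - 1)
    age[:n] = ages0
    active = list(range(n))
    members = {i: [i] for i in range(n)}
    Dc = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    tip_age = {i: [ages0[i]] for i in range(n)}
    nxt = n
    while len(active) > 1:
        best, bt = None, np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                u, v = active[ai], active[bi]
                d = Dc[(min(u, v), max(u, v))]
                mu_age = (np.mean(tip_age[u]) + np.mean(tip_age[v])) / 2.0
                t = d / (2.0 * rate_guess) + mu_age
                if t < bt:
                    bt, best = t, (u, v)
        u, v = best
        w = nxt
        nxt += 1
        age[w] = max(bt, age[u] + 1.0, age[v] + 1.0)
        left[w], right[w] = u, v
        parent[u] = parent[v] = w
        nu, nv = len(members[u]), len(members[v])
        members[w] = members[u] + members[v]
        tip_age[w] = tip_age[u] + tip_age[v]
        active = [x for x in active if x not in (u, v)]
        for x in active:
            du = Dc[(min(u, x), max(u, x))]
            dv = Dc[(min(v, x), max(v, x))]
            Dc[(min(w, x), max(w, x))] = (nu * du + nv * dv) / (nu + nv)
        active.append(w)
    return TimeTree(ids, parent, left, right, age, 2 * n - 2)


def _ancestors(tree: TimeTree, v: int) -> list:
    out = []
    u = v if not tree.is_tip(v) else tree.parent[v]
    while u != -1:
        out.append(int(u))
        u = tree.parent[u]
    return out


class _Move:
    __slots__ = ("name", "weight", "width", "accepted", "proposed")

    def __init__(self, name, weight, width):
        self.name, self.weight, self.width = name, weight, width
        self.accepted = 0
        self.proposed = 0


class _Chain:
    """One MCMC chain over a ModelState with cached likelihood partials."""

    def __init__(self, alignment, annotation, samples, calibration, settings,
                 partitions, start_tree, demography, pmd, rng):
        self.cal = calibration
        self.settings = settings
        self.rng = rng
        self.ann = annotation
        self.aln = alignment

        tip_ages = resolve_tip_ages(samples, calibration)
        if start_tree is None:
            rate0 = next(iter(partitions.values())).clock.mean_rate
            start_tree = heuristic_start_tree(alignment, samples, rate0)
        tree = start_tree.copy()
        for sid, a in tip_ages.items():
            tree.age[tree.tip_index(sid)] = a
        # repair any parent younger than a moved tip: push ancestors up
        for v in tree.postorder():
            floor = max(tree.age[tree.left[v]], tree.age[tree.right[v]])
            if tree.age[v] <= floor:
                tree.age[v] = floor + 1.0
        self.tree = tree
        self.parts = {name: replace(ps, clock=replace(ps.clock))
                      for name, ps in partitions.items()}
        self.demography = demography or DemographicModel()
        self.pmd = pmd or PMDModel(0.0)
        if settings.estimate_pmd and self.pmd.delta == 0:
            self.pmd = PMDModel(1e-9)  # starting value inside the prior support
        self.sampled_tips = [tree.tip_index(s)
                             for s in calibration.sampled_tips()]
        self.free_nodes = [int(v) for v in tree.postorder() if v != tree.root]

        if settings.sample_from_prior:
            self.engines = {}
        else:
            self.engines = build_partition_likelihoods(
                alignment, annotation, tree, self.parts, pmd=self.pmd)
        self.logliks = {}
        self._full_eval()
        self.prior = PreparedCalibration(calibration, tree)
        self.log_coal = coalescent_log_density(tree, self.demography)
        self.log_cal = self.prior(tree, rates=self._rates())
        if not np.isfinite(self.log_cal):
            raise MitoclockError(
                "initial state has zero prior probability; check calibration "
                "bounds against the starting tree")
        self.moves = self._build_moves()
        self.warnings = []

    # ------------------------------------------------------------ utilities
    def _rates(self):
        return [ps.clock.mean_rate for ps in self.parts.values()]

    def _branch_subs(self, name):
        ps = self.parts[name]
        durations = self.tree.branch_durations()
        return ps.clock.branch_substitutions(durations)

    def _full_eval(self):
        for name, eng in self.engines.items():
            self.logliks[name] = eng.compute(self.tree, self._branch_subs(name))

    def _hyper_log_prior(self) -> float:
        lp = 0.0
        if self.settings.estimate_demography:
            n0 = self.demography.N0
            if not (_N0_BOUNDS[0] <= n0 <= _N0_BOUNDS[1]):
                return -np.inf
            lp += -math.log(n0)
            if self.settings.estimate_growth:
                g = self.demography.growth_rate
                if g < 0:
                    return -np.inf
                lp += -g / _GROWTH_PRIOR_MEAN
        if self.settings.estimate_pmd:
            d = self.pmd.delta
            if not (_DELTA_BOUNDS[0] <= d <= _DELTA_BOUNDS[1]):
                return -np.inf
            lp += -math.log(d)
        for ps in self.parts.values():
            if ps.clock.variant == "UCLN":
                lp += -ps.clock.ucld_stdev / _UCLD_PRIOR_MEAN
                lp += ps.clock.branch_rate_log_prior()
        return lp

    def log_posterior(self) -> float:
        return (self.settings.beta * sum(self.logliks.values())
                + self.log_coal + self.log_cal + self._hyper_log_prior())

    # ---------------------------------------------------------------- moves
    def _build_moves(self):
        n_free = max(1, len(self.free_nodes))
        moves = [
            _Move("root_age", 2.0, 0.4),
            # joint rate-up/ages-down scale: breaks the rate-height ridge
            _Move("updown", 3.0, 0.08),
        ]
        if self.free_nodes:
            moves.append(_Move("node_age", 2.0 + 0.5 * n_free, 0.0))
        for name in self.parts:
            moves.append(_Move(f"rate_scale:{name}", 3.0, 0.3))
            moves.append(_Move(f"rate_uniform:{name}", 0.5, 0.0))
            if self.parts[name].clock.variant == "UCLN":
                moves.append(_Move(f"ucld:{name}", 1.0, 0.5))
                moves.append(_Move(f"branch_rate:{name}", 0.5 * n_free, 0.5))
        if self.settings.estimate_demography:
            moves.append(_Move("N0", 1.5, 0.5))
            if self.settings.estimate_growth:
                moves.append(_Move("growth", 1.5, 2e-5))
        if self.settings.estimate_pmd:
            moves.append(_Move("delta", 1.5, 1.0))
        if self.sampled_tips:
            moves.append(_Move("tip_age", 1.0 + 0.5 * len(self.sampled_tips), 0.0))
        if not self.settings.fix_topology:
            moves.append(_Move("narrow_exchange", 0.25 * n_free, 0.0))
        w = np.array([m.weight for m in moves])
        self._cumw = np.cumsum(w / w.sum())
        return moves

    def _scale_factor(self, width):
        return math.exp(width * (self.rng.random() - 0.5) * 2.0)

    def _eval_dirty(self, dirty, only=None):
        """Recompute likelihoods for dirty internal nodes; returns saved
        partial state for restoration."""
        saved = {}
        if self.settings.sample_from_prior:
            return saved
        idx = np.asarray(dirty, dtype=np.int64)
        for name, eng in self.engines.items():
            if only is not None and name != only:
                continue
            saved[name] = (self.logliks[name], idx,
                           eng.partials[idx].copy(), eng.slog[idx].copy())
            self.logliks[name] = eng.compute(self.tree, self._branch_subs(name),
                                             dirty=dirty)
        return saved

    def _restore(self, saved):
        for name, (ll, idx, part, slog) in saved.items():
            eng = self.engines[name]
            eng.partials[idx] = part
            eng.slog[idx] = slog
            self.logliks[name] = ll

    def _mh_age_move(self, dirty, tip_restore=None):
        """Shared accept/reject for a move that changed node/tip ages."""
        old_coal, old_cal = self.log_coal, self.log_cal
        self.log_cal = self.prior(self.tree, rates=self._rates())
        if not np.isfinite(self.log_cal):
            self.log_cal = old_cal
            return False, {}, old_coal, old_cal
        self.log_coal = coalescent_log_density(self.tree, self.demography)
        saved = self._eval_dirty(dirty)
        return True, saved, old_coal, old_cal

    def step(self):
        m = self.moves[int(np.searchsorted(self._cumw, self.rng.random()))]
        m.proposed += 1
        name = m.name
        rng = self.rng
        tree = self.tree
        accepted = False

        if name == "node_age":
            v = self.free_nodes[int(rng.integers(len(self.free_nodes)))]
            lo = max(tree.age[tree.left[v]], tree.age[tree.right[v]])
            hi = tree.age[tree.parent[v]]
            if hi <= lo:
                return
            old_age = tree.age[v]
            old_post = self.log_posterior()
            tree.age[v] = lo + rng.random() * (hi - lo)
            ok, saved, oc, ocal = self._mh_age_move([v] + _ancestors(tree, tree.parent[v]))
            if ok and math.log(rng.random() + 1e-300) < self.log_posterior() - old_post:
                accepted = True
            else:
                tree.age[v] = old_age
                if ok:
                    self._restore(saved)
                self.log_coal, self.log_cal = oc, ocal

        elif name == "root_age":
            root = tree.root
            lo = max(tree.age[tree.left[root]], tree.age[tree.right[root]])
            old_age = tree.age[root]
            s = self._scale_factor(m.width)
            old_post = self.log_posterior()
            tree.age[root] = lo + (old_age - lo) * s
            ok, saved, oc, ocal = self._mh_age_move([root])
            if ok and math.log(rng.random() + 1e-300) < (
                    self.log_posterior() - old_post + math.log(s)):
                accepted = True
            else:
                tree.age[root] = old_age
                if ok:
                    self._restore(saved)
                self.log_coal, self.log_cal = oc, ocal

        elif name == "tip_age":
            i = self.sampled_tips[int(rng.integers(len(self.sampled_tips)))]
            sid = tree.tip_ids[i]
            width = 0.5 * self.cal.tip_priors[sid][1]
            old_age = tree.age[i]
            new_age = old_age + rng.normal(0.0, width)
            if new_age < 0 or new_age >= tree.age[tree.parent[i]]:
                return
            old_post = self.log_posterior()
            tree.age[i] = new_age
            tip_saved = None
            if self.pmd.delta > 0:
                tip_saved = {n: e.partials[i].copy()
                             for n, e in self.engines.items()}
                for e in self.engines.values():
                    e.set_tip_age(i, new_age)
            ok, saved, oc, ocal = self._mh_age_move(_ancestors(tree, i))
            if ok and math.log(rng.random() + 1e-300) < self.log_posterior() - old_post:
                accepted = True
            else:
                tree.age[i] = old_age
                if tip_saved is not None:
                    for n, e in self.engines.items():
                        e.partials[i] = tip_saved[n]
                        e.tip_ages[i] = old_age
                if ok:
                    self._restore(saved)
                self.log_coal, self.log_cal = oc, ocal

        elif name == "updown":
            s = self._scale_factor(m.width)
            internal = [v for v in tree.postorder()]
            old_ages = tree.age[internal].copy()
            new_ages = old_ages / s
            # tips are fixed: the rescaled ages must keep every parent older
            tree.age[internal] = new_ages
            valid = True
            for v in internal:
                if (tree.age[v] <= tree.age[tree.left[v]]
                        or tree.age[v] <= tree.age[tree.right[v]]):
                    valid = False
                    break
            if not valid:
                tree.age[internal] = old_ages
                return
            tree.age[internal] = old_ages
            old_rates = {n_: ps.clock.mean_rate for n_, ps in self.parts.items()}
            old_demo = self.demography
            old_post = self.log_posterior()
            tree.age[internal] = new_ages
            for ps in self.parts.values():
                ps.clock.mean_rate *= s
            log_h = (len(old_rates) - len(internal)) * math.log(s)
            if self.settings.estimate_demography:
                # rescale the demography with the time axis so the
                # coalescent density moves coherently with the node ages
                new_g = old_demo.growth_rate
                if self.settings.estimate_growth and new_g > 0:
                    new_g = new_g * s
                    log_h += math.log(s)
                self.demography = replace(old_demo, N0=old_demo.N0 / s,
                                          growth_rate=new_g)
                log_h += -math.log(s)  # Jacobian of N0 -> N0/s
            ok, saved, oc, ocal = self._mh_age_move(internal)
            if ok and math.log(rng.random() + 1e-300) < (
                    self.log_posterior() - old_post + log_h):
                accepted = True
            else:
                tree.age[internal] = old_ages
                for n_, ps in self.parts.items():
                    ps.clock.mean_rate = old_rates[n_]
                self.demography = old_demo
                if ok:
                    self._restore(saved)
                self.log_coal, self.log_cal = oc, ocal

        elif name.startswith("rate_scale:") or name.startswith("rate_uniform:"):
            pname = name.split(":", 1)[1]
            clock = self.parts[pname].clock
            old_rate = clock.mean_rate
            if name.startswith("rate_scale:"):
                s = self._scale_factor(m.width)
                new_rate, log_h = old_rate * s, math.log(s)
            else:
                lo, hi = self.cal.rate_bounds
                new_rate, log_h = lo + rng.random() * (hi - lo), 0.0
            old_post = self.log_posterior()
            old_cal = self.log_cal
            clock.mean_rate = new_rate
            self.log_cal = self.prior(tree, rates=self._rates())
            if np.isfinite(self.log_cal):
                saved = self._eval_dirty(list(tree.postorder()), only=pname) \
                    if pname in self.engines else {}
                if math.log(rng.random() + 1e-300) < (
                        self.log_posterior() - old_post + log_h):
                    accepted = True
                else:
                    clock.mean_rate = old_rate
                    self._restore(saved)
                    self.log_cal = old_cal
            else:
                clock.mean_rate = old_rate
                self.log_cal = old_cal

        elif name == "N0" or name == "growth":
            old_demo = self.demography
            old_post = self.log_posterior()
            if name == "N0":
                s = self._scale_factor(m.width)
                new = replace(old_demo, N0=old_demo.N0 * s)
                log_h = math.log(s)
            else:
                g = abs(old_demo.growth_rate + rng.normal(0.0, m.width))
                new = replace(old_demo, variant="exp_growth" if g > 0 else old_demo.variant,
                              growth_rate=g)
                log_h = 0.0
            old_coal = self.log_coal
            self.demography = new
            self.log_coal = coalescent_log_density(tree, new)
            if math.log(rng.random() + 1e-300) < (
                    self.log_posterior() - old_post + log_h):
                accepted = True
            else:
                self.demography = old_demo
                self.log_coal = old_coal

        elif name == "delta":
            old_pmd = self.pmd
            s = self._scale_factor(m.width)
            new_delta = old_pmd.delta * s if old_pmd.delta > 0 else 1e-10
            old_post = self.log_posterior()
            self.pmd = PMDModel(new_delta)
            saved = {n: (self.logliks[n], e.partials.copy(), e.slog.copy())
                     for n, e in self.engines.items()}
            for n, e in self.engines.items():
                e.set_pmd(self.pmd)
                self.logliks[n] = e.compute(tree, self._branch_subs(n))
            if math.log(rng.random() + 1e-300) < (
                    self.log_posterior() - old_post + math.log(s)):
                accepted = True
            else:
                self.pmd = old_pmd
                for n, e in self.engines.items():
                    ll, part, slog = saved[n]
                    e.pmd = old_pmd
                    e.partials[:] = part
                    e.slog[:] = slog
                    self.logliks[n] = ll

        elif name.startswith("ucld:"):
            pname = name.split(":", 1)[1]
            clock = self.parts[pname].clock
            old = clock.ucld_stdev
            s = self._scale_factor(m.width)
            old_post = self.log_posterior()
            clock.ucld_stdev = (old if old > 0 else 0.01) * s
            if math.log(rng.random() + 1e-300) < (
                    self.log_posterior() - old_post + math.log(s)):
                accepted = True
            else:
                clock.ucld_stdev = old

        elif name.startswith("branch_rate:"):
            pname = name.split(":", 1)[1]
            clock = self.parts[pname].clock
            if clock.branch_rates is None:
                clock.branch_rates = np.ones(tree.n_nodes)
            v = self.free_nodes[int(rng.integers(len(self.free_nodes)))]
            old = clock.branch_rates[v]
            s = self._scale_factor(m.width)
            old_post = self.log_posterior()
            clock.branch_rates[v] = old * s
            saved = self._eval_dirty(
                _ancestors(tree, tree.parent[v]) if tree.is_tip(v)
                else _ancestors(tree, v), only=pname) \
                if pname in self.engines else {}
            if math.log(rng.random() + 1e-300) < (
                    self.log_posterior() - old_post + math.log(s)):
                accepted = True
            else:
                clock.branch_rates[v] = old
                self._restore(saved)

        elif name == "narrow_exchange":
            accepted = self._narrow_exchange()

        if accepted:
            m.accepted += 1

    def _narrow_exchange(self) -> bool:
        tree = self.tree
        rng = self.rng
        internal = [v for v in self.free_nodes if not tree.is_tip(v)]
        if not internal:
            return False
        v = internal[int(rng.integers(len(internal)))]
        p = int(tree.parent[v])
        sib = int(tree.left[p]) if tree.right[p] == v else int(tree.right[p])
        c = int(tree.left[v]) if rng.random() < 0.5 else int(tree.right[v])
        if tree.age[sib] >= tree.age[v]:
            return False
        old_post = self.log_posterior()
        self._swap(p, sib, v, c)
        ok, saved, oc, ocal = self._mh_age_move(list(tree.postorder()))
        if ok and math.log(rng.random() + 1e-300) < self.log_posterior() - old_post:
            return True
        self._swap(p, c, v, sib)  # undo
        if ok:
            self._restore(saved)
        self.log_coal, self.log_cal = oc, ocal
        return False

    def _swap(self, p, sib, v, c):
        """Exchange sib (child of p) with c (child of v)."""
        tree = self.tree
        if tree.left[p] == sib:
            tree.left[p] = c
        else:
            tree.right[p] = c
        if tree.left[v] == c:
            tree.left[v] = sib
        else:
            tree.right[v] = sib
        tree.parent[c] = p
        tree.parent[sib] = v
        tree.invalidate_topology()

    # ----------------------------------------------------------------- tune
    def tune(self):
        for mv in self.moves:
            if mv.proposed < 30 or mv.width == 0.0:
                continue
            rate = mv.accepted / mv.proposed
            if rate > 0.30:
                mv.width *= 1.3
            elif rate < 0.18:
                mv.width /= 1.3
            mv.accepted = mv.proposed = 0

    # ------------------------------------------------------------- recording
    def record(self) -> dict:
        out = {"root_age": float(self.tree.age[self.tree.root]),
               "loglik": float(sum(self.logliks.values())),
               "log_posterior": float(self.log_posterior())}
        single = len(self.parts) == 1
        for name, ps in self.parts.items():
            key = "rate" if single else f"rate_{name}"
            out[key] = ps.clock.mean_rate
            if ps.clock.variant == "UCLN":
                out["ucld_stdev" if single else f"ucld_stdev_{name}"] = \
                    ps.clock.ucld_stdev
        if self.settings.estimate_demography:
            out["N0"] = self.demography.N0
            out["growth_rate"] = self.demography.growth_rate
        if self.settings.estimate_pmd:
            out["delta"] = self.pmd.delta
        return out


def mcmc_run(alignment: Alignment, annotation: SiteAnnotation, samples,
             calibration: CalibrationSpec, settings: MCMCSettings,
             partitions: dict | None = None, start_tree: TimeTree | None = None,
             demography: DemographicModel | None = None,
             pmd: PMDModel | None = None) -> MCMCResult:
    """Run one or more chains and pool their post-burn-in samples."""
    if settings.steps <= 0:
        raise ValidationError("steps must be positive")
    partitions = partitions or default_partitions()
    burn = settings.resolved_burn_in()
    tree_thin = settings.tree_thin or 10 * settings.thin
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)

    traces: dict = {}
    trees: list = []
    loglik_trace = []
    warn: list = []
    for ci in range(settings.n_chains):
        rng = np.random.default_rng(seeds[ci])
        chain = _Chain(alignment, annotation, samples, calibration, settings,
                       partitions, start_tree, demography, pmd, rng)
        rows = []
        lls = []
        for step in range(settings.steps):
            chain.step()
            if settings.adapt and step < burn and step % 250 == 249:
                chain.tune()
            if step >= burn:
                if (step - burn) % settings.thin == 0:
                    rows.append(chain.record())
                    lls.append(sum(chain.logliks.values()))
                if settings.store_trees and (step - burn) % tree_thin == 0:
                    assert np.all(chain.tree.branch_durations() >= 0)
                    trees.append(chain.tree.copy())
        for mv in chain.moves:
            if mv.proposed > 50 and mv.accepted == 0:
                warn.append(f"chain {ci}: operator {mv.name} accepted nothing")
        if not rows:
            raise ValidationError("no retained samples: steps <= burn_in")
        for key in rows[0]:
            traces.setdefault(key, []).append(
                np.array([r[key] for r in rows]))
        loglik_trace.append(np.array(lls))
    summary = PosteriorSummary(traces)
    low = summary.low_ess_parameters()
    if low:
        warn.append(f"pooled ESS < 200 for {low}")
    return MCMCResult(summary, traces, trees, loglik_trace, settings, warn)
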