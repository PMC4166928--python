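"""Independent oracles used by several test modules.

Everything here is deliberately naive (exhaustive enumeration, brute-force
scans) and shares no code path with the implementations it checks.
"""

import itertools

import numpy as np

from mitoclock.likelihood import pmd_tip_partials
from mitoclock.simulate import PMDModel
from mitoclock.substitution import transition_matrix


def brute_force_loglik(tree, codes, spec, mu, pmd=None, branch_rates=None):
    """Exhaustive sum over all internal-node state assignments (<=5 taxa)."""
    pmd = pmd or PMDModel(0.0)
    rates, wts = spec.category_rates()
    pi = np.asarray(spec.pi)
    n = tree.n_tips
    assert n <= 5, "oracle is exponential in taxa"
    post = list(tree.postorder())
    mult = np.ones(2 * n - 1) if branch_rates is None else branch_rates
    total = 0.0
    for s in range(codes.shape[1]):
        site_l = 0.0
        for r, w in zip(rates, wts):
            P = {v: transition_matrix(spec, mu * tree.branch_length(v) * mult[v] * r)
                 for v in range(2 * n - 1) if v != tree.root}
            lsum = 0.0
            for assign in itertools.product(range(4), repeat=n - 1):
                states = dict(zip(post, assign))
                p = pi[states[tree.root]]
                for v in post:
                    for ch in (tree.left[v], tree.right[v]):
                        if ch < n:
                            tp = pmd_tip_partials(int(codes[ch, s]), tree.age[ch], pmd)
                            p *= float((P[ch][states[v]] * tp).sum())
                        else:
                            p *= P[ch][states[v], states[ch]]
                lsum += p
            site_l += w * lsum
        total += np.log(site_l)
    return total


def brute_force_singletons(codes, ids):
    """Column-by-column singleton recount with explicit python logic."""
    n_deam = {i: 0 for i in ids}
    n_other = {i: 0 for i in ids}
    for col in range(codes.shape[1]):
        column = [(i, int(c)) for i, c in enumerate(codes[:, col]) if c < 4]
        if len(column) < 3:
            continue
        values = [c for _, c in column]
        distinct = sorted(set(values))
        if len(distinct) != 2:
            continue
        counts = {d: values.count(d) for d in distinct}
        minor = min(distinct, key=lambda d: counts[d])
        major = max(distinct, key=lambda d: counts[d])
        if counts[minor] != 1 or counts[major] < 2:
            continue
        row = next(i for i, c in column if c == minor)
        # deamination-consistent: majority C & focal T, or majority G & focal A
        if (major, minor) in {(1, 3), (2, 0)}:
            n_deam[ids[row]] += 1
        else:
            n_other[ids[row]] += 1
    return n_deam, n_other


def brute_force_bipartitions(tree):
    """Non-trivial splits by explicit leaf-set recursion."""
    all_tips = frozenset(tree.tip_ids)
    ref = min(all_tips)
    splits = set()

    def leaves(v):
        if tree.is_tip(v):
            return frozenset([tree.tip_ids[v]])
        return leaves(tree.left[v]) | leaves(tree.right[v])

    for v in range(tree.n_tips, 2 * tree.n_tips - 1):
        if v == tree.root:
            continue
        side = leaves(v)
        if 2 <= len(side) <= len(all_tips) - 2:
            splits.add(side if ref not in side else all_tips - side)
    return splits


def brute_force_hpd(samples, level=0.95):
    """All contiguous windows over the sorted sample, shortest wins."""
    import math

    x = sorted(samples)
    n = len(x)
    m = math.ceil(level * n)
    best = None
    for k in range(n - m + 1):
        w = x[k + m - 1] - x[k]
        if best is None or w < best[0]:
            best = (w, x[k], x[k + m - 1])
    return best[1], best[2]
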