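"""Rooted binary time trees with node ages in years before present (BP).

The same object serves as the simulated genealogy and as the tree sampled
by MCMC.  Nodes are indexed ``0 .. n_tips-1`` for tips (in the order of
``tip_ids``) and ``n_tips .. 2*n_tips-2`` for internal nodes; the root may
be any internal index.  Ages increase into the past, so every parent is
strictly older than its children.
"""

from __future__ import annotations

import numpy as np
import dendropy

from mitoclock.errors import StructureError

AGE_TOL = 1e-9  # years; tolerance on parent > child


class TimeTree:
    """Rooted binary genealogy with node ages in years BP."""

    __slots__ = ("tip_ids", "parent", "left", "right", "age", "root", "_postorder")

    def __init__(self, tip_ids, parent, left, right, age, root, validate=True):
        self.tip_ids = list(tip_ids)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.float64)
        self.root = int(root)
        self._postorder = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def _validate(self) -> None:
        n = self.n_nodes
        if self.parent.shape != (n,) or self.age.shape != (n,):
            raise StructureError("inconsistent array sizes for a binary tree")
        for v in range(n):
            p = self.parent[v]
            if v == self.root:
                if p != -1:
                    raise StructureError("root must have parent -1")
                continue
            if not (0 <= p < n):
                raise StructureError(f"node {v} has invalid parent {p}")
            if self.age[p] - self.age[v] < -AGE_TOL:
                raise StructureError(
                    f"negative branch: node {v} (age {self.age[v]:.6g}) older "
                    f"than its parent {p} (age {self.age[p]:.6g})"
                )

    def copy(self) -> "TimeTree":
        return TimeTree(
            self.tip_ids,
            self.parent.copy(),
            self.left.copy(),
            self.right.copy(),
            self.age.copy(),
            self.root,
            validate=False,
        )

    # -------------------------------------------------------------- traversal
    def invalidate_topology(self) -> None:
        """Call after an in-place change to parent/left/right arrays."""
        self._postorder = None

    def postorder(self) -> np.ndarray:
        """Internal node indices, children always before parents (cached)."""
        if self._postorder is not None:
            return self._postorder
        order = []
        stack = [(self.root, False)]
        while stack:
            v, expanded = stack.pop()
            if self.is_tip(v):
                continue
            if expanded:
                order.append(v)
            else:
                stack.append((v, True))
                stack.append((self.left[v], False))
                stack.append((self.right[v], False))
        self._postorder = np.asarray(order, dtype=np.int64)
        return self._postorder

    def branch_length(self, v: int) -> float:
        """Duration in years of the branch from ``v`` up to its parent."""
        if v == self.root:
            raise StructureError("root has no parent branch")
        return float(self.age[self.parent[v]] - self.age[v])

    def branch_durations(self) -> np.ndarray:
        """Per-node parent-branch duration in years (0 at the root slot)."""
        out = self.age[self.parent] - self.age
        out[self.root] = 0.0
        return out

    # ------------------------------------------------------------------ query
    def tip_index(self, tip_id: str) -> int:
        try:
            return self.tip_ids.index(tip_id)
        except ValueError:
            raise StructureError(f"unknown tip id {tip_id!r}") from None

    def mrca(self, tip_ids) -> int:
        """Index of the most recent common ancestor of a set of tip ids."""
        return self.mrca_indices([self.tip_index(t) for t in tip_ids])

    def mrca_indices(self, idx) -> int:
        """MRCA node index from tip indices (avoids label lookups)."""
        if not idx:
            raise StructureError("mrca of an empty tip set")
        if len(idx) == 1:
            return idx[0]
        # ancestors of the first tip; successively restrict to the root path
        # of the common ancestor with each further tip
        anc = set()
        v = idx[0]
        while v != -1:
            anc.add(v)
            v = self.parent[v]
        for t in idx[1:]:
            v = t
            while v not in anc:
                v = self.parent[v]
            anc = set()
            while v != -1:
                anc.add(v)
                v = self.parent[v]
        return min(anc, key=lambda a: self.age[a])

    def clade_tips(self, v: int) -> frozenset:
        """Tip ids below node ``v`` (inclusive for a tip)."""
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(self.tip_ids[u])
            else:
                stack.append(self.left[u])
                stack.append(self.right[u])
        return frozenset(out)

    def tmrca(self, tip_ids) -> float:
        """Age in years BP of the MRCA of ``tip_ids``."""
        v = self.mrca(tip_ids)
        return float(self.age[v])

    # ----------------------------------------------------------- bipartitions
    def bipartitions(self) -> set:
        """Non-trivial unrooted bipartitions as canonical frozensets.

        Each internal edge of the unrooted version of the tree splits the
        tips in two; the split is represented by the side not containing
        the lexicographically smallest tip id.
        """
        all_tips = frozenset(self.tip_ids)
        ref = min(all_tips)
        splits = set()
        for v in self.postorder():
            if v == self.root:
                continue
            side = self.clade_tips(v)
            if len(side) < 2 or len(side) > len(all_tips) - 2:
                continue  # trivial split
            if ref in side:
                side = all_tips - side
            splits.add(side)
        return splits

    # --------------------------------------------------------------- pruning
    def prune_to(self, keep_ids) -> "TimeTree":
        """Restriction of the tree to a tip subset, unifurcations suppressed."""
        keep = set(keep_ids)
        missing = keep - set(self.tip_ids)
        if missing:
            raise StructureError(f"cannot prune to unknown tips {sorted(missing)}")
        if len(keep) < 2:
            raise StructureError("pruned tree needs at least 2 tips")
        d = self.to_dendropy()
        taxa = [t for t in d.taxon_namespace if t.label in keep]
        d.retain_taxa(taxa)
        return TimeTree.from_dendropy(d)

    # ------------------------------------------------------------ conversion
    def to_dendropy(self) -> dendropy.Tree:
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        nodes = {}
        for v in range(self.n_tips):
            nd = dendropy.Node()
            nd.taxon = ns.new_taxon(self.tip_ids[v])
            nodes[v] = nd
        for v in self.postorder():
            nd = dendropy.Node()
            nd.add_child(nodes[self.left[v]])
            nd.add_child(nodes[self.right[v]])
            nodes[v] = nd
        for v, nd in nodes.items():
            if v != self.root:
                nd.edge.length = self.branch_length(v)
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True
        return tree

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, tip_ages=None) -> "TimeTree":
        """Build from a dendropy tree whose edge lengths are in years.

        ``tip_ages`` maps tip label to age in years BP; tips default to age
        0.  Internal ages are recovered from tip ages plus branch lengths
        and must be consistent along every root-to-tip path.
        """
        leaves = [lf for lf in tree.leaf_node_iter()]
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf() and len(nd.child_nodes()) != 2:
                raise StructureError(
                    "binary tree required; found a node with "
                    f"{len(nd.child_nodes())} children"
                )
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise StructureError("duplicate tip labels")
        tip_ages = tip_ages or {}
        n = len(labels)
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        nxt = n
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        left = np.full(2 * n - 1, -1, dtype=np.int64)
        right = np.full(2 * n - 1, -1, dtype=np.int64)
        age = np.zeros(2 * n - 1)
        for i, lf in enumerate(leaves):
            age[i] = float(tip_ages.get(lf.taxon.label, 0.0))
        for nd in tree.postorder_internal_node_iter():
            v = nxt
            nxt += 1
            index[id(nd)] = v
            c1, c2 = nd.child_nodes()
            i1, i2 = index[id(c1)], index[id(c2)]
            left[v], right[v] = i1, i2
            parent[i1] = parent[i2] = v
            a1 = age[i1] + (c1.edge.length or 0.0)
            a2 = age[i2] + (c2.edge.length or 0.0)
            if abs(a1 - a2) > max(1e-6, 1e-8 * max(abs(a1), abs(a2))):
                raise StructureError(
                    f"inconsistent node age from the two child paths: {a1} vs {a2}"
                )
            if (c1.edge.length or 0.0) < 0 or (c2.edge.length or 0.0) < 0:
                raise StructureError("negative branch length")
            age[v] = 0.5 * (a1 + a2)
        root = index[id(tree.seed_node)]
        return cls(labels, parent, left, right, age, root)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TimeTree(n_tips={self.n_tips}, root_age={self.age[self.root]:.6g} y BP)"
        )
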