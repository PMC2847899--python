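"""Neighbor-joining trees, bootstrap split support, majority-rule consensus.

Trees are unrooted; they are stored with an arbitrary internal node as
the display root (trifurcating for a binary unrooted tree), which is the
usual Newick convention.  An internal edge corresponds to a bipartition
(split) of the leaf set; supports are percentages of bootstrap
replicates whose tree contains the same split.

The agglomeration is the standard Saitou-Nei algorithm: repeatedly join
the pair minimising ``Q_ij = (n-2) d_ij - R_i - R_j`` (``R`` = row
sums), with branch lengths from the usual NJ formulas.  Ties in Q are
broken toward the lowest (row, column) index pair so output is
deterministic across platforms.  Negative branch lengths, which NJ can
produce on non-additive input, are retained; the Newick writer can clamp
them to zero for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "PhyloNode",
    "Phylotree",
    "neighbor_joining",
    "bipartition_support",
    "majority_rule_consensus",
]


@dataclass
class PhyloNode:
    """Tree node; ``label`` set on leaves, ``support`` on internal edges."""

    label: str | None = None
    length: float | None = None  # edge to parent
    support: float | None = None
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["PhyloNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_labels()
        return frozenset(out)


class Phylotree:
    """Unrooted tree with branch lengths and per-split support."""

    def __init__(self, root: PhyloNode):
        self.root = root
        labels = [n.label for n in root.walk() if n.is_leaf]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        for n in root.walk():
            if n.length is not None and not np.isfinite(n.length):
                raise ValueError("branch lengths must be finite")

    # ------------------------------------------------------------------
    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_edges(self) -> int:
        return sum(1 for n in self.root.walk()) - 1

    def splits(self) -> dict[frozenset[str], PhyloNode]:
        """Non-trivial bipartitions keyed by their normalised leaf side.

        A split is normalised to the side *not* containing the
        lexicographically smallest leaf, making it invariant to the
        display rooting.
        """
        all_leaves = self.leaf_labels
        anchor = min(all_leaves)
        out: dict[frozenset[str], PhyloNode] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_labels()
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[side] = node
        return out

    def copy(self) -> "Phylotree":
        def rec(n: PhyloNode) -> PhyloNode:
            return PhyloNode(n.label, n.length, n.support, [rec(c) for c in n.children])

        return Phylotree(rec(self.root))

    # ---------------- Newick ----------------
    def to_newick(self, clamp_negative: bool = False, support_format: str = "{:g}") -> str:
        """Serialise to Newick; supports become internal-node labels."""

        def fmt_len(x: float | None) -> str:
            if x is None:
                return ""
            if clamp_negative and x < 0:
                x = 0.0
            return f":{x:.10g}"

        def rec(n: PhyloNode) -> str:
            if n.is_leaf:
                return n.label + fmt_len(n.length)
            inner = ",".join(rec(c) for c in n.children)
            label = support_format.format(n.support) if n.support is not None else ""
            return f"({inner}){label}{fmt_len(n.length)}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Phylotree":
        """Parse Newick (internal-node labels read as support values)."""
        dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

        def rec(dnode) -> PhyloNode:
            if dnode.is_leaf():
                return PhyloNode(label=dnode.taxon.label.replace(" ", "_"),
                                 length=dnode.edge.length)
            support = None
            if dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    pass
            return PhyloNode(
                label=None,
                length=dnode.edge.length,
                support=support,
                children=[rec(c) for c in dnode.child_nodes()],
            )

        return cls(rec(dtree.seed_node))

    def __repr__(self) -> str:
        return f"Phylotree({self.n_leaves} leaves)"


def neighbor_joining(m: DistanceMatrix) -> Phylotree:
    """Saitou-Nei neighbor joining on a labelled distance matrix.

    Produces an unrooted tree displayed with a trifurcating root (for
    three or more taxa).  On an additive matrix the true topology and
    branch lengths are recovered exactly.
    """
    n = m.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = m.values.astype(float).copy()
    nodes: list[PhyloNode] = [PhyloNode(label=l) for l in m.labels]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, column) pair among minima: argmin scans row-major
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        parent = PhyloNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances from the new node to every other active node
        new = np.zeros(d.shape[0] + 1)
        for a in active:
            if a in (i, j):
                continue
            new[a] = 0.5 * (d[i, a] + d[j, a] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new[:-1]
        d[:-1, -1] = new[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final 3-way join
    i, j, k3 = active
    a = 0.5 * (d[i, j] + d[i, k3] - d[j, k3])
    b = 0.5 * (d[i, j] + d[j, k3] - d[i, k3])
    c = 0.5 * (d[i, k3] + d[j, k3] - d[i, j])
    nodes[i].length, nodes[j].length, nodes[k3].length = a, b, c
    root = PhyloNode(children=[nodes[i], nodes[j], nodes[k3]])
    return Phylotree(root)


def bipartition_support(reference: Phylotree, boot: Sequence[Phylotree]) -> Phylotree:
    """Annotate a tree's internal edges with bootstrap split percentages.

    Every replicate must cover the same leaf set; each internal edge of
    *reference* receives ``100 * (replicates containing the same
    bipartition) / B``.
    """
    if not boot:
        raise ValueError("empty bootstrap set")
    for t in boot:
        if t.leaf_labels != reference.leaf_labels:
            raise ValueError("bootstrap tree leaf set differs from reference")
    counts: dict[frozenset[str], int] = {}
    for t in boot:
        for split in t.splits():
            counts[split] = counts.get(split, 0) + 1
    out = reference.copy()
    for split, node in out.splits().items():
        node.support = 100.0 * counts.get(split, 0) / len(boot)
    return out


def majority_rule_consensus(trees: Sequence[Phylotree]) -> Phylotree:
    """Strict-majority (>50%) consensus of trees on a shared leaf set.

    The output contains exactly the splits present in more than half of
    the inputs, each annotated with its percentage frequency.  Such
    splits are pairwise compatible by construction, so the tree always
    exists; branch lengths are not assigned.
    """
    if not trees:
        raise ValueError("empty tree list")
    leaves = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leaves:
            raise ValueError("trees must share one leaf set")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in t.splits():
            counts[split] = counts.get(split, 0) + 1
    ntrees = len(trees)
    majority = {s: c for s, c in counts.items() if c * 2 > ntrees}

    anchor = min(leaves)
    # clusters on the side away from the anchor; nest by containment
    clusters = sorted(majority, key=len, reverse=True)
    root = PhyloNode()
    node_of: dict[frozenset[str], PhyloNode] = {}

    def smallest_container(target: frozenset[str], candidates: list[frozenset[str]]):
        best = None
        for c in candidates:
            if c != target and target <= c and (best is None or len(c) < len(best)):
                best = c
        return best

    for cl in clusters:
        node = PhyloNode(support=100.0 * majority[cl] / ntrees)
        parent_cl = smallest_container(cl, clusters[: clusters.index(cl)])
        (node_of[parent_cl] if parent_cl is not None else root).children.append(node)
        node_of[cl] = node
    for leaf in sorted(leaves):
        if leaf == anchor:
            root.children.append(PhyloNode(label=leaf))
            continue
        parent_cl = smallest_container(frozenset([leaf]), clusters)
        target = root
        if parent_cl is not None:
            target = node_of[parent_cl]
        else:
            containing = [c for c in clusters if leaf in c]
            if containing:
                target = node_of[min(containing, key=len)]
        target.children.append(PhyloNode(label=leaf))
    return Phylotree(root)
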