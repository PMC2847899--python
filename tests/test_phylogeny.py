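"""Neighbor joining, split support, consensus — with a brute-force oracle.

The oracle enumerates every unrooted binary topology (by sequential
leaf insertion) and identifies the one whose branch lengths, fitted by
least squares on the path-incidence system, reproduce the input matrix
exactly.  For an additive matrix that topology is unique, so NJ must
return it.
"""

import itertools

import numpy as np
import pytest

from strpop.distance import DistanceMatrix
from strpop.phylogeny import (
    PhyloNode,
    Phylotree,
    bipartition_support,
    majority_rule_consensus,
    neighbor_joining,
)


# ----------------------------------------------------------------------
# oracle helpers: random additive trees + topology enumeration
# ----------------------------------------------------------------------

def random_additive(n, rng):
    """Random unrooted binary tree -> (labels, distance matrix, split set)."""
    adj = {0: {}, 1: {}, 2: {}, 3: {}}
    for a in (0, 1, 2):
        w = rng.uniform(0.5, 2.0)
        adj[a][3] = adj.setdefault(3, {}).setdefault(a, w) or w
        adj[3][a] = w
        adj[a] = {3: w}
    nxt, leaves = 4, [0, 1, 2]
    for _ in range(3, n):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid, leaf = nxt, nxt + 1
        nxt += 2
        c = rng.uniform(0.3, 0.7)
        del adj[u][v], adj[v][u]
        adj[mid] = {u: w * c, v: w * (1 - c), leaf: rng.uniform(0.5, 2.0)}
        adj[u][mid] = w * c
        adj[v][mid] = w * (1 - c)
        adj[leaf] = {mid: adj[mid][leaf]}
        leaves.append(leaf)

    labels = [f"T{i}" for i in range(n)]
    name = dict(zip(leaves, labels))
    # all-pairs path lengths by DFS from each leaf
    D = np.zeros((n, n))
    for i, s in enumerate(leaves):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, t in enumerate(leaves):
            D[i, j] = dist[t]
    allset = frozenset(labels)
    anchor = min(allset)
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                seen = {u}
                stack = [u]
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        if {x, y} == {u, v}:
                            continue
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                side = frozenset(name[x] for x in seen if x in name)
                if anchor in side:
                    side = allset - side
                if 2 <= len(side) <= n - 2:
                    splits.add(side)
    return labels, D, splits


def enumerate_topologies(labels):
    """Yield split sets of every unrooted binary topology on the labels."""
    n = len(labels)

    def build(tree_edges, next_internal, remaining):
        if not remaining:
            yield tree_edges
            return
        leaf = remaining[0]
        for idx in range(len(tree_edges)):
            u, v = tree_edges[idx]
            mid = next_internal
            new_edges = tree_edges[:idx] + tree_edges[idx + 1:]
            new_edges += [(u, mid), (mid, v), (mid, leaf)]
            yield from build(new_edges, next_internal + 1, remaining[1:])

    start = [(labels[0], "I0"), (labels[1], "I0"), (labels[2], "I0")]
    for edges in build(start, 1, labels[3:]):
        adj = {}
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        allset = frozenset(labels)
        anchor = min(allset)
        splits = set()
        for u, v in edges:
            seen = {u}
            stack = [u]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if {x, y} == {u, v}:
                        continue
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            side = frozenset(x for x in seen if x in allset)
            if anchor in side:
                side = allset - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        yield frozenset(splits), edges


def least_squares_fit_error(labels, D, edges):
    """Residual of fitting branch lengths to D on a fixed topology."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, {})[v] = None
        adj.setdefault(v, {})[u] = None
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        # path from labels[i] to labels[j]
        start, goal = labels[i], labels[j]
        prev = {start: None}
        stack = [start]
        while stack:
            x = stack.pop()
            if x == goal:
                break
            for nb in adj[x]:
                if nb not in prev:
                    prev[nb] = x
                    stack.append(nb)
        node = goal
        while prev[node] is not None:
            A[row, edge_index[frozenset((node, prev[node]))]] = 1.0
            node = prev[node]
        y[row] = D[i, j]
    coef, residual, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = neighbor_joining(DistanceMatrix(list("ABC"), d))
        lengths = {n.label: n.length for n in t.root.children}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_example(self):
        """Additive matrix of ((A:1,B:2):1,(C:3,D:4)) is recovered exactly."""
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert set(t.splits()) == {frozenset({"C", "D"})}  # AB|CD, far side of A
        lengths = {n.label: n.length for n in t.root.walk() if n.is_leaf}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [n.length for n in t.root.walk() if not n.is_leaf and n.length]
        assert internal == pytest.approx([1.0])

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_topologies(self, n):
        rng = np.random.default_rng(n)
        for _ in range(15):
            labels, D, true_splits = random_additive(n, rng)
            t = neighbor_joining(DistanceMatrix(labels, D))
            assert set(t.splits()) == true_splits

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_against_enumeration_oracle(self, n):
        """NJ output matches the unique zero-residual topology."""
        rng = np.random.default_rng(100 + n)
        for _ in range(3):
            labels, D, _ = random_additive(n, rng)
            fits = [
                (least_squares_fit_error(labels, D, edges), splits)
                for splits, edges in enumerate_topologies(labels)
            ]
            zero = [s for err, s in fits if err < 1e-16]
            assert len(zero) == 1
            t = neighbor_joining(DistanceMatrix(labels, D))
            assert frozenset(t.splits()) == zero[0]

    def test_leaf_and_edge_counts(self, full_loci_freqs):
        from strpop.distance import pairwise_matrix

        m = pairwise_matrix(full_loci_freqs, "DA")
        t = neighbor_joining(m)
        assert t.n_leaves == m.n
        assert t.n_edges == 2 * m.n - 3

    def test_rejects_small_input(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))


# ----------------------------------------------------------------------
# support and consensus
# ----------------------------------------------------------------------

def _tree_from_newick(text):
    return Phylotree.from_newick(text)


class TestBipartitionSupport:
    def test_identical_replicates_give_100(self):
        ref = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        out = bipartition_support(ref, [ref.copy() for _ in range(100)])
        supports = [n.support for n in out.splits().values()]
        assert supports and all(s == 100.0 for s in supports)

    def test_half_replicates_give_50(self):
        ref = _tree_from_newick("((A:1,B:1):1,C:1,D:1);")
        alt = _tree_from_newick("((A:1,C:1):1,B:1,D:1);")
        out = bipartition_support(ref, [ref.copy()] * 5 + [alt.copy()] * 5)
        (support,) = [n.support for n in out.splits().values()]
        assert support == 50.0

    def test_support_invariant_to_replicate_order(self):
        ref = _tree_from_newick("((A:1,B:1):1,C:1,D:1);")
        alt = _tree_from_newick("((A:1,C:1):1,B:1,D:1);")
        boots = [ref.copy()] * 3 + [alt.copy()] * 7
        s1 = [n.support for n in bipartition_support(ref, boots).splits().values()]
        s2 = [n.support for n in bipartition_support(ref, boots[::-1]).splits().values()]
        assert s1 == s2

    def test_leaf_set_mismatch_errors(self):
        ref = _tree_from_newick("((A:1,B:1):1,C:1,D:1);")
        other = _tree_from_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError, match="leaf set"):
            bipartition_support(ref, [other])

    def test_deep_clade_gets_high_support(self, full_loci_freqs):
        """A strongly differentiated language-group clade exceeds 90% support."""
        from strpop.distance import bootstrap_over_loci, pairwise_matrix

        boot = bootstrap_over_loci(full_loci_freqs, "DA", B=200, seed=5)
        ref = neighbor_joining(pairwise_matrix(full_loci_freqs, "DA"))
        out = bipartition_support(ref, [neighbor_joining(m) for m in boot.replicates])
        assert max(n.support for n in out.splits().values()) > 90.0


class TestConsensus:
    def test_identical_inputs(self):
        ref = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        cons = majority_rule_consensus([ref.copy() for _ in range(4)])
        assert set(cons.splits()) == set(ref.splits())
        assert all(n.support == 100.0 for n in cons.splits().values())

    def test_two_thirds_majority(self):
        t1 = _tree_from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = _tree_from_newick("((A:1,B:1):1,C:1,D:1);")
        t3 = _tree_from_newick("((A:1,C:1):1,B:1,D:1);")
        cons = majority_rule_consensus([t1, t2, t3])
        splits = cons.splits()
        assert set(splits) == {frozenset({"C", "D"})}  # AB|CD normalised away from A
        (node,) = splits.values()
        assert node.support == pytest.approx(200 / 3)

    def test_consensus_of_bootstrap_is_compatible(self, full_loci_freqs):
        from strpop.distance import bootstrap_over_loci

        boot = bootstrap_over_loci(full_loci_freqs, "DC", B=60, seed=8)
        cons = majority_rule_consensus([neighbor_joining(m) for m in boot.replicates])
        splits = list(cons.splits())
        allset = cons.leaf_labels
        for s1, s2 in itertools.combinations(splits, 2):
            assert (
                s1 <= s2 or s2 <= s1 or not (s1 & s2) or (s1 | s2) == allset
            ), "incompatible splits in majority-rule consensus"

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            majority_rule_consensus([])


class TestNewick:
    def test_writer_round_trip_bit_exact(self):
        t = _tree_from_newick("((A:1.5,B:2.25)80:0.5,(C:3,D:4)95:0.125,E:1);")
        text = t.to_newick()
        again = Phylotree.from_newick(text).to_newick()
        assert text == again

    def test_negative_length_clamping(self):
        root = PhyloNode(children=[
            PhyloNode("A", -0.5), PhyloNode("B", 1.0), PhyloNode("C", 2.0)
        ])
        t = Phylotree(root)
        assert ":-0.5" in t.to_newick()
        assert ":0" in t.to_newick(clamp_negative=True)
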