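import itertools
import random

import numpy as np
import pytest

from mybscan.phylogeny_engine import (MultipleAlignment, PhyloTree, align, build_tree,
                                      neighbor_joining, p_distance_matrix)
from mybscan.sequence_io import SequenceRecord


class TestAlign:
    def test_identical_sequences_align_gapless(self):
        msa = align([SequenceRecord("a", "MKWVL"), SequenceRecord("b", "MKWVL")])
        assert msa.rows == {"a": "MKWVL", "b": "MKWVL"}

    def test_single_deletion_creates_one_gap(self):
        # exhaustive check: every global alignment of MKW vs MW with affine
        # BLOSUM62 scoring that keeps both W and M matched has length 3 and
        # one gap in the shorter row
        msa = align([SequenceRecord("a", "MKW"), SequenceRecord("b", "MW")])
        assert msa.length == 3
        assert msa.rows["a"] == "MKW"
        assert msa.rows["b"].count("-") == 1
        assert msa.ungapped("b") == "MW"

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_ungapping_reproduces_inputs(self, n):
        rng = random.Random(n)
        recs = [SequenceRecord(f"s{i}", "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                                                for _ in range(rng.randint(20, 60))))
                for i in range(n)]
        msa = align(recs)
        for rec in recs:
            assert msa.ungapped(rec.id) == rec.residues

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError):
            align([SequenceRecord("a", "MKW")])

    def test_row_order_permutation_gives_same_columns(self, family):
        recs = family.baits[:10]
        msa1 = align(recs)
        msa2 = align(list(reversed(recs)))
        assert msa1.rows == msa2.rows  # dict comparison ignores insertion order


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # star tree: L_A = (dAB+dAC-dBC)/2 etc.
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = neighbor_joining(["A", "B", "C"], D)
        assert tree.distance("A", "B", "branch_length_sum") == pytest.approx(2.0)
        assert tree.distance("A", "C", "branch_length_sum") == pytest.approx(4.0)
        assert tree.distance("B", "C", "branch_length_sum") == pytest.approx(4.0)
        assert tree.distance("A", "B") == 2  # star: every pair 2 edges apart

    def test_four_taxa_recovers_generating_topology(self):
        # additive matrix for ((A,B),(C,D)): checked against the four-point
        # condition by brute force over the three possible topologies
        D = np.array([[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 4], [7, 7, 4, 0]], float)
        sums = {"AB|CD": D[0, 1] + D[2, 3], "AC|BD": D[0, 2] + D[1, 3],
                "AD|BC": D[0, 3] + D[1, 2]}
        assert min(sums, key=sums.get) == "AB|CD"  # four-point: true split has min sum
        tree = neighbor_joining(["A", "B", "C", "D"], D)
        assert tree.distance("A", "B") == 2
        assert tree.distance("A", "C") == 3

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (5, 2), (6, 3), (6, 4)])
    def test_consistency_on_additive_matrices(self, n, seed):
        labels, D, true_splits = _random_additive(n, seed)
        tree = neighbor_joining(labels, D)
        assert _splits(tree) == true_splits
        # and the branch-length sums reproduce the generating distances
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tree.distance(a, b, "branch_length_sum") == pytest.approx(
                        D[i, j], abs=1e-4)

    def test_topology_invariant_under_label_permutation(self):
        labels, D, _ = _random_additive(6, 7)
        t1 = neighbor_joining(labels, D)
        perm = list(range(6))
        random.Random(0).shuffle(perm)
        t2 = neighbor_joining([labels[i] for i in perm], D[np.ix_(perm, perm)])
        assert _splits(t1) == _splits(t2)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B"], np.zeros((2, 2)))


class TestBuildTree:
    def test_builtin_tree_covers_all_rows(self, family):
        msa = align(family.baits[:8])
        tree = build_tree(msa)
        assert tree.leaf_labels == {r.id for r in family.baits[:8]}

    def test_external_and_builtin_backends_same_leaf_set(self, family):
        import shutil
        if shutil.which("fasttree") is None and shutil.which("FastTree") is None:
            pytest.skip("FastTree not installed")
        msa = align(family.baits[:8])
        builtin = build_tree(msa, method="builtin")
        external = build_tree(msa, method="fasttree")
        assert builtin.leaf_labels == external.leaf_labels

    def test_small_alignment_rejected(self):
        msa = MultipleAlignment(rows={"a": "MKW", "b": "MKW"})
        with pytest.raises(ValueError):
            build_tree(msa)


class TestNewickIO:
    def test_round_trip_preserves_leaves_and_lengths(self):
        text = "(A:1,B:2,C:3);"
        tree = PhyloTree.from_newick(text)
        again = PhyloTree.from_newick(tree.to_newick())
        assert again.leaf_labels == {"A", "B", "C"}
        assert again.distance("A", "B", "branch_length_sum") == pytest.approx(3.0)

    def test_missing_branch_lengths_default_to_one(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        assert tree.distance("A", "B", "branch_length_sum") == pytest.approx(2.0)
        assert tree.distance("A", "C") == 3

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PhyloTree.from_newick("((A,B),A);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("((A,B,C);")


class TestPDistance:
    def test_pairwise_complete_columns_only(self):
        msa = MultipleAlignment(rows={"a": "MK-W", "b": "MKAW", "c": "M--W"})
        labels, D = p_distance_matrix(msa)
        i, j, k = labels.index("a"), labels.index("b"), labels.index("c")
        assert D[i, j] == 0.0      # 3 shared columns, all equal
        assert D[i, k] == 0.0      # 2 shared columns
        assert D[j, k] == 0.0


def _random_additive(n, seed):
    """Random binary unrooted tree with positive lengths -> additive matrix."""
    rng = random.Random(seed)
    labels = [chr(ord("A") + i) for i in range(n)]
    # random sequential joining to build a tree as an adjacency map
    nodes = list(range(n))
    adj = {i: [] for i in range(n)}
    nxt = n
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        a, b = nodes[j], nodes[i]
        u = nxt
        nxt += 1
        adj[u] = []
        for x in (a, b):
            w = rng.uniform(0.5, 2.0)
            adj[u].append((x, w))
            adj[x].append((u, w))
        nodes = [x for x in nodes if x not in (a, b)] + [u]
    center = nxt
    adj[center] = []
    for x in nodes:
        w = rng.uniform(0.5, 2.0)
        adj[center].append((x, w))
        adj[x].append((center, w))

    def dist(a, b):
        stack, seen = [(a, 0.0)], {a}
        while stack:
            u, d = stack.pop()
            if u == b:
                return d
            for v, w in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append((v, d + w))
        raise AssertionError

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = dist(i, j)

    # true splits: remove each internal edge, collect leaf bipartitions
    splits = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < v and u >= n and v >= n:
                side = _component_leaves(adj, v, u, n)
                splits.add(frozenset(labels[i] for i in side))
    return labels, D, {_canon(s, set(labels)) for s in splits}


def _component_leaves(adj, start, blocked, n):
    stack, seen = [start], {start, blocked}
    leaves = set()
    while stack:
        u = stack.pop()
        if u < n:
            leaves.add(u)
        for v, _ in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return leaves


def _canon(side, all_labels):
    other = frozenset(all_labels - set(side))
    return min(frozenset(side), other, key=lambda s: (len(s), sorted(s)))


def _splits(tree):
    """Non-trivial bipartitions of a PhyloTree, canonicalized."""
    labels = tree.leaf_labels
    leaf_nodes = set(tree.leaf_node.values())
    splits = set()
    for u in tree.adjacency:
        for v, _ in tree.adjacency[u]:
            if u < v and u not in leaf_nodes and v not in leaf_nodes:
                side = set()
                stack, seen = [v], {v, u}
                while stack:
                    x = stack.pop()
                    lab = tree.node_label.get(x)
                    if x in leaf_nodes:
                        side.add(lab)
                    for y, _ in tree.adjacency[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                if 1 < len(side) < len(labels) - 1:
                    splits.add(_canon(side, labels))
    return splits
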