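import random

import networkx as nx
import pytest

from mybscan.phylogeny_engine import PhyloTree
from mybscan.tree_classifier import (STATUS_MYB, STATUS_MYB_LIKE, STATUS_OUTLIER,
                                     classify_candidate, classify_candidates,
                                     exclude_outliers, exclude_outliers_from_distances,
                                     nearest_baits, patristic_distance)


def random_newick(n_leaves, rng):
    """Random binary tree with random branch lengths, as a Newick string."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a}:{rng.uniform(0.1, 2.0):.3f},{b}:{rng.uniform(0.1, 2.0):.3f})")
    return nodes[0] + ";"


def brute_force_edge_count(newick, a, b):
    """Independent oracle: dendropy parse + shortest path on a networkx graph."""
    import dendropy
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    g = nx.Graph()
    name = {}
    for i, node in enumerate(dt.preorder_node_iter()):
        name[id(node)] = node.taxon.label if node.taxon else f"__int{i}"
    for node in dt.preorder_node_iter():
        for child in node.child_nodes():
            g.add_edge(name[id(node)], name[id(child)])
    return nx.shortest_path_length(g, a, b)


class TestPatristicDistance:
    def test_identity_is_zero(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        assert patristic_distance(tree, "A", "A") == 0

    def test_hand_enumerated_paths(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        assert patristic_distance(tree, "A", "B") == 2
        assert patristic_distance(tree, "A", "C") == 3
        assert patristic_distance(tree, "B", "C") == 3

    def test_symmetry_on_cherry(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        assert patristic_distance(tree, "A", "C") == patristic_distance(tree, "B", "C")
        assert patristic_distance(tree, "A", "B") == patristic_distance(tree, "B", "A")

    def test_branch_length_mode(self):
        tree = PhyloTree.from_newick("((A:1,B:2):0.5,C:3);")
        assert patristic_distance(tree, "A", "C", "branch_length_sum") == pytest.approx(4.5)

    def test_unknown_leaf_is_an_error(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        with pytest.raises(KeyError):
            patristic_distance(tree, "A", "Z")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_trees(self, seed):
        rng = random.Random(seed)
        newick = random_newick(rng.randint(4, 32), rng)
        tree = PhyloTree.from_newick(newick)
        leaves = sorted(tree.leaf_labels)
        pairs = [(rng.choice(leaves), rng.choice(leaves)) for _ in range(15)]
        for a, b in pairs:
            assert patristic_distance(tree, a, b) == brute_force_edge_count(newick, a, b)

    @pytest.mark.parametrize("seed", range(3))
    def test_is_a_metric(self, seed):
        rng = random.Random(100 + seed)
        tree = PhyloTree.from_newick(random_newick(10, rng))
        leaves = sorted(tree.leaf_labels)
        d = {(a, b): patristic_distance(tree, a, b) for a in leaves for b in leaves}
        for a in leaves:
            for b in leaves:
                assert d[a, b] == d[b, a]
                for c in leaves:
                    assert d[a, c] <= d[a, b] + d[b, c]


class TestNearestBaits:
    def test_sister_bait(self):
        tree = PhyloTree.from_newick("((cand,b1),(b2,b3));")
        near, dist = nearest_baits(tree, "cand", ["b1", "b2", "b3"])
        assert near == {"b1"} and dist == 2

    def test_all_baits_at_minimum_returned(self):
        tree = PhyloTree.from_newick("(cand,b1,b2);")  # polytomy: both at 2 edges
        near, dist = nearest_baits(tree, "cand", ["b1", "b2"])
        assert near == {"b1", "b2"} and dist == 2

    def test_star_tree_returns_every_bait(self):
        tree = PhyloTree.from_newick("(cand,b1,b2,b3,b4);")
        near, _ = nearest_baits(tree, "cand", ["b1", "b2", "b3", "b4"])
        assert near == {"b1", "b2", "b3", "b4"}

    def test_empty_bait_set_is_an_error(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        with pytest.raises(ValueError):
            nearest_baits(tree, "A", [])


class TestExcludeOutliers:
    def test_single_pass_mean_rule(self):
        survivors, excluded, mean = exclude_outliers_from_distances(
            {"c1": 1, "c2": 1, "c3": 1, "c4": 10})
        assert mean == pytest.approx(3.25)
        assert excluded == {"c4"}          # 10 > 9.75
        assert survivors == {"c1", "c2", "c3"}

    def test_uniform_distances_keep_everything(self):
        survivors, excluded, _ = exclude_outliers_from_distances(
            {f"c{i}": 2 for i in range(4)})
        assert not excluded and len(survivors) == 4

    def test_single_candidate_always_kept(self):
        survivors, excluded, _ = exclude_outliers_from_distances({"only": 42.0})
        assert survivors == {"only"} and not excluded

    def test_boundary_is_strict(self):
        # d == 3 * mean exactly is kept ("exceeds" is strict)
        survivors, excluded, _ = exclude_outliers_from_distances(
            {"a": 1.0, "b": 1.0, "c": 4.0}, factor=2.0)
        assert excluded == set()  # mean 2, threshold 4, 4 is not > 4

    def test_monotone_in_factor(self):
        dists = {f"c{i}": float(i + 1) for i in range(10)}
        prev = set()
        for factor in (0.5, 1.0, 2.0, 3.0, 100.0):
            survivors, _, _ = exclude_outliers_from_distances(dists, factor=factor)
            assert prev <= survivors
            prev = survivors
        assert prev == set(dists)  # factor -> infinity excludes nothing

    def test_tree_interface_logs_excluded(self):
        # c_far sits 5 edges from the nearest bait; the others 2
        tree = PhyloTree.from_newick("((((c_far,x1),x2),(c1,b1)),((c2,b2),(c3,b3)));")
        survivors, report = exclude_outliers(
            tree, ["c1", "c2", "c3", "c_far"], ["b1", "b2", "b3"], factor=1.5)
        assert "c_far" not in survivors
        assert report and report[0][0] == "c_far"


class TestMajorityVote:
    LABELS = {"i1": "ingroup", "i2": "ingroup", "o1": "outgroup", "o2": "outgroup"}

    @pytest.mark.parametrize("near,expected", [
        ({"i1", "i2", "o1"}, STATUS_MYB),
        ({"o1"}, STATUS_MYB_LIKE),
        ({"i1", "o1"}, STATUS_MYB_LIKE),      # tie is conservative
        ({"i1"}, STATUS_MYB),
        ({"o1", "o2", "i1"}, STATUS_MYB_LIKE),
    ])
    def test_vote(self, near, expected):
        assert classify_candidate(near, self.LABELS) == expected

    def test_tie_flag_flips_ties_only(self):
        assert classify_candidate({"i1", "o1"}, self.LABELS, tie_is_myb=True) == STATUS_MYB
        assert classify_candidate({"o1", "o2"}, self.LABELS, tie_is_myb=True) == STATUS_MYB_LIKE

    def test_unlabeled_bait_is_an_error(self):
        with pytest.raises(KeyError, match="mystery"):
            classify_candidate({"i1", "mystery"}, self.LABELS)

    def test_empty_vote_is_an_error(self):
        with pytest.raises(ValueError):
            classify_candidate(set(), self.LABELS)


class TestClassifyCandidates:
    def test_statuses_and_outlier_interplay(self):
        tree = PhyloTree.from_newick(
            "((((far,x1),x2),(c1,in1)),((c2,out1),(in2,out2)));")
        labels = {"in1": "ingroup", "in2": "ingroup",
                  "out1": "outgroup", "out2": "outgroup"}
        outcomes = {o.candidate_id: o for o in classify_candidates(
            tree, ["c1", "c2", "far"], labels, factor=1.2)}
        assert outcomes["c1"].status == STATUS_MYB
        assert outcomes["c2"].status == STATUS_MYB_LIKE
        assert outcomes["far"].status == STATUS_OUTLIER
        assert outcomes["c1"].nearest_bait_ids == frozenset({"in1"})
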