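"""Fragmenting, tree estimation, consensus, and the newick/bipartition layer."""

import numpy as np
import pytest

from psgscan.phylo import Tree, robinson_foulds
from psgscan.simulate import SimulationConfig, simulate_codon_alignment
from psgscan.trees import (
    estimate_tree,
    fragment_alignment,
    majority_consensus,
    neighbor_joining,
    tn93_distance,
)


class TestNewick:
    def test_roundtrip_with_foreground_tags(self):
        nwk = "((A:0.1,B:0.2) #1:0.05,C:0.3,D:0.4);"
        tree = Tree.parse(nwk)
        fg = tree.foreground_edges()
        assert len(fg) == 1
        assert sorted(n.name for n in fg[0].children if n.is_leaf) == ["A", "B"]
        again = Tree.parse(tree.to_newick())
        assert len(again.foreground_edges()) == 1

    def test_set_foreground_by_mrca(self):
        tree = Tree.parse("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        node = tree.set_foreground(["C", "D"])
        assert sorted(l.name for l in Tree(node).leaves()) == ["C", "D"]
        # re-marking replaces the old labels
        tree.set_foreground(["A", "B"])
        assert len(tree.foreground_edges()) == 1

    def test_prune_preserves_foreground_and_lengths(self):
        tree = Tree.parse("((A:1,B:2) #1:3,(C:4,D:5):6,E:7);")
        pruned = tree.prune_to(["A", "C", "E"])
        assert sorted(pruned.leaf_names()) == ["A", "C", "E"]
        # the A leaf absorbs the suppressed foreground stem edge
        leaf_a = pruned.find_leaf("A")
        assert leaf_a.length == pytest.approx(4.0)  # 1 + 3
        assert leaf_a.foreground

    def test_bipartitions_anchor_normalized(self):
        t1 = Tree.parse("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = Tree.parse("((C:1,D:1):1,(A:1,B:1):1,E:1);")
        assert set(t1.bipartitions()) == set(t2.bipartitions())

    def test_robinson_foulds(self):
        t1 = Tree.parse("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = Tree.parse("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        assert robinson_foulds(t1, t1.copy()) == 0
        assert robinson_foulds(t1, t2) > 0


class TestFragmentation:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (45_000, [(0, 15_000), (15_000, 30_000), (30_000, 45_000)]),
            (10_000, [(0, 10_000)]),
            (46_500, [(0, 15_000), (15_000, 30_000), (30_000, 45_000), (45_000, 46_500)]),
            (45_400, [(0, 15_000), (15_000, 30_000), (30_000, 45_400)]),
        ],
    )
    def test_tiling_and_remainder_policy(self, length, expected):
        fs = fragment_alignment(length)
        assert fs.intervals == expected
        # intervals tile the alignment
        assert fs.intervals[0][0] == 0 and fs.intervals[-1][1] == length
        for (a1, b1), (a2, b2) in zip(fs.intervals, fs.intervals[1:]):
            assert b1 == a2

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            fragment_alignment(0)


class TestEstimateTree:
    def test_nj_consistent_on_additive_distances(self):
        truth = Tree.parse("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07,E:0.3);")
        names = truth.leaf_names()
        # exact additive distances via brute-force path sums
        import itertools

        D = np.zeros((len(names), len(names)))
        for i, j in itertools.combinations(range(len(names)), 2):
            D[i, j] = D[j, i] = _path_length(truth, names[i], names[j])
        nj = neighbor_joining(names, D)
        assert robinson_foulds(nj, truth) == 0

    def test_three_taxa(self):
        seqs = {"A": "ATGAAA" * 30, "B": "ATGAAG" * 30, "C": "ATGCAA" * 30}
        tree = estimate_tree(seqs)
        assert sorted(tree.leaf_names()) == ["A", "B", "C"]
        assert all(e.length >= 0 for e in tree.edges())

    def test_identical_sequences_star_with_zero_lengths(self):
        seqs = {n: "ATGAAACCC" * 20 for n in "ABCD"}
        with pytest.warns(UserWarning):
            tree = estimate_tree(seqs)
        assert all(e.length == 0 for e in tree.edges())

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            estimate_tree({"A": "ATG", "B": "ATG"})

    def test_input_order_invariance(self):
        truth = Tree.parse("(((A:0.06,B:0.06):0.04,C:0.08):0.03,(D:0.08,E:0.06):0.04,F:0.1);")
        cfg = SimulationConfig(truth.copy(), n_sites=1500, omega0=0.3, omega2=1.0, seed=13)
        aln, _ = simulate_codon_alignment(cfg)
        seqs = {t: aln.sequence(t) for t in aln.taxa}
        t1 = estimate_tree(seqs)
        t2 = estimate_tree(dict(reversed(list(seqs.items()))))
        assert robinson_foulds(t1, t2) == 0
        b1, b2 = t1.bipartitions(), t2.bipartitions()
        for split in b1:
            assert b1[split] == pytest.approx(b2[split], abs=1e-6)

    def test_recovers_simulated_topology(self):
        truth = Tree.parse("(((A:0.06,B:0.06):0.04,C:0.08):0.03,(D:0.08,E:0.06):0.04,F:0.1);")
        cfg = SimulationConfig(truth.copy(), n_sites=2500, omega0=0.3, omega2=1.0, seed=14)
        aln, _ = simulate_codon_alignment(cfg)
        est = estimate_tree(aln)
        assert robinson_foulds(est, truth) == 0

    def test_tn93_zero_for_identical(self):
        row = np.array([0, 1, 2, 3] * 25, dtype=np.int8)
        assert tn93_distance(row, row) == 0.0


def _path_length(tree, a, b):
    def ancestors(leaf):
        out = []
        node = tree.find_leaf(leaf)
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    pa, pb = ancestors(a), ancestors(b)
    ids = {id(n) for n in pa}
    lca = next(n for n in pb if id(n) in ids)
    total = 0.0
    for n in pa:
        if n is lca:
            break
        total += n.length
    for n in pb:
        if n is lca:
            break
        total += n.length
    return total


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = Tree.parse("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        cons = majority_consensus([t.copy(), t.copy(), t.copy()])
        assert all(v == 1.0 for v in cons.supports.values())
        assert robinson_foulds(cons.tree, t) == 0

    def test_two_of_three_retained_one_dropped(self):
        t_major = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        trees = [Tree.parse(t_major), Tree.parse(t_major),
                 Tree.parse("((A:1,C:1):1,(B:1,D:1):1,E:1);")]
        cons = majority_consensus(trees)
        assert set(cons.supports.values()) == {2 / 3}
        # the minority split {A, C} must not appear
        assert frozenset({"B", "D", "E"}) not in cons.supports
        assert robinson_foulds(cons.tree, trees[0]) == 0

    def test_single_tree_is_itself(self):
        t = Tree.parse("((A:1,B:2):3,(C:4,D:5):6,E:7);")
        cons = majority_consensus([t])
        assert robinson_foulds(cons.tree, t) == 0
        assert all(v == 1.0 for v in cons.supports.values())

    def test_consensus_lengths_are_means(self):
        t1 = Tree.parse("((A:1,B:1):1,(C:1,D:1):2,E:1);")
        t2 = Tree.parse("((A:3,B:1):1,(C:1,D:1):4,E:1);")
        cons = majority_consensus([t1, t2])
        split_cd = frozenset({"C", "D"})
        node = _find_cluster(cons.tree, {"C", "D"})
        assert node.length == pytest.approx(3.0)  # mean of 2 and 4
        leaf_a = cons.tree.find_leaf("A")
        assert leaf_a.length == pytest.approx(2.0)  # mean of 1 and 3

    def test_leaf_set_mismatch_names_offender(self):
        t1 = Tree.parse("((A:1,B:1):1,C:1,D:1);")
        t2 = Tree.parse("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError, match="tree 1"):
            majority_consensus([t1, t2])


def _find_cluster(tree, leaves):
    for node in tree.postorder():
        if not node.is_leaf:
            below = {l.name for l in Tree(node).leaves()}
            if below == leaves:
                return node
    raise AssertionError(f"cluster {leaves} not found")
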