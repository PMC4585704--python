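"""p-distance, neighbor-joining, bootstrap; scikit-bio as an independent oracle."""

import numpy as np
import pytest

from alphoid import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    p_distance,
    pairwise_p_distance,
)
from alphoid.phylo import PhyloTree, TreeNode
from alphoid.synthetic import _mutate


class TestPDistance:
    def test_identical_sequences(self):
        assert p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_quarter(self):
        assert p_distance("AAAA", "AAAT") == 0.25

    def test_pairwise_deletion(self):
        # gap and N columns drop out: 0 differences over 2 comparable sites
        assert p_distance("AA-N", "AAAA") == 0.0

    def test_ambiguity_codes_excluded(self):
        assert p_distance("ARGT", "AAGT") == 0.0

    def test_no_overlap_raises(self):
        with pytest.raises(ValueError, match="no overlap"):
            p_distance("--NN", "AAAA")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("AAA", "AAAA")


def _random_additive_tree(rng, n_leaves):
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        a = nodes.pop(rng.integers(len(nodes)))
        b = nodes.pop(rng.integers(len(nodes)))
        parent = TreeNode()
        parent.children = [(a, float(rng.uniform(0.5, 2.0))),
                           (b, float(rng.uniform(0.5, 2.0)))]
        nodes.append(parent)
    root = TreeNode()
    root.children = [(n, float(rng.uniform(0.5, 2.0))) for n in nodes]
    return PhyloTree(root)


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {child.name: l for child, l in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    @pytest.mark.parametrize("seed", range(20))
    def test_additive_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        true = _random_additive_tree(rng, int(rng.integers(4, 9)))
        dm = true.leaf_distances()
        rec = nj_tree(dm)
        assert rec.bipartitions() == true.bipartitions()
        out = rec.leaf_distances()
        idx = [out.labels.index(l) for l in dm.labels]
        assert np.abs(out.values[np.ix_(idx, idx)] - dm.values).max() < 1e-9

    def test_equal_distances_give_valid_binary_tree(self):
        labels = list("ABCDE")
        values = np.ones((5, 5)) - np.eye(5)
        tree = nj_tree(DistanceMatrix(labels, values))
        assert sorted(tree.leaf_names) == labels

        def check(node):
            if node.is_leaf():
                return
            for child, length in node.children:
                assert length >= 0
                check(child)

        check(tree.root)

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        true = _random_additive_tree(rng, 8)
        dm = true.leaf_distances()
        ours = nj_tree(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
        their_bps = set()
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            rest = frozenset(dm.labels) - below
            if 1 < len(below) < len(dm.labels) - 1:
                their_bps.add(min(below, rest, key=sorted))
        assert ours.bipartitions() == their_bps


class TestBootstrap:
    def _clades(self, cset, n=5, noise=0.02):
        rng = np.random.default_rng(0)
        a = [_mutate(cset["GGO_consensus_Atype"].sequence.replace("F", "A")
                     .replace("I", "C").replace("J", "G"), noise, rng) for _ in range(n)]
        b = [_mutate(cset["gD1.0"].sequence, noise, rng) for _ in range(n)]
        rows = a + b
        width = min(len(r) for r in rows)
        return ([f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)],
                [r[:width] for r in rows])

    def test_clean_split_has_full_support(self, cset):
        labels, rows = self._clades(cset, noise=0.0)
        tree = bootstrap_support(labels, rows, reps=50, seed=1)
        split = frozenset(l for l in labels if l.startswith("A"))
        supports = {}

        def walk(node):
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node.support is not None:
                supports[min(below, frozenset(labels) - below, key=sorted)] = node.support
            return below

        walk(tree.root)
        assert supports[min(split, frozenset(labels) - split, key=sorted)] == 100.0

    def test_same_seed_reproducible(self, cset):
        labels, rows = self._clades(cset)
        t1 = bootstrap_support(labels, rows, reps=30, seed=5)
        t2 = bootstrap_support(labels, rows, reps=30, seed=5)
        assert t1.newick() == t2.newick()

    def test_support_stable_across_replicate_counts(self, cset):
        labels, rows = self._clades(cset)
        split = min(
            frozenset(l for l in labels if l.startswith("A")),
            frozenset(l for l in labels if l.startswith("B")),
            key=sorted,
        )

        def split_support(tree):
            out = {}

            def walk(node):
                if node.is_leaf():
                    return frozenset([node.name])
                below = frozenset().union(*(walk(c) for c, _ in node.children))
                if node.support is not None:
                    out[min(below, frozenset(labels) - below, key=sorted)] = node.support
                return below

            walk(tree.root)
            return out.get(split, 0.0)

        s50 = split_support(bootstrap_support(labels, rows, reps=50, seed=2))
        s500 = split_support(bootstrap_support(labels, rows, reps=500, seed=2))
        assert abs(s50 - s500) <= 10.0


class TestABSeparation:
    def test_ab_bipartition_dominates_tree(self, cset):
        # 40 simulated monomers, half per type: the longest internal edge of
        # the NJ tree separates A-derived from B-derived leaves
        rng = np.random.default_rng(3)
        labels, seqs = [], []
        for i in range(20):
            labels.append(f"A{i}")
            seqs.append(_mutate(cset["gJ1"].sequence, 0.02, rng))
            labels.append(f"B{i}")
            seqs.append(_mutate(cset["gJ2"].sequence, 0.02, rng))
        dm = DistanceMatrix.from_sequences(labels, seqs)
        tree = nj_tree(dm)
        edges = []

        def walk(node):
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            return below

        def collect(node):
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, length in node.children:
                sub = collect(child)
                below |= sub
                if 1 < len(sub) < len(labels) - 1:
                    edges.append((length, sub))
            return below

        collect(tree.root)
        _, best = max(edges, key=lambda e: e[0])
        side = {l[0] for l in best}
        other = {l[0] for l in set(labels) - best}
        assert side == {"A"} and other == {"B"} or side == {"B"} and other == {"A"}

    def test_sf1_and_sf2_monomers_do_not_mix(self, cset):
        # at 1% noise no SF1-derived leaf has an SF2-derived nearest neighbor
        rng = np.random.default_rng(4)
        labels, seqs = [], []
        for i in range(6):
            for name in ("gJ1", "gJ2"):
                labels.append(f"SF1_{name}_{i}")
                seqs.append(_mutate(cset[name].sequence, 0.01, rng))
            for name in ("gD1.0", "gD2.1"):
                labels.append(f"SF2_{name}_{i}")
                seqs.append(_mutate(cset[name].sequence, 0.01, rng))
        dm = DistanceMatrix.from_sequences(labels, seqs)
        for i, label in enumerate(labels):
            if not label.startswith("SF1"):
                continue
            row = dm.values[i].copy()
            row[i] = np.inf
            nearest = labels[int(np.argmin(row))]
            assert nearest.startswith("SF1")
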