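"""Distances, neighbor joining (vs independent oracles), bootstrap,
patristic distances and MPPD family assignment."""

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM, TreeNode
from skbio.tree import nj as skbio_nj

from bsnptyper.panel import Allele, Haplotype
from bsnptyper.clustering import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    fractional_dissimilarity,
    jackknife_stability,
    mppd_clusters,
    neighbor_joining,
    patristic_matrix,
)
from bsnptyper.simulate import SimConfig, generate_founder_haplotypes

from _oracles import random_additive_tree, tree_splits
from conftest import hap


def binhap(bits) -> Haplotype:
    return Haplotype(alleles=tuple(Allele(int(b)) for b in bits))


class TestFractionalDissimilarity:
    def test_identical_is_zero(self):
        assert fractional_dissimilarity(hap("XYXB"), hap("XYXB")) == 0.0

    def test_31_of_90_differences(self):
        """Two haplotypes differing at 31 of 90 core SNPs (the B2-vs-B15
        pattern) have dissimilarity 31/90 = 0.3444."""
        a = binhap([0] * 90)
        b = binhap([1] * 31 + [0] * 59)
        assert fractional_dissimilarity(a, b) == pytest.approx(0.3444, abs=5e-5)

    def test_pairwise_deletion_of_missing(self):
        # 90 sites, one MISSING at a differing site: 30 diffs / 89 shared
        a = binhap([0] * 90)
        bits = [1] * 31 + [0] * 59
        b = Haplotype(alleles=tuple(
            Allele.MISSING if i == 0 else Allele(bits[i]) for i in range(90)
        ))
        assert fractional_dissimilarity(a, b) == pytest.approx(30 / 89)

    def test_both_is_its_own_state(self):
        assert fractional_dissimilarity(hap("B"), hap("X")) == 1.0
        assert fractional_dissimilarity(hap("B"), hap("B")) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            fractional_dissimilarity(hap("XY"), hap("XYX"))

    def test_no_comparable_positions_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            fractional_dissimilarity(hap("FF"), hap("XY"))

    def test_bounded_semimetric_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            a = Haplotype(alleles=tuple(
                Allele(int(x)) for x in rng.integers(0, 3, n)
            ))
            b = Haplotype(alleles=tuple(
                Allele(int(x)) for x in rng.integers(0, 3, n)
            ))
            d_ab = fractional_dissimilarity(a, b)
            assert 0.0 <= d_ab <= 1.0
            assert d_ab == fractional_dissimilarity(b, a)
            assert (d_ab == 0.0) == (a.alleles == b.alleles)

    def test_matrix_refuses_sparse_pairs(self):
        a = Haplotype(alleles=(Allele.X,) * 2 + (Allele.MISSING,) * 8)
        b = Haplotype(alleles=(Allele.MISSING,) * 8 + (Allele.X,) * 2)
        with pytest.raises(ValueError, match="comparable"):
            distance_matrix([a, b], ["a", "b"])

    def test_matrix_agrees_with_pairwise_function(self, rng):
        haps = [
            Haplotype(alleles=tuple(Allele(int(x))
                                    for x in rng.integers(0, 3, 20)))
            for _ in range(6)
        ]
        D = distance_matrix(haps)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert D.d[i, j] == pytest.approx(
                        fractional_dissimilarity(haps[i], haps[j])
                    )


class TestNeighborJoining:
    def test_two_taxa_split_the_distance(self):
        D = DistanceMatrix(labels=("a", "b"),
                           d=np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}

    def test_three_taxa_closed_form(self):
        # three-point formulas: la = (dab + dac - dbc) / 2, etc.
        dab, dac, dbc = 0.6, 0.8, 0.4
        D = DistanceMatrix(
            labels=("a", "b", "c"),
            d=np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0.0]]),
        )
        tree = neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((dab + dac - dbc) / 2)
        assert lengths["b"] == pytest.approx((dab + dbc - dac) / 2)
        assert lengths["c"] == pytest.approx((dac + dbc - dab) / 2)

    def test_four_taxa_known_topology(self):
        # tree ((a,b),(c,d)) with internal branch 0.3
        labels = ("a", "b", "c", "d")
        d = np.array([
            [0.0, 0.2, 0.8, 0.9],
            [0.2, 0.0, 0.8, 0.9],
            [0.8, 0.8, 0.0, 0.3],
            [0.9, 0.9, 0.3, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        assert tree_splits(tree) == {frozenset({"a", "b"})}

    def test_fewer_than_two_labels_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=("a",), d=np.zeros((1, 1))))

    def test_recovers_random_additive_topologies(self, rng):
        """NJ is consistent on additive distances: the generating
        topology is recovered exactly (RF distance 0), 25 random trees."""
        for _ in range(25):
            n = int(rng.integers(4, 11))
            labels, D, true_splits = random_additive_tree(rng, n)
            tree = neighbor_joining(
                DistanceMatrix(labels=tuple(labels), d=D)
            )
            assert tree_splits(tree) == true_splits

    def test_agrees_with_skbio_nj_topology(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            labels, D, _ = random_additive_tree(rng, n)
            D = D + rng.uniform(0, 0.01, D.shape)
            D = np.triu(D, 1)
            D = D + D.T
            mine = neighbor_joining(DistanceMatrix(labels=tuple(labels), d=D))
            ref = skbio_nj(SkbioDM(D, ids=labels))
            assert tree_splits(mine) == tree_splits(ref)

    def test_deterministic_under_ties(self):
        # four equidistant taxa: every pair ties on Q; smallest label
        # pair must be joined, giving a reproducible topology
        d = np.ones((4, 4)) - np.eye(4)
        trees = [
            neighbor_joining(DistanceMatrix(labels=("d", "c", "b", "a"), d=d))
            for _ in range(3)
        ]
        splits = [tree_splits(t) for t in trees]
        assert splits[0] == splits[1] == splits[2] == {frozenset({"a", "b"})}

    def test_negative_lengths_clamped(self):
        d = np.array([
            [0.0, 0.1, 1.0, 1.0],
            [0.1, 0.0, 0.11, 1.0],
            [1.0, 0.11, 0.0, 0.1],
            [1.0, 1.0, 0.1, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(labels=("a", "b", "c", "d"), d=d))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0.0


class TestPatristic:
    def test_two_leaf_distance_adds_branches(self):
        tree = TreeNode.read(["(a:0.1,b:0.2);"])
        nodes, dist = patristic_matrix(tree)
        names = {n.name: i for i, n in enumerate(nodes) if n.name}
        assert dist[names["a"], names["b"]] == pytest.approx(0.3)

    def test_zero_length_tree_all_zero(self):
        tree = TreeNode.read(["((a:0,b:0):0,c:0);"])
        _, dist = patristic_matrix(tree)
        assert np.all(dist == 0)

    def test_matches_graph_shortest_path_oracle(self, rng):
        import networkx as nx

        labels, D, _ = random_additive_tree(rng, 8)
        tree = neighbor_joining(DistanceMatrix(labels=tuple(labels), d=D))
        nodes, dist = patristic_matrix(tree)
        g = nx.Graph()
        for node in tree.traverse(include_self=False):
            g.add_edge(id(node.parent), id(node), weight=node.length)
        sp = dict(nx.all_pairs_dijkstra_path_length(g))
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if i < j:
                    assert dist[i, j] == pytest.approx(sp[id(u)][id(v)])

    def test_missing_lengths_rejected(self):
        tree = TreeNode.read(["(a,b);"])
        with pytest.raises(ValueError, match="branch lengths"):
            patristic_matrix(tree)


class TestBootstrap:
    @pytest.fixture
    def four_taxa_split(self):
        # 40 of 80 columns split {A,B} vs {C,D}; the rest are constant
        cols = []
        for i in range(40):
            cols.append([0, 0, 1, 1])
        for i in range(40):
            cols.append([0, 0, 0, 0])
        X = np.array(cols).T
        return [binhap(row) for row in X], ["A", "B", "C", "D"]

    def test_fully_supported_split_gets_100(self, four_taxa_split):
        haps, labels = four_taxa_split
        tree, consensus = bootstrap_support(haps, labels, n_reps=200, seed=3)
        supports = [n.support for n in tree.non_tips() if hasattr(n, "support")]
        assert supports == [pytest.approx(100.0)]
        assert frozenset({"A", "B"}) in tree_splits(consensus) or frozenset(
            {"C", "D"}
        ) in tree_splits(consensus)

    def test_single_replicate_supports_are_0_or_100(self, rng):
        haps = [binhap(rng.integers(0, 2, 30)) for _ in range(6)]
        tree, _ = bootstrap_support(haps, n_reps=1, seed=1)
        for n in tree.non_tips():
            if hasattr(n, "support"):
                assert n.support in (0.0, 100.0)

    def test_seed_reproducibility(self, rng):
        haps = [binhap(rng.integers(0, 2, 40)) for _ in range(8)]
        t1, _ = bootstrap_support(haps, n_reps=50, seed=7)
        t2, _ = bootstrap_support(haps, n_reps=50, seed=7)
        s1 = [n.support for n in t1.non_tips() if hasattr(n, "support")]
        s2 = [n.support for n in t2.non_tips() if hasattr(n, "support")]
        assert s1 == s2


class TestMppdClusters:
    def _family_tree(self):
        # two tight clades separated by long branches, among scattered
        # distant singletons (the tight pairs are a small minority of all
        # node-pair distances, as in a realistically diverse topology)
        return TreeNode.read([
            "((((a:0.01,b:0.012):0.008,c:0.011):0.3,"
            "((d:0.009,e:0.01):0.007,f:0.012):0.28):0.1,"
            "(g:0.9,(h:1.4,(i:1.8,j:2.2):0.5):0.4):0.2);"
        ])

    def test_two_tight_clades_two_families(self):
        tree = self._family_tree()
        out = mppd_clusters(tree, percentile=10.0, bootstrap_min=0.0)
        fams = {out.assignment[x] for x in "abc"}
        assert len(fams) == 1
        assert len({out.assignment[x] for x in "def"}) == 1
        assert {out.assignment[x] for x in "def"} != fams
        # the scattered haplotypes stay singleton families
        assert len({out.assignment[x] for x in "ghij"}) == 4

    def test_star_tree_gives_singletons(self):
        tree = TreeNode.read(["(a:1,b:1,c:1,d:1,e:1);"])
        out = mppd_clusters(tree, percentile=5.0, bootstrap_min=0.0)
        assert len(set(out.assignment.values())) == 5

    def test_percentile_100_single_family(self):
        tree = self._family_tree()
        out = mppd_clusters(tree, percentile=100.0, bootstrap_min=0.0)
        assert len(set(out.assignment.values())) == 1

    def test_low_bootstrap_flags_but_keeps_membership(self):
        tree = self._family_tree()
        for node in tree.non_tips():
            node.support = 60.0
        out = mppd_clusters(tree, percentile=10.0, bootstrap_min=70.0)
        multi = [k for k, v in out.members.items() if len(v) > 1]
        assert multi
        for fam in multi:
            assert out.meets_mppd[fam]
            assert not out.meets_bootstrap[fam]

    def test_requires_supports_when_bootstrap_min_positive(self):
        with pytest.raises(ValueError, match="support"):
            mppd_clusters(self._family_tree(), 10.0, bootstrap_min=70.0)

    def test_letters_assigned_without_gaps(self):
        tree = self._family_tree()
        out = mppd_clusters(tree, percentile=10.0, bootstrap_min=0.0)
        letters = sorted(set(out.assignment.values()))
        assert letters == [chr(ord("A") + i) for i in range(len(letters))]

    def test_simulated_families_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimConfig(seed=31, n_families=6, haps_per_family=4,
                        within_family_diff=3, between_family_diff=30)
        founders, truth = generate_founder_haplotypes(cfg)
        labels = [f"H{i:02d}" for i in range(len(founders))]
        tree, _ = bootstrap_support(founders, labels, n_reps=100, seed=2)
        out = mppd_clusters(tree, percentile=10.0, bootstrap_min=70.0)
        pred = [out.assignment[l] for l in labels]
        assert adjusted_rand_score(truth.founder_family, pred) == 1.0
        for fam in set(pred):
            assert out.meets_bootstrap[fam]


class TestJackknife:
    def test_separated_families_fully_persist(self):
        cfg = SimConfig(seed=41, n_families=8, haps_per_family=3,
                        within_family_diff=3, between_family_diff=40)
        founders, _ = generate_founder_haplotypes(cfg)
        pers = jackknife_stability(
            founders, drop_fraction=0.25, n_reps=60, seed=5
        )
        assert pers and all(v == 1.0 for v in pers.values())

    def test_seed_reproducibility(self):
        cfg = SimConfig(seed=41, n_families=2, haps_per_family=3,
                        within_family_diff=3, between_family_diff=40)
        founders, _ = generate_founder_haplotypes(cfg)
        a = jackknife_stability(founders, drop_fraction=0.3, n_reps=30, seed=9)
        b = jackknife_stability(founders, drop_fraction=0.3, n_reps=30, seed=9)
        assert a == b

    def test_bad_drop_fraction_rejected(self):
        with pytest.raises(ValueError):
            jackknife_stability([hap("X")], drop_fraction=1.5)
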