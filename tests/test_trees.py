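"""Dice distances, complete-linkage trees, bootstraps, VGC cuts, silhouettes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import phagetax as pt
from phagetax.proteins import ProteinRecord, protein_clusters
from phagetax.trees import Node, cut_tree, hierarchical_tree, silhouette_width

from conftest import random_distance_frame


def _catalog_from_presence(presence: dict[str, list[str]]):
    """Catalog where each listed feature name becomes one PC per genome."""
    prots = []
    edges = {}
    by_pc = {}
    for g, pcs in presence.items():
        for i, pc in enumerate(pcs):
            pid = f"{g}|p{i}"
            prots.append(ProteinRecord(pid, g, "K" * 60))
            by_pc.setdefault(pc, []).append(pid)
    for members in by_pc.values():
        for a, b in zip(members, members[1:]):
            edges[tuple(sorted((a, b)))] = (0.0, 99.0)
    return protein_clusters(prots, pt.HitGraph([p.protein_id for p in prots], edges))


class TestGenomeDistance:
    def test_identical_pc_sets_distance_zero(self):
        cat = _catalog_from_presence({"a": ["x", "y"], "b": ["x", "y"]})
        assert pt.genome_distance(cat, "a", "b") == 0.0

    def test_disjoint_pc_sets_distance_one(self):
        cat = _catalog_from_presence({"a": ["x", "y"], "b": ["u", "v"]})
        assert pt.genome_distance(cat, "a", "b") == 1.0

    def test_dice_arithmetic(self):
        # |A|=10, |B|=6, shared 4 -> 1 - 8/16 = 0.5
        a = [f"s{i}" for i in range(4)] + [f"a{i}" for i in range(6)]
        b = [f"s{i}" for i in range(4)] + [f"b{i}" for i in range(2)]
        cat = _catalog_from_presence({"a": a, "b": b})
        assert pt.genome_distance(cat, "a", "b") == pytest.approx(0.5)

    def test_semimetric_properties(self):
        rng = np.random.default_rng(0)
        pcs = [f"x{i}" for i in range(12)]
        presence = {
            f"g{k}": [p for p in pcs if rng.random() < 0.6] or [pcs[0]]
            for k in range(5)
        }
        cat = _catalog_from_presence(presence)
        for a in presence:
            assert pt.genome_distance(cat, a, a) == 0.0
            for b in presence:
                dab = pt.genome_distance(cat, a, b)
                assert 0.0 <= dab <= 1.0
                assert dab == pytest.approx(pt.genome_distance(cat, b, a))

    def test_unknown_genome_rejected(self):
        cat = _catalog_from_presence({"a": ["x"], "b": ["x"]})
        with pytest.raises(ValueError):
            pt.genome_distance(cat, "a", "zz")


def _frame(ids, entries):
    n = len(ids)
    D = np.zeros((n, n))
    for (a, b), d in entries.items():
        i, j = ids.index(a), ids.index(b)
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)


class TestHierarchicalTree:
    def test_two_leaves_merge_at_their_distance(self):
        tree = pt.hierarchical_tree(_frame(["A", "B"], {("A", "B"): 0.4}))
        assert tree.root.height == pytest.approx(0.4)

    def test_three_leaves_merge_order(self):
        D = _frame(["A", "B", "C"], {("A", "B"): 0.2, ("A", "C"): 0.8, ("B", "C"): 0.8})
        tree = pt.hierarchical_tree(D)
        heights = sorted(n.height for n in tree.internal_nodes())
        assert heights == pytest.approx([0.2, 0.8])
        assert {frozenset(["A", "B"])} == {
            n.leaves for n in tree.internal_nodes() if n.height < 0.5
        }

    def test_identical_genomes_collapse_at_zero(self):
        D = _frame(["A", "B", "C"], {})
        tree = pt.hierarchical_tree(D)
        assert all(n.height == 0.0 for n in tree.internal_nodes())

    def test_matches_scipy_on_five_leaves(self):
        """Independent oracle: scipy complete linkage on distinct distances."""
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        for seed in range(5):
            D = random_distance_frame(5, seed)
            Z = hierarchy.linkage(squareform(D.values, checks=False), method="complete")
            tree = pt.hierarchical_tree(D)
            ours = sorted(round(n.height, 10) for n in tree.internal_nodes())
            assert ours == pytest.approx(sorted(Z[:, 2]))
            # cluster composition agrees too (distinct distances: unique tree)
            ids = list(D.index)
            scipy_clusters = set()
            members = {i: frozenset([ids[i]]) for i in range(5)}
            for k, (i, j, h, _) in enumerate(Z):
                merged = members[int(i)] | members[int(j)]
                members[5 + k] = merged
                scipy_clusters.add(merged)
            assert {n.leaves for n in tree.internal_nodes()} == scipy_clusters

    @given(st.integers(0, 500))
    def test_complete_linkage_heights_monotone(self, seed):
        D = random_distance_frame(7, seed)
        tree = pt.hierarchical_tree(D)

        def check(node):
            if node.children:
                for ch in node.children:
                    assert ch.height <= node.height + 1e-12
                    check(ch)

        check(tree.root)

    def test_invalid_matrices_rejected(self):
        bad = pd.DataFrame([[0.0, 0.3], [0.5, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            pt.hierarchical_tree(bad)
        diag = pd.DataFrame([[0.1, 0.3], [0.3, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            pt.hierarchical_tree(diag)
        with pytest.raises(ValueError):
            pt.hierarchical_tree(_frame(["A", "B"], {("A", "B"): 0.4}), linkage="average")


class TestBootstrap:
    def _catalog(self):
        # two groups with disjoint PC content
        presence = {}
        for g in range(3):
            presence[f"a{g}"] = [f"x{i}" for i in range(10)]
            presence[f"b{g}"] = [f"y{i}" for i in range(10)]
        return _catalog_from_presence(presence)

    def test_single_replicate_supports_are_zero_or_one(self):
        tree = pt.bootstrap_supports(self._catalog(), n_replicates=1, seed=0)
        assert all(n.support in (0.0, 1.0) for n in tree.internal_nodes())

    def test_fixed_seed_reproducible(self):
        t1 = pt.bootstrap_supports(self._catalog(), n_replicates=50, seed=7)
        t2 = pt.bootstrap_supports(self._catalog(), n_replicates=50, seed=7)
        assert [n.support for n in t1.internal_nodes()] == [
            n.support for n in t2.internal_nodes()
        ]

    def test_disjoint_families_have_strong_root_splits(self):
        tree = pt.bootstrap_supports(self._catalog(), n_replicates=200, seed=1)
        groups = {frozenset(f"a{g}" for g in range(3)), frozenset(f"b{g}" for g in range(3))}
        for node in tree.internal_nodes():
            if node.leaves in groups:
                assert node.support >= 0.95

    def test_column_order_invariance(self):
        cat = self._catalog()
        shuffled = pt.PCCatalog(
            cat.pc_of, cat.counts[list(reversed(cat.counts.columns))], cat.records
        )
        t1 = pt.bootstrap_supports(cat, n_replicates=100, seed=3)
        t2 = pt.bootstrap_supports(shuffled, n_replicates=100, seed=3)
        s1 = {n.leaves: n.support for n in t1.internal_nodes()}
        s2 = {n.leaves: n.support for n in t2.internal_nodes()}
        assert set(s1) == set(s2)
        # identical resampling law: supports agree closely
        for k in s1:
            assert abs(s1[k] - s2[k]) <= 0.1

    def test_invalid_replicates(self):
        with pytest.raises(ValueError):
            pt.bootstrap_supports(self._catalog(), n_replicates=0)


class TestCutTree:
    def test_two_clades_split_at_deep_merge(self):
        ids = ["A", "B", "C", "D"]
        D = _frame(ids, {("A", "B"): 0.2, ("C", "D"): 0.3,
                         ("A", "C"): 0.95, ("A", "D"): 0.95,
                         ("B", "C"): 0.95, ("B", "D"): 0.95})
        tree = pt.hierarchical_tree(D)
        vgc = cut_tree(tree, D, 0.9)
        assert vgc.n_clusters() == 2

    def test_shallow_tree_is_one_cluster(self):
        D = random_distance_frame(6, 1) * 0.5  # all distances < 0.9
        np.fill_diagonal(D.values, 0.0)
        tree = pt.hierarchical_tree(D)
        assert cut_tree(tree, D, 0.9).n_clusters() == 1

    def test_invalid_height(self):
        D = _frame(["A", "B"], {("A", "B"): 0.4})
        tree = pt.hierarchical_tree(D)
        with pytest.raises(ValueError):
            cut_tree(tree, D, 0.0)
        with pytest.raises(ValueError):
            cut_tree(tree, D, 1.5)

    @given(st.integers(0, 500))
    def test_lower_cut_refines_higher_cut(self, seed):
        D = random_distance_frame(8, seed)
        tree = pt.hierarchical_tree(D)
        h1, h2 = 0.4, 0.8
        lo = cut_tree(tree, D, h1)
        hi = cut_tree(tree, D, h2)
        for cluster in set(lo.assignment.values()):
            members = [g for g, c in lo.assignment.items() if c == cluster]
            assert len({hi.assignment[g] for g in members}) == 1


class TestSilhouette:
    def test_arithmetic(self):
        # a = 0.1, b = 0.9 -> (0.9-0.1)/0.9 = 0.888...
        D = _frame(["A", "B", "C"], {("A", "B"): 0.1, ("A", "C"): 0.9, ("B", "C"): 0.9})
        part = {"A": "c1", "B": "c1", "C": "c2"}
        assert silhouette_width(D, part, "A") == pytest.approx(0.8 / 0.9)

    def test_equal_cohesion_and_separation_zero(self):
        D = _frame(["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5})
        part = {"A": "c1", "B": "c1", "C": "c2"}
        assert silhouette_width(D, part, "A") == 0.0

    def test_singleton_convention_zero(self):
        D = _frame(["A", "B"], {("A", "B"): 0.4})
        assert silhouette_width(D, {"A": "c1", "B": "c2"}, "A") == 0.0

    def test_unknown_genome_rejected(self):
        D = _frame(["A", "B"], {("A", "B"): 0.4})
        with pytest.raises(ValueError):
            silhouette_width(D, {"A": "c1", "B": "c1"}, "zz")

    def test_matches_sklearn_on_random_partition(self):
        from sklearn.metrics import silhouette_samples

        D = random_distance_frame(10, 5)
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
        part = {g: f"c{l}" for g, l in zip(D.index, labels)}
        expected = silhouette_samples(D.values, labels, metric="precomputed")
        for g, e in zip(D.index, expected):
            assert silhouette_width(D, part, g) == pytest.approx(e, abs=1e-12)
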