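"""Genome-content distances, complete-linkage trees, VGCs and silhouettes.

Genome distances are Sørensen–Dice dissimilarities on protein-cluster
presence/absence,

    d(a, b) = 1 - 2 |PC(a) ∩ PC(b)| / (|PC(a)| + |PC(b)|),

so two genomes sharing no protein cluster are at distance 1 and identical
PC sets are at distance 0.  The hierarchical tree uses complete linkage
(merge heights are therefore monotone and stay in [0, 1]); node supports
are plain bootstrap proportions over PC-column resampling.  Cutting the
tree at a distance threshold (0.9 by default) yields viral genome clusters
(VGCs), the family-level proxy, each genome annotated with its silhouette
width against the resulting partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .proteins import PCCatalog

VGC_CUT_HEIGHT = 0.9
DEFAULT_BOOTSTRAPS = 1000


@dataclass
class Node:
    height: float
    leaves: frozenset[str]
    children: tuple["Node", "Node"] | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def walk(self):
        yield self
        if self.children:
            for ch in self.children:
                yield from ch.walk()


@dataclass
class Dendrogram:
    root: Node
    ids: list[str]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def clusters(self) -> set[frozenset[str]]:
        return {n.leaves for n in self.root.walk()}

    def to_newick(self) -> str:
        def fmt(node: Node, parent_h: float) -> str:
            bl = max(parent_h - node.height, 0.0)
            if node.is_leaf:
                return f"{next(iter(node.leaves))}:{bl:.6f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = "" if node.support is None else f"{node.support:.3f}"
            return f"({inner}){label}:{bl:.6f}"

        if self.root.is_leaf:
            return f"{next(iter(self.root.leaves))};"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:.3f}"
        return f"({inner}){label};"


@dataclass
class VGCPartition:
    assignment: dict[str, str]
    cut_height: float
    silhouette: dict[str, float]

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, c in self.assignment.items():
            out.setdefault(c, []).append(g)
        return {k: sorted(v) for k, v in out.items()}

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def mean_silhouette(self) -> float:
        return float(np.mean(list(self.silhouette.values())))


# ---------------------------------------------------------------------------
# distances


def genome_distance(catalog: PCCatalog, a: str, b: str) -> float:
    """Dice dissimilarity of two genomes' PC presence sets."""
    pa, pb = catalog.pcs_of_genome(a), catalog.pcs_of_genome(b)
    if not pa and not pb:
        return 0.0
    return 1.0 - 2.0 * len(pa & pb) / (len(pa) + len(pb))


def distance_matrix(catalog: PCCatalog) -> pd.DataFrame:
    P = (catalog.counts.values > 0).astype(float)
    sizes = P.sum(axis=1)
    inter = P @ P.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - 2.0 * inter / denom
    D[denom == 0] = 0.0
    np.fill_diagonal(D, 0.0)
    ids = list(catalog.counts.index)
    return pd.DataFrame(D, index=ids, columns=ids)


def _as_matrix(distances) -> tuple[np.ndarray, list[str]]:
    if isinstance(distances, pd.DataFrame):
        return distances.values.astype(float), [str(i) for i in distances.index]
    raise TypeError("distances must be a labelled square DataFrame")


# ---------------------------------------------------------------------------
# complete linkage with deterministic lexicographic tie-break


def _complete_linkage(D: np.ndarray, ids: list[str]) -> Node:
    n = len(ids)
    nodes: dict[int, Node] = {i: Node(0.0, frozenset([ids[i]])) for i in range(n)}
    reps = list(ids)
    active = list(range(n))
    dist = D.astype(float).copy()
    while len(active) > 1:
        sub = dist[np.ix_(active, active)]
        iu = np.triu_indices(len(active), k=1)
        vals = sub[iu]
        m = vals.min()
        cand = np.flatnonzero(vals == m)
        best = None
        for c in cand:
            i, j = active[iu[0][c]], active[iu[1][c]]
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        hi, hj = nodes[i].height, nodes[j].height
        h = max(float(dist[i, j]), hi, hj)
        left, right = (nodes[i], nodes[j]) if reps[i] <= reps[j] else (nodes[j], nodes[i])
        merged = Node(h, nodes[i].leaves | nodes[j].leaves, (left, right))
        for k in active:
            if k not in (i, j):
                dist[i, k] = dist[k, i] = max(dist[i, k], dist[j, k])
        reps[i] = min(reps[i], reps[j])
        nodes[i] = merged
        active.remove(j)
    return nodes[active[0]]


def hierarchical_tree(distances: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Complete-linkage merge tree; ties merge the lexicographically smallest pair."""
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    D, ids = _as_matrix(distances)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric (within 1e-9)")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return Dendrogram(_complete_linkage(D, ids), ids)


# ---------------------------------------------------------------------------
# bootstrap supports


def bootstrap_supports(
    catalog: PCCatalog,
    tree: Dendrogram | None = None,
    n_replicates: int = DEFAULT_BOOTSTRAPS,
    seed: int = 0,
) -> Dendrogram:
    """Bootstrap PC columns and annotate each internal node with the fraction
    of replicates in which its leaf set reappears as a cluster."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids = list(catalog.counts.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 genomes for bootstrap supports")
    if tree is None:
        tree = hierarchical_tree(distance_matrix(catalog))
    P = (catalog.counts.values > 0).astype(float)
    n_pcs = P.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {n.leaves: 0 for n in tree.internal_nodes()}
    for _ in range(n_replicates):
        cols = rng.integers(0, n_pcs, size=n_pcs)
        c = np.bincount(cols, minlength=n_pcs).astype(float)
        sizes = P @ c
        inter = (P * c) @ P.T
        denom = sizes[:, None] + sizes[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            D = 1.0 - 2.0 * inter / denom
        D[denom == 0] = 1.0
        np.fill_diagonal(D, 0.0)
        root = _complete_linkage(D, ids)
        seen = {n.leaves for n in root.walk() if not n.is_leaf}
        for ls in counts:
            if ls in seen:
                counts[ls] += 1
    for node in tree.internal_nodes():
        node.support = counts[node.leaves] / n_replicates
    return tree


# ---------------------------------------------------------------------------
# tree cutting and silhouettes


def cut_tree(
    tree: Dendrogram, distances: pd.DataFrame, height: float = VGC_CUT_HEIGHT
) -> VGCPartition:
    """Cut into VGCs: maximal subtrees whose merge height is below ``height``.

    Every genome is assigned; per-genome silhouette widths are computed
    against the resulting partition (singleton clusters get 0 by convention).
    """
    if not (0.0 < height <= 1.0):
        raise ValueError("cut height must be in (0, 1]")

    groups: list[frozenset[str]] = []

    def collect(node: Node) -> None:
        if node.height < height:
            groups.append(node.leaves)
        else:
            for ch in node.children:
                collect(ch)

    collect(tree.root)
    groups.sort(key=lambda g: min(g))
    assignment = {g: f"VGC_{i + 1}" for i, grp in enumerate(groups) for g in sorted(grp)}
    sil = {g: silhouette_width(distances, assignment, g) for g in tree.ids}
    return VGCPartition(assignment, height, sil)


def silhouette_width(
    distances: pd.DataFrame, partition: Mapping[str, str], genome_id: str
) -> float:
    """s = (b - a) / max(a, b); a = mean within-cluster distance, b = smallest
    mean distance to another cluster; singletons score 0 by convention."""
    if genome_id not in partition:
        raise ValueError(f"unknown genome {genome_id!r}")
    D, ids = _as_matrix(distances)
    pos = {g: i for i, g in enumerate(ids)}
    own = partition[genome_id]
    mates = [g for g in partition if partition[g] == own and g != genome_id]
    if not mates:
        return 0.0
    i = pos[genome_id]
    a = float(np.mean([D[i, pos[g]] for g in mates]))
    others: dict[str, list[float]] = {}
    for g, cl in partition.items():
        if cl != own:
            others.setdefault(cl, []).append(D[i, pos[g]])
    if not others:
        return 0.0
    b = min(float(np.mean(v)) for v in others.values())
    denom = max(a, b)
    return 0.0 if denom == 0 else (b - a) / denom
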