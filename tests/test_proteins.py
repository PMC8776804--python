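"""ORF calling, reciprocal-hit filtering, protein clusters and core sets."""

import numpy as np
import pytest

import phagetax as pt
from phagetax.genome import reverse_complement
from phagetax.proteins import (
    ProteinRecord,
    bitscore,
    evalue,
    hitgraph_from_tabular,
    protein_clusters,
)

STOP_PAD = "TAATAA" * 20  # stop codons in every forward frame, no starts in reverse


def _gene(n_codons: int, body_codon: str = "GCA") -> str:
    return "ATG" + body_codon * (n_codons - 2) + "TAA"


class TestCallOrfs:
    def test_single_planted_orf(self):
        seq = STOP_PAD + _gene(100) + STOP_PAD  # 300 nt gene
        g = pt.Genome("g", seq)
        orfs = pt.call_orfs(g)
        assert len(orfs) == 1
        assert len(orfs[0].sequence) == 99
        assert orfs[0].strand == "+"
        assert orfs[0].start == len(STOP_PAD)
        assert orfs[0].end == len(STOP_PAD) + 300

    def test_all_a_sequence_has_no_orfs(self):
        assert pt.call_orfs(pt.Genome("g", "A" * 2_000)) == []

    def test_reverse_strand_orf_found(self):
        gene = _gene(80)
        seq = STOP_PAD + reverse_complement(gene) + STOP_PAD
        g = pt.Genome("g", seq)
        orfs = pt.call_orfs(g)
        assert len(orfs) == 1
        assert orfs[0].strand == "-"
        assert orfs[0].sequence == "M" + "A" * 78

    def test_matches_six_frame_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        g = pt.Genome("g", seq)
        got = {(o.start, o.end, o.strand, o.sequence) for o in pt.call_orfs(g, min_aa=30)}
        assert got == _orf_oracle(seq, 30)

    def test_min_aa_filter(self):
        seq = STOP_PAD + _gene(40) + STOP_PAD
        g = pt.Genome("g", seq)
        assert len(pt.call_orfs(g, min_aa=30)) == 1
        assert pt.call_orfs(g, min_aa=60) == []


def _orf_oracle(seq: str, min_aa: int) -> set:
    """Independent six-frame scan: first start after each stop, walk to stop."""
    from Bio.Seq import Seq

    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            pos = frame
            start = None
            while pos + 3 <= L:
                codon = s[pos : pos + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if start is not None and (pos - start) // 3 >= min_aa:
                        aa = str(Seq(s[start:pos]).translate())
                        if strand == "+":
                            iv = (start, pos + 3)
                        else:
                            iv = (L - pos - 3, L - start)
                        out.add((iv[0], iv[1], strand, aa))
                    start = None
                elif start is None and codon in ("ATG", "GTG", "TTG"):
                    start = pos
                pos += 3
    return out


class TestHitFiltering:
    def _prots(self):
        return [
            ProteinRecord("a|p1", "a", "MKVLAEQ" * 30),
            ProteinRecord("b|p1", "b", "MKVLAEQ" * 30),
        ]

    def test_identical_proteins_connected(self):
        graph = pt.all_vs_all_hits(self._prots())
        assert ("a|p1", "b|p1") in graph.edges
        e, b = graph.edges[("a|p1", "b|p1")]
        assert e <= 1e-4 and b >= 50

    def test_unrelated_proteins_not_connected(self):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        p1 = ProteinRecord("a|p1", "a", "".join(rng.choice(aas, 150)))
        p2 = ProteinRecord("b|p1", "b", "".join(rng.choice(aas, 150)))
        graph = pt.all_vs_all_hits([p1, p2], seed_prefilter=False)
        assert graph.edges == {}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pt.all_vs_all_hits([])

    def test_karlin_altschul_conversion(self):
        # bitscore = (lambda*S - ln K)/ln 2; a raw score of 300 is ~140 bits
        assert bitscore(300) == pytest.approx((0.3176 * 300 - np.log(0.134)) / np.log(2))
        assert evalue(300, 200, 200) == pytest.approx(200 * 200 * 2 ** (-bitscore(300)))

    @pytest.mark.parametrize(
        "e1,b1,e2,b2,kept",
        [
            (1e-20, 120.0, 1e-20, 120.0, True),
            (1e-2, 120.0, 1e-20, 120.0, False),   # e-value above 1e-4 in one direction
            (1e-20, 40.0, 1e-20, 120.0, False),   # bitscore below 50 in one direction
        ],
    )
    def test_tabular_filters(self, tmp_path, e1, b1, e2, b2, kept):
        prots = self._prots()
        path = tmp_path / "hits.tsv"
        path.write_text(
            f"a|p1\tb|p1\t100.0\t210\t0\t0\t1\t210\t1\t210\t{e1}\t{b1}\n"
            f"b|p1\ta|p1\t100.0\t210\t0\t0\t1\t210\t1\t210\t{e2}\t{b2}\n"
        )
        graph = hitgraph_from_tabular(prots, path)
        assert (("a|p1", "b|p1") in graph.edges) is kept

    def test_tabular_requires_reciprocal_hits(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("a|p1\tb|p1\t100.0\t210\t0\t0\t1\t210\t1\t210\t1e-30\t200\n")
        graph = hitgraph_from_tabular(self._prots(), path)
        assert graph.edges == {}


class TestProteinClusters:
    def test_edgeless_graph_gives_singletons(self):
        prots = [ProteinRecord(f"g|p{i}", "g", "MKV" * 20) for i in range(5)]
        graph = pt.HitGraph([p.protein_id for p in prots], {})
        cat = protein_clusters(prots, graph)
        assert len(set(cat.pc_of.values())) == 5

    def test_path_graph_is_one_cluster(self):
        prots = [ProteinRecord(x, "g", "MKV" * 20) for x in ("a", "b", "c")]
        graph = pt.HitGraph(["a", "b", "c"], {("a", "b"): (0, 99), ("b", "c"): (0, 99)})
        cat = protein_clusters(prots, graph)
        assert len(set(cat.pc_of.values())) == 1
        assert cat.pc_of["a"] == "PC|a"

    def test_two_identical_proteomes_pair_every_pc(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(aas, 120)) for _ in range(6)]
        prots = [
            ProteinRecord(f"{g}|p{i}", g, s)
            for g in ("gA", "gB")
            for i, s in enumerate(seqs)
        ]
        cat = protein_clusters(prots, pt.all_vs_all_hits(prots))
        assert (cat.counts.values == 1).all()
        assert cat.counts.shape == (2, 6)

    def test_matches_bfs_component_oracle(self):
        rng = np.random.default_rng(3)
        ids = [f"g|p{i}" for i in range(30)]
        prots = [ProteinRecord(x, "g", "MKV" * 15) for x in ids]
        edges = {}
        for _ in range(25):
            i, j = rng.choice(30, size=2, replace=False)
            a, b = sorted((ids[i], ids[j]))
            edges[(a, b)] = (0.0, 100.0)
        cat = protein_clusters(prots, pt.HitGraph(ids, edges))
        # independent BFS
        adj = {x: set() for x in ids}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen, comps = set(), []
        for x in ids:
            if x in seen:
                continue
            stack, comp = [x], set()
            while stack:
                y = stack.pop()
                if y in comp:
                    continue
                comp.add(y)
                stack.extend(adj[y] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        ours = {}
        for pid, pc in cat.pc_of.items():
            ours.setdefault(pc, set()).add(pid)
        assert {frozenset(v) for v in ours.values()} == set(comps)


class TestCoreSets:
    def _catalog(self, genome_pcs: dict[str, list[str]], lengths=None):
        prots = []
        for g, pcs in genome_pcs.items():
            for i, pc in enumerate(pcs):
                n = (lengths or {}).get((g, i), 50)
                prots.append(ProteinRecord(f"{g}|p{i}", g, "K" * n))
        # synthetic graph: proteins labelled with the same pc name are linked
        edges = {}
        by_pc = {}
        for g, pcs in genome_pcs.items():
            for i, pc in enumerate(pcs):
                by_pc.setdefault(pc, []).append(f"{g}|p{i}")
        for members in by_pc.values():
            for a, b in zip(members, members[1:]):
                edges[tuple(sorted((a, b)))] = (0.0, 99.0)
        return protein_clusters(prots, pt.HitGraph([p.protein_id for p in prots], edges))

    def test_identical_proteomes_all_core(self):
        cat = self._catalog({"gA": [f"x{i}" for i in range(8)],
                             "gB": [f"x{i}" for i in range(8)]})
        core = pt.core_pcs(cat, ["gA", "gB"])
        assert len(core.core_pcs) == 8

    def test_missing_pc_excluded(self):
        cat = self._catalog({"gA": ["x0", "x1", "x2"], "gB": ["x0", "x1"]})
        core = pt.core_pcs(cat, ["gA", "gB"])
        assert len(core.core_pcs) == 2

    def test_duplicates_dropped_keep_longest(self):
        cat = self._catalog(
            {"gA": ["x0", "x0"], "gB": ["x0", "x1"]},
            lengths={("gA", 0): 40, ("gA", 1): 90},
        )
        core = pt.core_pcs(cat, ["gA", "gB"])
        assert core.duplicates_dropped == 1
        pc = core.core_pcs[0]
        assert core.representatives[pc]["gA"] == "gA|p1"  # the 90-residue paralog

    def test_unknown_member_rejected(self):
        cat = self._catalog({"gA": ["x0"], "gB": ["x0"]})
        with pytest.raises(ValueError):
            pt.core_pcs(cat, ["gA", "nope"])
        with pytest.raises(ValueError):
            pt.core_pcs(cat, ["gA"])

    def test_planted_universal_genes(self, small_community):
        genomes = [g for g in small_community.genomes
                   if g.truth_labels["family"] == "F1"]
        prots = [p for g in genomes for p in pt.call_orfs(g, min_aa=100)]
        cat = protein_clusters(prots, pt.all_vs_all_hits(prots))
        core = pt.core_pcs(cat, [g.id for g in genomes], family_id="F1")
        # every planted gene is shared within the family, so the core is large
        assert len(core.core_pcs) >= 10
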