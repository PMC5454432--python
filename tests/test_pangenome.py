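import math
import random

import numpy as np
import pytest

from sirvpop.io import FeatureRecord, GenomeRecord
from sirvpop.pangenome import (
    AlignmentParams,
    ORFRecord,
    bit_score,
    build_similarity_graph,
    extract_orfs,
    find_orfs_naive,
    local_align,
    make_clusters,
    mcl_cluster,
    partition_core_variable,
    presence_absence,
    rescue_missed_orfs,
)
from .oracles import blosum62, mcl_oracle, sw_score_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def _orf(orf_id, genome_id, protein, start=0):
    feat = FeatureRecord(orf_id, start, start + 3 * len(protein) + 3, "+", "CDS")
    return ORFRecord(orf_id, genome_id, feat, protein)


class TestLocalAlign:
    def test_self_alignment_is_diagonal_sum(self):
        seq = "MKVLHEAGAW"
        expected = sum(blosum62(c, c) for c in seq)
        assert local_align(seq, seq) == expected

    def test_classic_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        assert local_align(a, b) == sw_score_oracle(a, b)

    def test_no_positive_pair_floors_at_zero(self):
        assert local_align("PPPP", "GGGG") == 0.0

    def test_agrees_with_oracle_on_200_random_pairs(self):
        rng = random.Random(42)
        for _ in range(200):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
            assert local_align(a, b) == sw_score_oracle(a, b), (a, b)

    def test_symmetric(self):
        assert local_align("MKWV", "MQWIV") == local_align("MQWIV", "MKWV")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MK")


class TestBitScore:
    def test_zero_raw_score(self):
        p = AlignmentParams()
        assert bit_score(0.0, p) == pytest.approx(-math.log(p.k) / math.log(2))

    def test_closed_form(self):
        p = AlignmentParams(lam=0.267, k=0.041)
        # high-precision evaluation of (lambda*S - ln K)/ln 2 at S=100
        assert bit_score(100.0, p) == pytest.approx(43.12818987177933, rel=1e-12)

    def test_strictly_increasing(self):
        p = AlignmentParams()
        bits = [bit_score(s, p) for s in range(0, 200, 10)]
        assert all(x < y for x, y in zip(bits, bits[1:]))


class TestSimilarityGraph:
    def test_duplicate_proteins_ratio_one(self):
        orfs = [_orf("a", "g1", "MKVLHEAGAWGH"), _orf("b", "g2", "MKVLHEAGAWGH")]
        edges = build_similarity_graph(orfs)
        assert len(edges) == 1 and edges[0].ratio == pytest.approx(1.0)

    def test_threshold_boundary_behavior(self):
        a, b = "MKVLHEAGAWGHEEWMK", "MKVANEAGAWGHACWMK"
        orfs = [_orf("a", "g1", a), _orf("b", "g2", b)]
        p = AlignmentParams(prefilter_k=0)
        bits = bit_score(local_align(a, b, p), p)
        self_bits = min(
            bit_score(local_align(a, a, p), p), bit_score(local_align(b, b, p), p)
        )
        ratio = bits / self_bits
        kept = build_similarity_graph(orfs, p, ratio_threshold=ratio - 0.01)
        dropped = build_similarity_graph(orfs, p, ratio_threshold=ratio + 0.01)
        at_threshold = build_similarity_graph(orfs, p, ratio_threshold=ratio)
        assert len(kept) == 1 and len(dropped) == 0
        assert len(at_threshold) == 1  # "0.3 or higher" keeps the boundary

    def test_unrelated_proteins_no_edge(self):
        orfs = [_orf("a", "g1", "MKKKKKKKKK"), _orf("b", "g2", "WWDDCCGGPP")]
        assert build_similarity_graph(orfs) == []

    def test_edge_stored_once_per_pair(self):
        orfs = [_orf(x, f"g{x}", "MKVLHEAGAWGH") for x in "abc"]
        edges = build_similarity_graph(orfs)
        pairs = {frozenset((e.orf_a, e.orf_b)) for e in edges}
        assert len(pairs) == len(edges) == 3

    def test_prefilter_does_not_change_edges(self):
        rng = random.Random(3)
        orfs = [
            _orf(f"o{i}", f"g{i}", "".join(rng.choice(AA) for _ in range(30)))
            for i in range(8)
        ] + [_orf("dup", "g9", "MKVLHEAGAWGHMKVLHEAGAWGHMKVLHE")]
        with_f = build_similarity_graph(orfs, AlignmentParams(prefilter_k=4), 0.3)
        without = build_similarity_graph(orfs, AlignmentParams(prefilter_k=0), 0.3)
        key = lambda e: (e.orf_a, e.orf_b)
        assert sorted(map(key, with_f)) == sorted(map(key, without))


class _Edge:
    def __init__(self, a, b, w):
        self.orf_a, self.orf_b, self.ratio = a, b, w


class TestMCL:
    def test_two_disjoint_triangles(self):
        edges = [
            _Edge(*p, 1.0)
            for p in [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        ]
        clusters, converged = mcl_cluster(edges, list("abcxyz"))
        assert converged
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_weak_bridge_splits_path(self):
        edges = [_Edge("a", "b", 1.0), _Edge("b", "c", 0.05), _Edge("c", "d", 1.0)]
        clusters, _ = mcl_cluster(edges, list("abcd"), inflation=2.0)
        assert sorted(map(sorted, clusters)) == [["a", "b"], ["c", "d"]]
        assert mcl_oracle(
            {("a", "b"): 1.0, ("b", "c"): 0.05, ("c", "d"): 1.0}, list("abcd")
        ) == frozenset({frozenset("ab"), frozenset("cd")})

    def test_single_node_singleton(self):
        clusters, _ = mcl_cluster([], ["solo"])
        assert clusters == [{"solo"}]

    def test_matches_independent_oracle_on_random_graphs(self):
        rng = random.Random(11)
        for trial in range(15):
            n = rng.randint(2, 8)
            nodes = [f"n{i}" for i in range(n)]
            weights = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.45:
                        weights[(nodes[i], nodes[j])] = round(rng.uniform(0.1, 1.0), 3)
            edges = [_Edge(u, v, w) for (u, v), w in weights.items()]
            clusters, _ = mcl_cluster(edges, nodes)
            assert frozenset(map(frozenset, clusters)) == mcl_oracle(weights, nodes), (
                trial,
                weights,
            )

    def test_invariant_to_node_relabeling_and_order(self):
        weights = {("a", "b"): 0.9, ("b", "c"): 0.8, ("d", "e"): 0.7}
        edges = [_Edge(u, v, w) for (u, v), w in weights.items()]
        c1, _ = mcl_cluster(edges, list("abcde"))
        relabel = {"a": "z9", "b": "q1", "c": "m5", "d": "k2", "e": "w7"}
        edges2 = [_Edge(relabel[e.orf_a], relabel[e.orf_b], e.ratio) for e in edges]
        c2, _ = mcl_cluster(edges2, list(relabel.values()))
        back = frozenset(
            frozenset(k for k, v in relabel.items() if v in s) for s in c2
        )
        assert frozenset(map(frozenset, c1)) == back


class TestExtractOrfs:
    def _genome(self, seq, feats):
        g = GenomeRecord("g1", seq)
        for f in feats:
            g.add_feature(f)
        return g

    def test_plus_strand_minimal(self):
        g = self._genome("ATGTAA", [FeatureRecord("f1", 0, 6, "+", "CDS")])
        orfs, flagged = extract_orfs(g)
        assert orfs[0].protein == "M" and not flagged

    def test_minus_strand_revcomp(self):
        g = self._genome("TTACAT", [FeatureRecord("f1", 0, 6, "-", "CDS")])
        orfs, _ = extract_orfs(g)
        assert orfs[0].protein == "M"

    def test_bad_length_names_feature(self):
        g = self._genome("ATGTAAC", [FeatureRecord("oddfeat", 0, 7, "+", "CDS")])
        with pytest.raises(ValueError, match="oddfeat"):
            extract_orfs(g)

    def test_internal_stop_flagged_not_raised(self):
        g = self._genome("ATGTAAGCTTAA", [FeatureRecord("f1", 0, 12, "+", "CDS")])
        orfs, flagged = extract_orfs(g)
        assert flagged == ["f1"] and orfs == []

    def test_naive_caller_finds_planted_orf(self):
        rng = random.Random(5)
        inner = []
        while len(inner) < 70:
            c = "".join(rng.choice("ACGT") for _ in range(3))
            if c not in ("TAA", "TAG", "TGA"):
                inner.append(c)
        orf = "ATG" + "".join(inner) + "TAA"
        # G-free padding: no start codons, in-frame stops right before the ORF
        pad = "TAA" * 30
        seq = pad + orf + pad
        feats = find_orfs_naive(GenomeRecord("g", seq), min_codons=60)
        start = len(pad)
        assert any(
            f.start == start and f.end == start + len(orf) and f.strand == "+"
            for f in feats
        )


class TestRescueAndPartition:
    def _population(self):
        # g1 and g2 annotate the gene; g3 carries an exact unannotated copy
        cds = "ATGGAAGTTCTGCACGAAGCTGGTGCTTGGGGTCACGAAGAATGGATGAAAGTTTAA"
        prot_len = len(cds) // 3 - 1
        genomes = []
        for gid, annotate, carry in [("g1", True, True), ("g2", True, True), ("g3", False, True), ("g4", False, False)]:
            seq = "TTTT" + (cds if carry else "A" * len(cds)) + "GGGG"
            g = GenomeRecord(gid, seq)
            if annotate:
                g.add_feature(FeatureRecord(f"{gid}_x", 4, 4 + len(cds), "+", "CDS"))
            genomes.append(g)
        orf_index = {}
        for g in genomes:
            for o in extract_orfs(g)[0]:
                orf_index[o.orf_id] = o
        clusters = make_clusters([set(orf_index)], orf_index)
        assert len(clusters[0].members) == 2 and prot_len == 18
        return genomes, orf_index, clusters

    def test_unannotated_copy_upgraded(self):
        genomes, orf_index, clusters = self._population()
        from .oracles import six_frame_contains

        prot = next(iter(orf_index.values())).protein
        assert six_frame_contains(genomes[2].sequence, prot)  # oracle: copy is there
        assert not six_frame_contains(genomes[3].sequence, prot)
        matrix = rescue_missed_orfs(clusters, genomes, orf_index, AlignmentParams())
        assert matrix.loc["c1", "g3"] == "present_no_start"
        assert matrix.loc["c1", "g4"] == "absent"

    def test_annotated_cell_unchanged(self):
        genomes, orf_index, clusters = self._population()
        matrix = rescue_missed_orfs(clusters, genomes, orf_index)
        assert matrix.loc["c1", "g1"] == "present"

    def test_partition_core_requires_all_genomes(self):
        genomes, orf_index, clusters = self._population()
        pre = presence_absence(clusters, [g.id for g in genomes])
        labelled, _ = partition_core_variable(clusters, [g.id for g in genomes], pre)
        assert labelled[0].status == "variable"  # g3/g4 lack annotation
        post = rescue_missed_orfs(clusters, genomes, orf_index, matrix=pre)
        labelled2, stats = partition_core_variable(clusters, [g.id for g in genomes], post)
        assert labelled2[0].status == "variable"  # g4 genuinely lacks the gene
        three = [g.id for g in genomes[:3]]
        labelled3, _ = partition_core_variable(clusters, three, post.loc[:, three])
        assert labelled3[0].status == "core"  # rescued g3 counts toward core

    def test_singleton_cluster_is_variable(self):
        orf_index = {"only": _orf("only", "g1", "MKVLHEAGAW")}
        clusters = make_clusters([{"only"}], orf_index)
        pre = presence_absence(clusters, ["g1", "g2"])
        labelled, _ = partition_core_variable(clusters, ["g1", "g2"], pre)
        assert labelled[0].status == "variable"

    def test_multi_copy_flagged(self):
        orf_index = {
            "a1": _orf("a1", "g1", "MKVLHEAGAW"),
            "a2": _orf("a2", "g1", "MKVLHEAGAW", start=100),
        }
        clusters = make_clusters([{"a1", "a2"}], orf_index)
        df = presence_absence(clusters, ["g1"])
        assert df.loc["c1", "g1"] == "multi"


class TestClusterNaming:
    def test_ids_ordered_by_size_then_member(self):
        orf_index = {
            x: _orf(x, f"g{i}", "MKVLHEAGAW") for i, x in enumerate(["b1", "b2", "a1"])
        }
        clusters = make_clusters([{"a1"}, {"b1", "b2"}], orf_index)
        assert [(c.cluster_id, len(c.members)) for c in clusters] == [("c1", 2), ("c2", 1)]


def test_end_to_end_cluster_recovery(demo_result, small_population):
    """Cluster assignments reproduce the simulated truth partition exactly."""
    assert demo_result.metrics["cluster_ari"] == 1.0
    truth_core = {
        lab for lab, st in small_population.truth.gene_labels.values() if st == "core"
    }
    assert demo_result.metrics["n_core_clusters"] == len(truth_core)
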