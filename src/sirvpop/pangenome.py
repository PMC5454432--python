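"""Homologous gene clustering and the core/variable pangenome partition.

ORFs are extracted from CDS annotations and compared all-against-all by exact
Smith-Waterman local alignment (BLOSUM62, affine gaps). Raw scores are
converted to bits with the Karlin-Altschul formula and screened by the
bit-score ratio: alignment bits over the smaller self-alignment bits, keeping
pairs at ratio >= 0.3 by default. The similarity graph is clustered by Markov
clustering (expansion/inflation iteration); missed or miscalled ORFs are
rescued by aligning cluster proteins against all six translated frames of
each genome, and clusters present in every genome are labelled core.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import FeatureRecord, GenomeRecord, translate_cds

PRESENT = "present"
PRESENT_NO_START = "present_no_start"
MULTI = "multi"
ABSENT = "absent"


@dataclass
class ORFRecord:
    orf_id: str
    genome_id: str
    feature: FeatureRecord
    protein: str


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for protein alignment and bit-score conversion.

    Gap convention is BLAST-style: a gap of length k costs open + k*extend.
    lam and k are the Karlin-Altschul constants for gapped BLOSUM62 11/1.
    prefilter_k > 0 skips pairs sharing no protein k-mer (they cannot reach
    the ratio screen); 0 disables the prefilter.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041
    prefilter_k: int = 4

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


_ALIGNER_CACHE: dict[tuple, PairwiseAligner] = {}


def _scoring_matrix(name: str):
    m = substitution_matrices.load(name)
    # ambiguous residue X scores 0 against everything
    if "X" in m.alphabet:
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


def _get_aligner(params: AlignmentParams, mode: str = "local") -> PairwiseAligner:
    key = (params.matrix_name, params.gap_open, params.gap_extend, mode)
    if key not in _ALIGNER_CACHE:
        aligner = PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = _scoring_matrix(params.matrix_name)
        # BLAST gap cost open + k*extend == biopython (open+extend) + (k-1)*extend
        aligner.open_gap_score = -(params.gap_open + params.gap_extend)
        aligner.extend_gap_score = -params.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def _sanitize(protein: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in protein.upper())


def local_align(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal Smith-Waterman local alignment score under affine gaps."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    params = params or AlignmentParams()
    aligner = _get_aligner(params, "local")
    alphabet = str(aligner.substitution_matrix.alphabet)
    return float(aligner.score(_sanitize(a, alphabet), _sanitize(b, alphabet)))


def bit_score(raw_score: float, params: AlignmentParams | None = None) -> float:
    """Karlin-Altschul bit score: (lambda * S - ln K) / ln 2."""
    params = params or AlignmentParams()
    return (params.lam * raw_score - math.log(params.k)) / math.log(2)


# ---------------------------------------------------------------------------
# ORF extraction


def extract_orfs(genome: GenomeRecord) -> tuple[list[ORFRecord], list[str]]:
    """One ORF per CDS feature; returns (orfs, ids flagged for internal stops).

    Minus-strand CDSs are reverse-complemented before translation. A CDS whose
    length is not divisible by 3 is an error naming the feature; internal
    stops flag the ORF and exclude it from clustering.
    """
    orfs, flagged = [], []
    for feat in genome.features:
        if feat.kind != "CDS":
            continue
        nt = genome.feature_seq(feat)
        if len(nt) % 3 != 0:
            raise ValueError(f"CDS {feat.feature_id}: length {len(nt)} not divisible by 3")
        try:
            prot = translate_cds(nt)
        except ValueError:
            flagged.append(feat.feature_id)
            continue
        if not prot:
            flagged.append(feat.feature_id)
            continue
        orfs.append(ORFRecord(feat.feature_id, genome.id, feat, prot))
    return orfs, flagged


def find_orfs_naive(genome: GenomeRecord, min_codons: int = 60) -> list[FeatureRecord]:
    """Fallback ORF caller for FASTA-only input.

    Per frame and strand, within each stop-to-stop segment the longest ORF
    beginning at an ATG/GTG/TTG start and running to the stop is kept if it
    spans at least min_codons codons (stop included).
    """
    starts = {"ATG", "GTG", "TTG"}
    found = []
    n = len(genome.sequence)
    for strand in "+-":
        seq = genome.sequence if strand == "+" else _rc(genome.sequence)
        for frame in range(3):
            seg_start = frame
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    orf = _longest_orf_in_segment(seq, seg_start, i + 3, starts, min_codons)
                    if orf:
                        found.append((strand, *orf))
                    seg_start = i + 3
    feats = []
    for k, (strand, s, e) in enumerate(sorted(found, key=lambda t: (t[1], t[2], t[0]))):
        if strand == "-":
            s, e = n - e, n - s
        feats.append(FeatureRecord(f"{genome.id}_naive{k + 1:03d}", s, e, strand, "CDS"))
    return feats


def _rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _longest_orf_in_segment(seq, seg_start, seg_end, starts, min_codons):
    for i in range(seg_start, seg_end - 2, 3):
        if seq[i : i + 3] in starts:
            if (seg_end - i) // 3 >= min_codons:
                return (i, seg_end)
            return None
    return None


# ---------------------------------------------------------------------------
# similarity graph


@dataclass
class SimilarityEdge:
    orf_a: str
    orf_b: str
    raw_score: float
    bits: float
    ratio: float


def _kmer_set(protein: str, k: int) -> set[str]:
    return {protein[i : i + k] for i in range(len(protein) - k + 1)}


def build_similarity_graph(
    orfs: list[ORFRecord],
    params: AlignmentParams | None = None,
    ratio_threshold: float = 0.3,
) -> list[SimilarityEdge]:
    """All-vs-all bit-score-ratio screen.

    ratio = bits(a,b) / min(self-bits a, self-bits b); edges kept iff
    ratio >= ratio_threshold. One edge per unordered pair, no self-edges.
    """
    if len(orfs) < 2:
        return []
    params = params or AlignmentParams()
    self_bits = {o.orf_id: bit_score(local_align(o.protein, o.protein, params), params) for o in orfs}
    kmers = (
        {o.orf_id: _kmer_set(o.protein, params.prefilter_k) for o in orfs}
        if params.prefilter_k > 0
        else None
    )
    edges = []
    for a, b in itertools.combinations(orfs, 2):
        if kmers is not None and kmers[a.orf_id].isdisjoint(kmers[b.orf_id]):
            continue
        raw = local_align(a.protein, b.protein, params)
        bits = bit_score(raw, params)
        ratio = bits / min(self_bits[a.orf_id], self_bits[b.orf_id])
        if ratio >= ratio_threshold:
            edges.append(SimilarityEdge(a.orf_id, b.orf_id, raw, bits, ratio))
    return edges


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    edges: list[SimilarityEdge],
    node_ids: list[str],
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> tuple[list[set[str]], bool]:
    """Markov clustering of the weighted similarity graph.

    Self-loops are set to each node's maximum incident weight (1 for isolated
    nodes); the column-stochastic matrix is iterated by expansion (squaring)
    and inflation (elementwise power, renormalization) until the maximum
    column change drops below tol. Clusters are the connected components of
    the attractor matrix; returns (clusters, converged).
    """
    ids = sorted(node_ids)
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    M = np.zeros((n, n))
    for e in edges:
        i, j = index[e.orf_a], index[e.orf_b]
        w = max(e.ratio, 0.0)
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = M**inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    adj = csr_matrix((M + M.T) > prune)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for nid, i in index.items():
        clusters[labels[i]].add(nid)
    return clusters, converged


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[str]
    status: str = ""  # core | variable
    genomes: dict[str, int] = field(default_factory=dict)  # genome -> copy number


def make_clusters(member_sets: list[set[str]], orf_index: dict[str, ORFRecord]) -> list[GeneCluster]:
    """Label clusters c1..cN ordered by size desc, then smallest member id."""
    ordered = sorted(member_sets, key=lambda s: (-len(s), min(s)))
    clusters = []
    for k, members in enumerate(ordered, 1):
        genomes: dict[str, int] = {}
        for m in members:
            g = orf_index[m].genome_id
            genomes[g] = genomes.get(g, 0) + 1
        clusters.append(
            GeneCluster(cluster_id=f"c{k}", members=sorted(members), genomes=genomes)
        )
    return clusters


# ---------------------------------------------------------------------------
# presence/absence, rescue, partition


def presence_absence(clusters: list[GeneCluster], genome_ids: list[str]) -> pd.DataFrame:
    """Cluster x genome matrix with entries absent/present/multi."""
    df = pd.DataFrame(ABSENT, index=[c.cluster_id for c in clusters], columns=genome_ids)
    for c in clusters:
        for g, copies in c.genomes.items():
            df.loc[c.cluster_id, g] = MULTI if copies > 1 else PRESENT
    df.index.name = "cluster"
    return df


def six_frame_translations(genome: GenomeRecord) -> list[str]:
    """The six translated frames with '*' at stops (TBLASTN-style targets)."""
    frames = []
    for seq in (genome.sequence, _rc(genome.sequence)):
        for off in range(3):
            sub = seq[off : off + 3 * ((len(seq) - off) // 3)]
            frames.append(str(Seq(sub).translate(table=1)))
    return frames


def rescue_missed_orfs(
    clusters: list[GeneCluster],
    genomes: list[GenomeRecord],
    orf_index: dict[str, ORFRecord],
    params: AlignmentParams | None = None,
    ratio_threshold: float = 0.3,
    matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Upgrade absent cells where a cluster protein hits the genome's six
    translated frames at a qualifying bit-score ratio.

    For each absent cluster x genome cell, member proteins (largest first) are
    locally aligned against all six frames; a hit with
    bits / self-bits >= ratio_threshold marks the cell present_no_start.
    """
    params = params or AlignmentParams()
    if matrix is None:
        matrix = presence_absence(clusters, [g.id for g in genomes])
    matrix = matrix.copy()
    frames_cache = {g.id: six_frame_translations(g) for g in genomes}
    for c in clusters:
        members = sorted(
            c.members, key=lambda m: -len(orf_index[m].protein)
        )
        for g in genomes:
            if matrix.loc[c.cluster_id, g.id] != ABSENT:
                continue
            if _cluster_hits_genome(members, frames_cache[g.id], orf_index, params, ratio_threshold):
                matrix.loc[c.cluster_id, g.id] = PRESENT_NO_START
    return matrix


def _cluster_hits_genome(members, frames, orf_index, params, threshold) -> bool:
    for m in members:
        prot = orf_index[m].protein
        self_bits = bit_score(local_align(prot, prot, params), params)
        for frame in frames:
            if not frame:
                continue
            bits = bit_score(local_align(prot, frame, params), params)
            if bits / self_bits >= threshold:
                return True
    return False


def partition_core_variable(
    clusters: list[GeneCluster], genome_ids: list[str], matrix: pd.DataFrame
) -> tuple[list[GeneCluster], pd.DataFrame]:
    """Label clusters core (non-absent in every genome) or variable.

    Returns the labelled clusters and a per-genome statistics table with the
    core fraction (core ORFs / total annotated ORFs).
    """
    labelled = []
    for c in clusters:
        status = (
            "core"
            if all(matrix.loc[c.cluster_id, g] != ABSENT for g in genome_ids)
            else "variable"
        )
        labelled.append(replace(c, status=status))
    rows = []
    core_ids = {c.cluster_id for c in labelled if c.status == "core"}
    for g in genome_ids:
        total = sum(c.genomes.get(g, 0) for c in labelled)
        core = sum(c.genomes.get(g, 0) for c in labelled if c.cluster_id in core_ids)
        rows.append(
            {
                "genome": g,
                "n_orfs": total,
                "n_core_orfs": core,
                "core_fraction": core / total if total else 0.0,
            }
        )
    return labelled, pd.DataFrame(rows)
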