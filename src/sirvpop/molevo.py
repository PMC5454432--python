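"""Within-cluster codon alignment and molecular-evolution statistics.

Implements the Nei–Gojobori (1986) pathway-counting estimate of Pn/Ps (the
convention used by SNAP), Jukes–Cantor distances with alignment-wide complete
deletion, and neighbor-joining trees on the resulting distance matrices.
Protein-guided codon alignment uses a star/progressive scheme around the
longest member: each member is globally aligned to the centre and gaps are
merged ("once a gap, always a gap"), then every protein gap is expanded to a
codon gap.
"""

from __future__ import annotations

import io as _io
import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

from .io import translate_cds

GAP_CODON = "---"
BASES = "ACGT"

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    """Codon-aware nucleotide alignment: rows padded in triplets."""

    ids: list[str]
    rows: list[str]
    cluster_id: str = ""

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")
        if lens and next(iter(lens)) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, member_id: str) -> str:
        return self.rows[self.ids.index(member_id)]

    def ungapped(self, member_id: str) -> str:
        return self.row(member_id).replace("-", "")


def _pairwise_global(a: str, b: str):
    """Best global protein alignment (BLOSUM62, BLAST-style 11/1 gaps)."""
    from .pangenome import AlignmentParams, _get_aligner

    aligner = _get_aligner(AlignmentParams(), mode="global")
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def align_codons(cds: dict[str, str], cluster_id: str = "") -> CodonAlignment:
    """Align a set of in-frame CDSs via their protein translations.

    The longest protein (ties broken by id) is the star centre; every other
    member is aligned to it and insertions are merged. Stop codons ride along
    as a final aligned column.
    """
    if len(cds) < 2:
        raise ValueError("need at least two CDSs to align")
    prots = {mid: translate_cds(nt) for mid, nt in cds.items()}
    order = sorted(prots, key=lambda m: (-len(prots[m]), m))
    centre = order[0]
    cl = len(prots[centre])

    # per-member: residues inserted before each centre position, and the
    # residue (or None) aligned to each centre position
    pre_ins: dict[str, list[str]] = {centre: [""] * (cl + 1)}
    aligned: dict[str, list[str | None]] = {centre: list(prots[centre])}
    for mid in order[1:]:
        tgt, qry = _pairwise_global(prots[centre], prots[mid])
        ins = [""] * (cl + 1)
        res: list[str | None] = []
        ci = 0
        for tc, qc in zip(tgt, qry):
            if tc == "-":
                ins[ci] += qc
            else:
                res.append(None if qc == "-" else qc)
                ci += 1
        pre_ins[mid] = ins
        aligned[mid] = res

    slot = [max(len(pre_ins[m][k]) for m in cds) for k in range(cl + 1)]

    rows = []
    for mid in cds:
        codons = [cds[mid][i : i + 3] for i in range(0, len(cds[mid]), 3)]
        n_res = len(prots[mid])
        it = iter(codons[:n_res])
        out: list[str] = []
        for k in range(cl + 1):
            insert = pre_ins[mid][k]
            out.append(GAP_CODON * (slot[k] - len(insert)))
            out.extend(next(it) for _ in insert)
            if k < cl:
                r = aligned[mid][k]
                out.append(GAP_CODON if r is None else next(it))
        # trailing stop codon as one final column
        out.append(codons[n_res] if len(codons) > n_res else GAP_CODON)
        rows.append("".join(out))
    return CodonAlignment(ids=list(cds), rows=rows, cluster_id=cluster_id)


# ---------------------------------------------------------------------------
# Nei-Gojobori


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Potential synonymous sites of a sense codon.

    Per position, the fraction of the 3 possible changes that are synonymous;
    changes creating stop codons count as nonsynonymous so that syn + nonsyn
    sites always total 3.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                s += 1 / 3
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) differences between two sense codons.

    All orderings of the single-step mutational pathways are weighted equally;
    pathways passing through a stop codon are excluded. Returns None when every
    pathway is excluded (the codon pair is then skipped).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    syn_tot = nonsyn_tot = 0.0
    n_valid = 0
    for perm in itertools.permutations(diff):
        cur = codon_a
        path = []
        ok = True
        for pos in perm:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            path.append((cur, nxt))
            cur = nxt
        if not ok:
            continue
        n_valid += 1
        for a, b in path:
            if CODON_TO_AA[a] == CODON_TO_AA[b]:
                syn_tot += 1
            else:
                nonsyn_tot += 1
    if n_valid == 0:
        return None
    return syn_tot / n_valid, nonsyn_tot / n_valid


@dataclass
class PnPsResult:
    """Nei-Gojobori site and difference counts for a pair (or pooled set)."""

    id_a: str
    id_b: str
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    n_codons: int = 0
    undefined: bool = False

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pn(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def ratio(self) -> float:
        """Pn/Ps; nan when undefined (Ps = 0)."""
        if self.undefined or self.ps == 0:
            return float("nan")
        return self.pn / self.ps


def _iter_codon_pairs(row_a: str, row_b: str):
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        yield ca, cb


def nei_gojobori_pair(row_a: str, row_b: str, id_a: str = "a", id_b: str = "b") -> PnPsResult:
    """Nei-Gojobori proportion-based Pn/Ps for one codon-aligned pair.

    Codons containing gaps, N, or stops in either row are skipped pairwise.
    """
    if len(row_a) != len(row_b) or len(row_a) % 3:
        raise ValueError("rows must be codon-aligned and of equal length")
    res = PnPsResult(id_a=id_a, id_b=id_b)
    for ca, cb in _iter_codon_pairs(row_a, row_b):
        d = pathway_differences(ca, cb)
        if d is None:
            continue
        sa, sb = synonymous_sites(ca), synonymous_sites(cb)
        res.S += (sa + sb) / 2
        res.N += 3 - (sa + sb) / 2
        res.Sd += d[0]
        res.Nd += d[1]
        res.n_codons += 1
    if res.n_codons == 0 or res.Sd == 0:
        res.undefined = True
    return res


def cluster_pnps(alignment: CodonAlignment, min_members: int = 2) -> PnPsResult:
    """Pooled Pn/Ps over all unordered member pairs of a cluster alignment.

    The cluster ratio is (sum Nd / sum N) / (sum Sd / sum S), pooling pathway
    and site counts across pairs rather than averaging per-pair ratios.
    """
    if len(alignment.ids) < min_members:
        raise ValueError(
            f"cluster {alignment.cluster_id or '?'} has {len(alignment.ids)} members, "
            f"fewer than min_members={min_members}"
        )
    pooled = PnPsResult(id_a=alignment.cluster_id or "cluster", id_b="pooled")
    any_defined = False
    for a, b in itertools.combinations(range(len(alignment.ids)), 2):
        pair = nei_gojobori_pair(
            alignment.rows[a], alignment.rows[b], alignment.ids[a], alignment.ids[b]
        )
        pooled.S += pair.S
        pooled.N += pair.N
        pooled.Sd += pair.Sd
        pooled.Nd += pair.Nd
        pooled.n_codons += pair.n_codons
        if not pair.undefined:
            any_defined = True
    pooled.undefined = not any_defined or pooled.Sd == 0
    return pooled


# ---------------------------------------------------------------------------
# distances and trees


def complete_deletion_mask(rows: list[str]) -> np.ndarray:
    """Boolean mask of columns free of gaps and N in every row."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    bad = (arr == ord("-")) | (arr == ord("N"))
    return ~bad.any(axis=0)


def jc_distance(row_a: str, row_b: str, keep: np.ndarray | None = None) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3).

    `keep` is the complete-deletion column mask computed over the whole
    alignment (every column with a gap or N in any row removed); by default it
    is computed from the pair alone. p >= 0.75 saturates to infinity.
    """
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    if a.size != b.size:
        raise ValueError("rows must be aligned")
    if keep is None:
        keep = complete_deletion_mask([row_a, row_b])
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no sites left after complete deletion")
    p = float(np.mean(a != b))
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log1p(-4 * p / 3)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    model: str = "JC"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        self.values = v


def jc_matrix(alignment_rows: dict[str, str]) -> DistanceMatrix:
    """All-pairs JC distances under alignment-wide complete deletion."""
    ids = list(alignment_rows)
    keep = complete_deletion_mask([alignment_rows[i] for i in ids])
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = jc_distance(alignment_rows[ids[i]], alignment_rows[ids[j]], keep)
    return DistanceMatrix(ids=ids, values=d)


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string.

    Negative branch lengths are clamped to zero; taxa are processed in sorted
    id order so ties resolve deterministically.
    """
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(matrix.values, matrix.values.T):
        raise ValueError("distance matrix is not symmetric")
    order = sorted(range(len(matrix.ids)), key=lambda i: matrix.ids[i])
    ids = [matrix.ids[i] for i in order]
    vals = matrix.values[np.ix_(order, order)]
    tree = _skbio_nj(_SkbioDM(vals, ids), neg_as_zero=True)
    return str(tree).strip()


def tip_sets(newick: str) -> list[frozenset[str]]:
    """Tip-name set below every internal node of a Newick tree."""
    tree = TreeNode.read(_io.StringIO(newick))
    out = []
    for node in tree.non_tips(include_self=True):
        out.append(frozenset(t.name for t in node.tips()))
    return out


def is_monophyletic(newick: str, taxa: set[str]) -> bool:
    """True if `taxa` form a clade of the (unrooted) tree.

    A subset is monophyletic in the unrooted sense iff some edge bipartition
    separates it exactly; equivalently some node's tip set equals the subset
    or its complement.
    """
    taxa = frozenset(taxa)
    sets = tip_sets(newick)
    all_tips = max(sets, key=len)
    return any(s == taxa or all_tips - s == taxa for s in sets)


@dataclass
class ConcatenatedAlignment:
    """Per-genome concatenation of single-copy cluster alignments."""

    rows: dict[str, str] = field(default_factory=dict)
    n_clusters: int = 0


def concatenate_alignments(
    alignments: list[CodonAlignment], member_to_genome: dict[str, str]
) -> ConcatenatedAlignment:
    """Concatenate cluster alignments genome-wise (single-copy clusters only).

    Only clusters with exactly one member per genome, covering the same genome
    set, are concatenated; others are skipped.
    """
    genome_sets = []
    usable = []
    for aln in alignments:
        genomes = [member_to_genome[m] for m in aln.ids]
        if len(set(genomes)) == len(genomes):
            usable.append((aln, genomes))
            genome_sets.append(frozenset(genomes))
    if not usable:
        return ConcatenatedAlignment()
    common = frozenset.intersection(*genome_sets)
    rows: dict[str, list[str]] = {g: [] for g in sorted(common)}
    n = 0
    for aln, genomes in usable:
        if not common <= frozenset(genomes):
            continue
        by_genome = dict(zip(genomes, aln.rows))
        for g in rows:
            rows[g].append(by_genome[g])
        n += 1
    return ConcatenatedAlignment(rows={g: "".join(parts) for g, parts in rows.items()}, n_clusters=n)
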