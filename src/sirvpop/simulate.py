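"""Synthetic SIRV-like virus populations and host CRISPR arrays, with truth.

The generator emulates the structure the downstream analysis assumes: ~35 kb
AT-rich linear genomes carrying a syntenic central block of core genes
flanked by terminal variable genes, two (or more) geographic clades related
by a simple regional tree, and hosts whose repeat-spacer arrays record
protospacers sampled from local viruses at low divergence and foreign
viruses at higher divergence, plus decoy spacers unrelated to any virus.

Genes evolve codon-wise: a binomial number of substitutions is applied per
branch, with nonsynonymous proposals accepted at probability omega (<1 gives
purifying selection, Pn/Ps < 1) and stop-creating changes rejected. Gene
gain/loss flips terminal variable genes per branch. Protospacers are sampled
at positions whose flanking bases already satisfy the PAM motif, so every
planted spacer has a detectable PAM.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crispr
from .io import (
    FeatureRecord,
    GenomeRecord,
    InfectionMatrix,
    revcomp,
    write_fasta,
    write_gff,
    write_infection_matrix,
)
from .molevo import CODON_TO_AA, STOP_CODONS

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population."""

    seed: int = 0
    n_regions: int = 2
    viruses_per_region: int = 5
    genome_length: int = 35000
    genome_length_sd: int = 1200
    gc_content: float = 0.265
    n_core_genes: int = 30
    n_variable_pool: int = 64
    core_substitution_rate: float = 0.05
    variable_substitution_rate: float = 0.10
    omega_core: float = 0.2
    omega_variable: float = 0.3
    gene_gain_loss_rate: float = 0.05
    variable_presence_prob: float = 0.35
    min_gene_codons: int = 100
    max_gene_codons: int = 230
    hosts_per_region: int = 3
    host_genome_length: int = 12000
    spacers_per_host: int = 30
    spacer_length: int = 39
    local_spacer_fraction: float = 0.8
    spacer_divergence_local: float = 0.05
    spacer_divergence_foreign: float = 0.25
    decoy_fraction: float = 0.1
    pam_motif: str = "CCN"
    repeat_sequence: str = "GATAATCTCTTATAGAATTGAAAGC"
    # exact-word anchor shared by decoy exclusion and seeded spacer matching
    match_word_size: int = 12
    region_names: tuple[str, ...] = ("Nymph Lake", "Iceland")
    # fraction of root-to-tip divergence on the shared regional branch
    region_branch_fraction: float = 0.6
    id_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "local_spacer_fraction",
            "spacer_divergence_local",
            "spacer_divergence_foreign",
            "decoy_fraction",
            "variable_presence_prob",
            "region_branch_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("core_substitution_rate", "variable_substitution_rate", "gene_gain_loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mean_gene = 3 * (self.min_gene_codons + self.max_gene_codons) / 2 + 6
        if self.n_core_genes * mean_gene >= self.genome_length:
            raise ValueError("core genes cannot fit in genome_length")

    def region_name(self, r: int) -> str:
        if r < len(self.region_names):
            return self.region_names[r]
        return f"Region{r + 1}"


@dataclass
class SpacerTruth:
    spacer_id: str
    host_id: str
    array_index: int
    sequence: str
    decoy: bool
    source_virus: str = ""
    start: int = -1
    end: int = -1
    strand: str = ""
    n_mutations: int = 0
    pam: str = ""


@dataclass
class SimulatedTruth:
    """Ground-truth ledger: gene labels, spacer provenance, tree, immunity."""

    gene_labels: dict[str, tuple[str, str]] = field(default_factory=dict)  # orf -> (cluster, status)
    spacers: list[SpacerTruth] = field(default_factory=list)
    tree_newick: str = ""
    immunity: dict[tuple[str, str], bool] = field(default_factory=dict)
    region_of: dict[str, str] = field(default_factory=dict)  # genome id -> region name


@dataclass
class Population:
    viruses: list[GenomeRecord]
    hosts: list[GenomeRecord]
    truth: SimulatedTruth
    infection: InfectionMatrix
    config: SimulationConfig


# ---------------------------------------------------------------------------
# sequence primitives


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _sense_codon_gc(base_gc: float) -> float:
    """Expected G+C of sense codons when bases are drawn at base_gc and stop
    codons are rejected (rejection discards AT-rich codons, raising G+C)."""
    p = {b: (base_gc / 2 if b in "GC" else (1 - base_gc) / 2) for b in "ACGT"}
    total = num = 0.0
    for codon in CODON_TO_AA:
        w = p[codon[0]] * p[codon[1]] * p[codon[2]]
        total += w
        num += w * sum(b in "GC" for b in codon) / 3
    return num / total


from functools import lru_cache


@lru_cache(maxsize=None)
def _calibrated_base_gc(target_gc: float) -> float:
    """Base-level G+C whose stop-rejected sense codons average target_gc."""
    from scipy.optimize import brentq

    return float(brentq(lambda g: _sense_codon_gc(g) - target_gc, 1e-6, 1 - 1e-6, xtol=1e-9))


def _random_gene(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random sense codons + TAA, at the target sense-codon composition."""
    base_gc = _calibrated_base_gc(gc)
    p = np.array([(1 - base_gc) / 2, base_gc / 2, base_gc / 2, (1 - base_gc) / 2])
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(BASES, size=3, p=p))
        if c not in STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def evolve_gene(
    seq: str, p_sub: float, omega: float, rng: np.random.Generator, gc: float = 0.5
) -> str:
    """Apply a binomial number of accepted substitutions to a gene.

    Mutable sites exclude the start and stop codons. Each accepted event
    changes one base, proposing the replacement from the genome's base
    composition (so composition does not drift toward 50% G+C); nonsynonymous
    proposals are accepted with probability omega and stop-creating proposals
    are always rejected, so the realized substitution count matches
    Binomial(sites, p_sub) while the syn/nonsyn composition reflects
    purifying selection.
    """
    if p_sub <= 0:
        return seq
    s = list(seq)
    lo, hi = 3, len(seq) - 3
    n_sites = hi - lo
    target = rng.binomial(n_sites, min(p_sub, 1.0))
    base_p = {b: (gc / 2 if b in "GC" else (1 - gc) / 2) for b in "ACGT"}
    accepted = 0
    guard = 0
    while accepted < target and guard < 1000 * (target + 1):
        guard += 1
        pos = int(rng.integers(lo, hi))
        old = s[pos]
        others = [b for b in "ACGT" if b != old]
        w = np.array([base_p[b] for b in others])
        new = str(rng.choice(others, p=w / w.sum()))
        cstart = pos - (pos % 3)
        codon_old = "".join(s[cstart : cstart + 3])
        codon_new = codon_old[: pos % 3] + new + codon_old[pos % 3 + 1 :]
        if codon_new in STOP_CODONS:
            continue
        if CODON_TO_AA[codon_old] != CODON_TO_AA[codon_new] and rng.random() > omega:
            continue
        s[pos] = new
        accepted += 1
    return "".join(s)


def _mutate_spacer(seq: str, q: float, rng: np.random.Generator) -> tuple[str, int]:
    s = list(seq)
    n = 0
    for i in range(len(s)):
        if rng.random() < q:
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
            n += 1
    return "".join(s), n


# ---------------------------------------------------------------------------
# population simulation


def simulate_population(config: SimulationConfig) -> Population:
    """Simulate virus genomes, host genomes with CRISPR arrays, and truth."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # --- ancestral genes
    n_pool = cfg.n_variable_pool
    core_roots, var_roots, strands = [], [], {}
    for k in range(cfg.n_core_genes):
        n_codons = int(rng.integers(cfg.min_gene_codons, cfg.max_gene_codons + 1))
        core_roots.append(_random_gene(rng, n_codons, cfg.gc_content))
        strands[f"core{k + 1:02d}"] = "+" if rng.random() < 0.5 else "-"
    for k in range(n_pool):
        n_codons = int(rng.integers(cfg.min_gene_codons, cfg.max_gene_codons + 1))
        var_roots.append(_random_gene(rng, n_codons, cfg.gc_content))
        strands[f"var{k + 1:02d}"] = "+" if rng.random() < 0.5 else "-"
    var_side = ["L" if k % 2 == 0 else "R" for k in range(n_pool)]

    # ancestral intergenic sequence, keyed by the downstream gene; evolves
    # neutrally along the same tree, then is sliced to each genome's gap size
    gap_labels = list(strands) + ["terminus"]
    gap_root_len = (cfg.genome_length + 4 * cfg.genome_length_sd) // (cfg.n_core_genes + 1) + 50
    gap_roots = {lab: _random_nt(rng, gap_root_len, cfg.gc_content) for lab in gap_labels}

    rb, tb = cfg.region_branch_fraction, 1.0 - cfg.region_branch_fraction

    truth = SimulatedTruth()
    viruses: list[GenomeRecord] = []
    tips_by_region: dict[str, list[str]] = {}
    region_tags = []
    for r in range(cfg.n_regions):
        name = cfg.region_name(r)
        tag = "".join(w[0] for w in name.split()).upper() or f"R{r + 1}"
        region_tags.append(tag)

        core_anc = [
            evolve_gene(g, cfg.core_substitution_rate * rb, cfg.omega_core, rng, cfg.gc_content)
            for g in core_roots
        ]
        var_anc = [
            evolve_gene(g, cfg.variable_substitution_rate * rb, cfg.omega_variable, rng, cfg.gc_content)
            for g in var_roots
        ]
        gap_anc = {
            lab: _evolve_neutral(g, cfg.core_substitution_rate * rb, rng, cfg.gc_content)
            for lab, g in gap_roots.items()
        }
        region_presence = rng.random(n_pool) < cfg.variable_presence_prob

        tips_by_region[name] = []
        for i in range(cfg.viruses_per_region):
            vid = f"SIRV-{tag}{i + 1}"
            tips_by_region[name].append(vid)
            truth.region_of[vid] = name
            core_tip = [
                evolve_gene(g, cfg.core_substitution_rate * tb, cfg.omega_core, rng, cfg.gc_content)
                for g in core_anc
            ]
            presence = region_presence.copy()
            flips = rng.random(n_pool) < cfg.gene_gain_loss_rate
            presence ^= flips
            var_tip = {
                k: evolve_gene(var_anc[k], cfg.variable_substitution_rate * tb, cfg.omega_variable, rng, cfg.gc_content)
                for k in range(n_pool)
                if presence[k]
            }
            gap_tip = {
                lab: _evolve_neutral(g, cfg.core_substitution_rate * tb, rng, cfg.gc_content)
                for lab, g in gap_anc.items()
            }
            genome = _assemble_genome(
                vid, name, core_tip, var_tip, var_side, strands, gap_tip, cfg, rng, truth
            )
            viruses.append(genome)

    _relabel_realized_core(truth, viruses)
    truth.tree_newick = _regional_newick(tips_by_region, rb, tb, cfg)

    # --- hosts
    hosts = _simulate_hosts(cfg, rng, viruses, truth, region_tags)

    # --- truth immunity and observed infection, from sequence-level targeting
    infection = _infection_from_truth(cfg, viruses, hosts, truth)
    return Population(viruses=viruses, hosts=hosts, truth=truth, infection=infection, config=cfg)


def _relabel_realized_core(truth: SimulatedTruth, viruses: list[GenomeRecord]) -> None:
    """Core status is defined by realized universality: a gene family is core
    iff every simulated genome carries it, regardless of which pool it came
    from (terminal variable genes can drift into universality)."""
    present: dict[str, set[str]] = {}
    for orf_id, (label, _status) in truth.gene_labels.items():
        genome = orf_id.rsplit("_", 1)[0]
        present.setdefault(label, set()).add(genome)
    n = len(viruses)
    for orf_id, (label, _status) in list(truth.gene_labels.items()):
        status = "core" if len(present[label]) == n else "variable"
        truth.gene_labels[orf_id] = (label, status)


def _regional_newick(tips_by_region, rb, tb, cfg) -> str:
    parts = []
    for name, tips in tips_by_region.items():
        inner = ",".join(
            f"{t}:{tb * cfg.core_substitution_rate:.6f}" for t in tips
        )
        parts.append(f"({inner}):{rb * cfg.core_substitution_rate:.6f}")
    return f"({','.join(parts)});"


def _evolve_neutral(seq: str, p_sub: float, rng: np.random.Generator, gc: float) -> str:
    """Neutral per-base substitution (non-coding sequence), composition kept."""
    if p_sub <= 0:
        return seq
    arr = np.array(list(seq))
    n_sub = rng.binomial(arr.size, min(p_sub, 1.0))
    if n_sub == 0:
        return seq
    pos = rng.choice(arr.size, size=n_sub, replace=False)
    base_p = {b: (gc / 2 if b in "GC" else (1 - gc) / 2) for b in "ACGT"}
    for p in pos:
        others = [b for b in "ACGT" if b != arr[p]]
        w = np.array([base_p[b] for b in others])
        arr[p] = rng.choice(others, p=w / w.sum())
    return "".join(arr)


def _assemble_genome(vid, location, core_tip, var_tip, var_side, strands, gap_tip, cfg, rng, truth):
    left = [(f"var{k + 1:02d}", var_tip[k]) for k in sorted(var_tip) if var_side[k] == "L"]
    right = [(f"var{k + 1:02d}", var_tip[k]) for k in sorted(var_tip) if var_side[k] == "R"]
    core = [(f"core{k + 1:02d}", g) for k, g in enumerate(core_tip)]
    order = left + core + right
    total_gene = sum(len(g) for _, g in order)
    target = int(rng.normal(cfg.genome_length, cfg.genome_length_sd)) if cfg.genome_length_sd else cfg.genome_length
    n_gaps = len(order) + 1
    pad = target - total_gene
    if pad < 2 * n_gaps:
        raise ValueError(
            f"infeasible packing: {total_gene} bp of genes in a {target} bp genome"
        )
    gap_sizes = np.full(n_gaps, pad // n_gaps)
    gap_sizes[: pad % n_gaps] += 1
    if gap_sizes.max() > len(gap_tip["terminus"]):
        raise ValueError("intergenic gap exceeds ancestral gap pool length")
    parts = []
    features = []
    pos = 0
    for gi, (label, gene) in enumerate(order):
        gap = gap_tip[label][: int(gap_sizes[gi])]
        parts.append(gap)
        pos += len(gap)
        strand = strands[label]
        placed = gene if strand == "+" else revcomp(gene)
        parts.append(placed)
        orf_id = f"{vid}_{label}"
        features.append(FeatureRecord(orf_id, pos, pos + len(gene), strand, "CDS"))
        status = "core" if label.startswith("core") else "variable"
        truth.gene_labels[orf_id] = (label, status)
        pos += len(gene)
    parts.append(gap_tip["terminus"][: int(gap_sizes[-1])])
    genome = GenomeRecord(id=vid, sequence="".join(parts), location=location)
    for f in features:
        genome.add_feature(f)
    return genome


# ---------------------------------------------------------------------------
# hosts, arrays, spacers


def _virus_kmer_bank(viruses: list[GenomeRecord], k: int) -> set[str]:
    bank: set[str] = set()
    for v in viruses:
        for seq in (v.sequence, revcomp(v.sequence)):
            bank.update(seq[i : i + k] for i in range(len(seq) - k + 1))
    return bank


def _sample_decoy(rng, length, gc, bank, k, max_tries=1000) -> str:
    for _ in range(max_tries):
        s = _random_nt(rng, length, gc)
        if all(s[i : i + k] not in bank for i in range(length - k + 1)):
            return s
    raise RuntimeError("could not sample a decoy spacer disjoint from the viruses")


def _sample_protospacer(rng, virus: GenomeRecord, cfg, max_tries=5000):
    """Uniform protospacer whose flanking bases already satisfy the PAM."""
    L = cfg.spacer_length
    k = len(cfg.pam_motif)
    n = len(virus.sequence)
    for _ in range(max_tries):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(k, n - L - k + 1))
        if strand == "+":
            pam = virus.sequence[start - k : start]
        else:
            pam = revcomp(virus.sequence[start + L : start + L + k])
        if crispr.iupac_match(pam, cfg.pam_motif):
            proto = virus.sequence[start : start + L]
            if strand == "-":
                proto = revcomp(proto)
            return start, start + L, strand, proto, pam
    raise RuntimeError(f"no PAM-adjacent protospacer found in {virus.id}")


def _simulate_hosts(cfg, rng, viruses, truth, region_tags):
    bank = _virus_kmer_bank(viruses, cfg.match_word_size)
    by_region: dict[str, list[GenomeRecord]] = {}
    for v in viruses:
        by_region.setdefault(v.location, []).append(v)
    regions = [cfg.region_name(r) for r in range(cfg.n_regions)]
    hosts = []
    for r, name in enumerate(regions):
        tag = region_tags[r]
        for h in range(cfg.hosts_per_region):
            hid = f"HOST-{tag}{h + 1}"
            truth.region_of[hid] = name
            spacer_seqs = []
            for s_idx in range(cfg.spacers_per_host):
                sp_id = f"{hid}_s{s_idx + 1:02d}"
                if rng.random() < cfg.decoy_fraction:
                    seq = _sample_decoy(rng, cfg.spacer_length, cfg.gc_content, bank, cfg.match_word_size)
                    truth.spacers.append(
                        SpacerTruth(sp_id, hid, s_idx, seq, decoy=True)
                    )
                else:
                    local = rng.random() < cfg.local_spacer_fraction
                    pool = by_region[name] if local else [
                        v for v in viruses if v.location != name
                    ]
                    virus = pool[int(rng.integers(len(pool)))]
                    start, end, strand, proto, pam = _sample_protospacer(rng, virus, cfg)
                    q = cfg.spacer_divergence_local if local else cfg.spacer_divergence_foreign
                    seq, n_mut = _mutate_spacer(proto, q, rng)
                    truth.spacers.append(
                        SpacerTruth(
                            sp_id, hid, s_idx, seq, decoy=False,
                            source_virus=virus.id, start=start, end=end,
                            strand=strand, n_mutations=n_mut, pam=pam,
                        )
                    )
                spacer_seqs.append(seq)
            hosts.append(_build_host_genome(hid, name, spacer_seqs, cfg, rng))
    return hosts


def _build_host_genome(hid, location, spacer_seqs, cfg, rng):
    rep = cfg.repeat_sequence
    array = rep + "".join(s + rep for s in spacer_seqs)
    flank = cfg.host_genome_length - len(array)
    if flank < 200:
        raise ValueError("host_genome_length too small for the CRISPR array")
    left = int(rng.integers(100, flank - 100))
    reverse = rng.random() < 0.5
    placed = revcomp(array) if reverse else array
    seq = _random_nt(rng, left, cfg.gc_content) + placed + _random_nt(
        rng, flank - left, cfg.gc_content
    )
    genome = GenomeRecord(id=hid, sequence=seq, location=location)
    strand = "-" if reverse else "+"
    n_sp = len(spacer_seqs)
    for k in range(n_sp + 1):
        if reverse:
            # repeat k in crRNA order sits at the far end of the placed array
            off = len(array) - (k + 1) * len(rep) - k * cfg.spacer_length
        else:
            off = k * (len(rep) + cfg.spacer_length)
        genome.add_feature(
            FeatureRecord(f"{hid}_rep{k + 1}", left + off, left + off + len(rep), strand, "repeat")
        )
    for k in range(n_sp):
        if reverse:
            off = len(array) - (k + 1) * (len(rep) + cfg.spacer_length)
        else:
            off = (k + 1) * len(rep) + k * cfg.spacer_length
        genome.add_feature(
            FeatureRecord(f"{hid}_sp{k + 1}", left + off, left + off + cfg.spacer_length, strand, "spacer")
        )
    return genome


def _infection_from_truth(cfg, viruses, hosts, truth) -> InfectionMatrix:
    """Observed plaque outcomes derived from sequence-level protection.

    A host is protected against a virus iff at least one of its (true)
    spacers has an above-threshold identity window with a PAM in that virus —
    the same targeting rule the caller applies, evaluated on the planted
    spacer list. Protected pairs clear at no titer; unprotected pairs clear
    all replicates at every titer (no anti-CRISPR discordance is planted).
    """
    spacers_by_host: dict[str, list[crispr.Spacer]] = {}
    for st in truth.spacers:
        spacers_by_host.setdefault(st.host_id, []).append(
            crispr.Spacer(st.spacer_id, st.host_id, st.sequence, "truth", st.array_index)
        )
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for h in hosts:
        counts[h.id] = {}
        for v in viruses:
            immune = crispr.predicted_immune(
                spacers_by_host.get(h.id, []),
                v,
                id_threshold=cfg.id_threshold,
                pam_motif=cfg.pam_motif,
                word_size=cfg.match_word_size,
            )
            truth.immunity[(h.id, v.id)] = immune
            c = 0 if immune else 3
            counts[h.id][v.id] = {"high": c, "medium": c, "low": c}
    return InfectionMatrix(
        hosts=[h.id for h in hosts], viruses=[v.id for v in viruses], counts=counts
    )


# ---------------------------------------------------------------------------
# fixture emission


def emit_fixture(population: Population, out_dir: str | Path) -> dict[str, Path]:
    """Write the population as FASTA/GFF/TSV files loadable by the io layer."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "viruses": out / "viruses.fasta",
        "hosts": out / "hosts.fasta",
        "features": out / "features.gff",
        "virus_features": out / "viruses.gff",
        "host_features": out / "hosts.gff",
        "samples": out / "samples.tsv",
        "infection": out / "infection.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_spacers": out / "truth_spacers.tsv",
        "truth_immunity": out / "truth_immunity.tsv",
        "tree": out / "truth_tree.nwk",
        "config": out / "config.json",
    }
    pop = population
    write_fasta(pop.viruses, paths["viruses"])
    write_fasta(pop.hosts, paths["hosts"])
    write_gff(pop.viruses + pop.hosts, paths["features"])
    write_gff(pop.viruses, paths["virus_features"])
    write_gff(pop.hosts, paths["host_features"])
    samples = pd.DataFrame(
        [
            {"id": g.id, "location": g.location, "region": g.location, "role": role}
            for role, group in (("virus", pop.viruses), ("host", pop.hosts))
            for g in group
        ]
    )
    samples.to_csv(paths["samples"], sep="\t", index=False)
    write_infection_matrix(pop.infection, paths["infection"])
    pd.DataFrame(
        [
            {"orf_id": o, "cluster_truth": c, "status": s}
            for o, (c, s) in sorted(pop.truth.gene_labels.items())
        ]
    ).to_csv(paths["truth_genes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "spacer_id": st.spacer_id,
                "host_id": st.host_id,
                "array_index": st.array_index,
                "sequence": st.sequence,
                "decoy": int(st.decoy),
                "source_virus": st.source_virus,
                "start": st.start + 1 if not st.decoy else "",
                "end": st.end if not st.decoy else "",
                "strand": st.strand,
                "n_mutations": st.n_mutations if not st.decoy else "",
                "pam": st.pam,
            }
            for st in pop.truth.spacers
        ]
    ).to_csv(paths["truth_spacers"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"host": h, "virus": v, "immune": int(i)}
            for (h, v), i in sorted(pop.truth.immunity.items())
        ]
    ).to_csv(paths["truth_immunity"], sep="\t", index=False)
    paths["tree"].write_text(pop.truth.tree_newick + "\n")
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(pop.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
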