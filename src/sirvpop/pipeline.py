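"""End-to-end pipeline: clustering -> selection/trees -> CRISPR -> biogeography.

Stages run in a fixed order with per-stage logging; any stage failure aborts
with the stage name. A demo mode generates a synthetic population first and
scores the pipeline output against the simulated truth.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biogeo, crispr, molevo, pangenome
from .io import (
    GenomeRecord,
    InfectionMatrix,
    apply_sample_sheet,
    read_fasta,
    read_gff,
    read_infection_matrix,
    read_sample_sheet,
    write_tables,
)
from .pangenome import AlignmentParams
from .simulate import Population, SimulationConfig, emit_fixture, simulate_population

log = logging.getLogger("sirvpop")


@dataclass
class PipelineConfig:
    """All tunable settings of the pipeline, serializable to JSON."""

    ratio_threshold: float = 0.3
    inflation: float = 2.0
    id_threshold: float = 0.5
    pam_motif: str = "CCN"
    pam_side: str = "5prime"
    seed_length: int = 8
    word_size: int = 12
    min_pnps_members: int = 5
    require_pam: bool = True
    do_rescue: bool = True
    reference_repeat: str | None = None
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("ratio_threshold", "id_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")


@dataclass
class PipelineResult:
    clusters: list[pangenome.GeneCluster]
    presence: pd.DataFrame
    presence_pre_rescue: pd.DataFrame
    core_stats: pd.DataFrame
    pnps: pd.DataFrame
    tree_newick: str
    distance_ids: list[str]
    spacers: list[crispr.Spacer]
    matches: list[crispr.SpacerMatch]
    immunity: list[crispr.ImmunityCall]
    fractions: pd.DataFrame
    fractions_by_virus: pd.DataFrame
    identity_hist: pd.DataFrame
    partition: biogeo.RegionPartition
    metrics: dict[str, float]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc
            log.info("stage %-18s %6.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("cluster")
def _run_clustering(viruses, cfg: PipelineConfig):
    orf_index: dict[str, pangenome.ORFRecord] = {}
    flagged_all = []
    for g in viruses:
        orfs, flagged = pangenome.extract_orfs(g)
        flagged_all.extend(flagged)
        for o in orfs:
            orf_index[o.orf_id] = o
    orfs = list(orf_index.values())
    edges = pangenome.build_similarity_graph(orfs, cfg.alignment, cfg.ratio_threshold)
    member_sets, converged = pangenome.mcl_cluster(
        edges, [o.orf_id for o in orfs], inflation=cfg.inflation
    )
    if not converged:
        log.warning("MCL did not converge within the iteration budget")
    clusters = pangenome.make_clusters(member_sets, orf_index)
    return orf_index, clusters, flagged_all


@_stage("partition")
def _run_partition(clusters, viruses, orf_index, cfg: PipelineConfig):
    genome_ids = [g.id for g in viruses]
    pre = pangenome.presence_absence(clusters, genome_ids)
    post = (
        pangenome.rescue_missed_orfs(
            clusters, viruses, orf_index, cfg.alignment, cfg.ratio_threshold, matrix=pre
        )
        if cfg.do_rescue
        else pre
    )
    clusters, core_stats = pangenome.partition_core_variable(clusters, genome_ids, post)
    return clusters, pre, post, core_stats


@_stage("molevo")
def _run_molevo(clusters, orf_index, viruses, cfg: PipelineConfig):
    by_id = {g.id: g for g in viruses}
    alignments = []
    pnps_rows = []
    for c in clusters:
        if len(c.members) < 2:
            continue
        cds = {m: by_id[orf_index[m].genome_id].feature_seq(orf_index[m].feature) for m in c.members}
        aln = molevo.align_codons(cds, cluster_id=c.cluster_id)
        alignments.append((c, aln))
        if len(c.members) >= cfg.min_pnps_members:
            r = molevo.cluster_pnps(aln, min_members=cfg.min_pnps_members)
            pnps_rows.append(
                {
                    "cluster": c.cluster_id,
                    "status": c.status,
                    "n_members": len(c.members),
                    "S": r.S,
                    "N": r.N,
                    "Sd": r.Sd,
                    "Nd": r.Nd,
                    "ps": r.ps,
                    "pn": r.pn,
                    "pnps": r.ratio,
                    "undefined": int(r.undefined),
                }
            )
    pnps = pd.DataFrame(pnps_rows)
    member_to_genome = {m: orf_index[m].genome_id for m in orf_index}
    core_alns = [a for c, a in alignments if c.status == "core"]
    tree = ""
    ids: list[str] = []
    if core_alns:
        concat = molevo.concatenate_alignments(core_alns, member_to_genome)
        if len(concat.rows) >= 3:
            dm = molevo.jc_matrix(concat.rows)
            tree = molevo.nj_tree(dm)
            ids = dm.ids
    return pnps, tree, ids


@_stage("crispr")
def _run_crispr(hosts, viruses, infection: InfectionMatrix | None, cfg: PipelineConfig):
    reference = cfg.reference_repeat
    spacers: list[crispr.Spacer] = []
    array_rows = []
    for h in hosts:
        for arr in crispr.detect_arrays(h):
            sps = crispr.orient_spacers(arr, h, reference_repeat=reference)
            spacers.extend(sps)
            array_rows.append(
                {
                    "host": h.id,
                    "start": arr.start + 1,
                    "end": arr.end,
                    "n_repeats": len(arr.repeats),
                    "n_spacers": len(arr.spacers),
                    "orientation": arr.orientation,
                    "repeat_consensus": arr.repeat_consensus,
                }
            )
    matches: list[crispr.SpacerMatch] = []
    for sp in spacers:
        for v in viruses:
            matches.extend(
                crispr.match_spacer(
                    sp,
                    v,
                    report_threshold=cfg.id_threshold,
                    seed_length=cfg.seed_length,
                    pam_motif=cfg.pam_motif,
                    pam_side=cfg.pam_side,
                    word_size=cfg.word_size,
                )
            )
    by_pair: dict[tuple[str, str], list[crispr.SpacerMatch]] = {}
    host_of = {s.spacer_id: s.host_id for s in spacers}
    for m in matches:
        by_pair.setdefault((host_of[m.spacer_id], m.virus_id), []).append(m)
    calls = []
    for h in hosts:
        for v in viruses:
            observed = None
            if infection is not None and h.id in infection.counts:
                observed = infection.counts[h.id].get(v.id)
            calls.append(
                crispr.call_immunity(
                    h.id,
                    v.id,
                    by_pair.get((h.id, v.id), []),
                    observed=observed,
                    id_threshold=cfg.id_threshold,
                    require_pam=cfg.require_pam,
                )
            )
    return spacers, matches, calls, pd.DataFrame(array_rows)


@_stage("biogeo")
def _run_biogeo(spacers, matches, samples, viruses, clusters, orf_index, cfg: PipelineConfig):
    per_loc, per_loc_virus = biogeo.match_fractions(spacers, matches, samples, cfg.id_threshold)
    hist = biogeo.identity_distribution(matches, spacers, samples, cfg.id_threshold)
    orf_status = {}
    for c in clusters:
        for m in c.members:
            orf_status[m] = c.status
    part = biogeo.region_partition(matches, viruses, orf_status, cfg.id_threshold)
    return per_loc, per_loc_virus, hist, part


def run_pipeline(
    viruses: list[GenomeRecord],
    hosts: list[GenomeRecord],
    samples: pd.DataFrame,
    cfg: PipelineConfig,
    infection: InfectionMatrix | None = None,
    population: Population | None = None,
) -> PipelineResult:
    """Run every stage on loaded inputs; returns tables and summary metrics."""
    orf_index, clusters, flagged = _run_clustering(viruses, cfg)
    clusters, pre, post, core_stats = _run_partition(clusters, viruses, orf_index, cfg)
    pnps, tree, dist_ids = _run_molevo(clusters, orf_index, viruses, cfg)
    spacers, matches, calls, arrays_df = _run_crispr(hosts, viruses, infection, cfg)
    per_loc, per_loc_virus, hist, part = _run_biogeo(
        spacers, matches, samples, viruses, clusters, orf_index, cfg
    )

    metrics = _summary_metrics(
        viruses, clusters, pnps, tree, spacers, matches, calls, population
    )
    tables = {
        "clusters": pd.DataFrame(
            [
                {
                    "orf_id": m,
                    "genome": orf_index[m].genome_id,
                    "cluster": c.cluster_id,
                    "status": c.status,
                }
                for c in clusters
                for m in c.members
            ]
        ),
        "presence_absence": post.reset_index(),
        "presence_absence_pre_rescue": pre.reset_index(),
        "core_stats": core_stats,
        "pnps": pnps,
        "arrays": arrays_df,
        "matches": pd.DataFrame(
            [
                {
                    "spacer_id": m.spacer_id,
                    "virus": m.virus_id,
                    "start": m.start + 1,
                    "end": m.end,
                    "strand": m.strand,
                    "full_identity": m.full_identity,
                    "half5_identity": m.half5_identity,
                    "seed_identity": m.seed_identity,
                    "pam_present": int(m.pam_present),
                    "pam_sequence": m.pam_sequence,
                }
                for m in matches
            ]
        ),
        "immunity": pd.DataFrame(
            [
                {
                    "host": c.host_id,
                    "virus": c.virus_id,
                    "n_matches_with_pam": c.n_matches_with_pam,
                    "n_matches_no_pam": c.n_matches_no_pam,
                    "n_spacers_with_pam": c.n_spacers_with_pam,
                    "best_full_identity": c.best_full_identity,
                    "predicted": c.predicted,
                    "discordance": c.discordance,
                }
                for c in calls
            ]
        ),
        "fractions": per_loc,
        "fractions_by_virus": per_loc_virus,
        "identity_hist": hist,
        "region_partition": part.per_virus,
        "region_summary": part.summary,
        "metrics": pd.DataFrame([metrics]),
    }
    return PipelineResult(
        clusters=clusters,
        presence=post,
        presence_pre_rescue=pre,
        core_stats=core_stats,
        pnps=pnps,
        tree_newick=tree,
        distance_ids=dist_ids,
        spacers=spacers,
        matches=matches,
        immunity=calls,
        fractions=per_loc,
        fractions_by_virus=per_loc_virus,
        identity_hist=hist,
        partition=part,
        metrics=metrics,
        tables=tables,
    )


def _summary_metrics(viruses, clusters, pnps, tree, spacers, matches, calls, population):
    metrics: dict[str, float] = {}
    lengths = [len(v) for v in viruses]
    gc = [
        (v.sequence.count("G") + v.sequence.count("C")) / len(v) for v in viruses
    ]
    metrics["n_viruses"] = len(viruses)
    metrics["mean_genome_length"] = float(np.mean(lengths))
    metrics["mean_gc_percent"] = float(100 * np.mean(gc))
    metrics["n_clusters_total"] = len(clusters)
    metrics["n_core_clusters"] = sum(c.status == "core" for c in clusters)
    if len(pnps):
        core = pnps[(pnps["status"] == "core") & (pnps["undefined"] == 0)]
        if len(core):
            metrics["frac_core_pnps_lt1"] = float((core["pnps"] < 1).mean())
    metrics["n_spacers"] = len(spacers)
    metrics["n_matches_reported"] = len(matches)
    if population is not None:
        metrics.update(_truth_metrics(clusters, tree, spacers, matches, calls, population))
    return metrics


def _truth_metrics(clusters, tree, spacers, matches, calls, population: Population):
    from sklearn.metrics import adjusted_rand_score

    truth = population.truth
    out: dict[str, float] = {}
    pred, true = [], []
    for c in clusters:
        for m in c.members:
            if m in truth.gene_labels:
                pred.append(c.cluster_id)
                true.append(truth.gene_labels[m][0])
    if pred:
        out["cluster_ari"] = float(adjusted_rand_score(true, pred))
    truth_core = {lab for lab, st in truth.gene_labels.values() if st == "core"}
    out["n_core_clusters_truth"] = float(len(truth_core))
    if tree:
        regions: dict[str, set[str]] = {}
        for v in population.viruses:
            regions.setdefault(v.location, set()).add(v.id)
        out["same_region_monophyly"] = float(
            all(molevo.is_monophyletic(tree, taxa) for taxa in regions.values())
        )
    # identity recovery: best full-identity of each non-decoy spacer vs its source
    best: dict[tuple[str, str], float] = {}
    for m in matches:
        key = (m.spacer_id, m.virus_id)
        best[key] = max(best.get(key, 0.0), m.full_identity)
    det_by_host: dict[str, list] = {}
    for s in spacers:
        det_by_host.setdefault(s.host_id, []).append(s)
    local_ids, foreign_ids = [], []
    matched_truth = 0
    n_truth = 0
    for st in truth.spacers:
        if st.decoy:
            continue
        n_truth += 1
        cands = [
            s for s in det_by_host.get(st.host_id, []) if s.sequence == st.sequence
        ]
        if not cands:
            continue
        matched_truth += 1
        b = max((best.get((s.spacer_id, st.source_virus), 0.0) for s in cands), default=0.0)
        local = truth.region_of[st.host_id] == truth.region_of[st.source_virus]
        (local_ids if local else foreign_ids).append(b)
    out["spacer_recovery"] = matched_truth / n_truth if n_truth else 0.0
    if local_ids:
        out["mean_identity_local_pct"] = float(100 * np.mean(local_ids))
    if foreign_ids:
        out["mean_identity_foreign_pct"] = float(100 * np.mean(foreign_ids))
    concordant = [c for c in calls if c.discordance]
    if concordant:
        out["immunity_concordance"] = float(
            np.mean([c.discordance == "concordant" for c in concordant])
        )
    return out


def run_demo(
    seed: int = 0,
    out_dir: str | Path | None = None,
    sim_config: SimulationConfig | None = None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Simulate a population and run the full pipeline against it."""
    cfg = cfg or PipelineConfig()
    sim = sim_config or cfg.simulation
    sim = dataclasses.replace(sim, seed=seed)
    cfg = dataclasses.replace(
        cfg,
        simulation=sim,
        pam_motif=sim.pam_motif,
        reference_repeat=sim.repeat_sequence,
        id_threshold=sim.id_threshold,
        word_size=sim.match_word_size,
    )
    population = simulate_population(sim)
    samples = pd.DataFrame(
        [
            {"id": g.id, "location": g.location}
            for g in population.viruses + population.hosts
        ]
    )
    result = run_pipeline(
        population.viruses,
        population.hosts,
        samples,
        cfg,
        infection=population.infection,
        population=population,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        emit_fixture(population, out_dir / "fixture")
        write_tables(result.tables, out_dir, config=cfg, seed=seed)
        (out_dir / "core_tree.nwk").write_text(result.tree_newick + "\n")
    return result


def run_from_files(
    genomes_fasta: str | Path,
    features_gff: str | Path,
    sample_sheet: str | Path,
    cfg: PipelineConfig,
    hosts_fasta: str | Path | None = None,
    infection_tsv: str | Path | None = None,
    out_dir: str | Path | None = None,
    fallback_orfs: bool = False,
) -> PipelineResult:
    """Run the pipeline on user-supplied files."""
    viruses = read_fasta(genomes_fasta)
    hosts = read_fasta(hosts_fasta) if hosts_fasta else []
    read_gff(features_gff, viruses + hosts)
    if fallback_orfs:
        for g in viruses:
            if not any(f.kind == "CDS" for f in g.features):
                log.info("no CDS features for %s; using naive ORF caller", g.id)
                for f in pangenome.find_orfs_naive(g):
                    g.add_feature(f)
    samples = read_sample_sheet(sample_sheet)
    apply_sample_sheet(viruses + hosts, samples)
    infection = read_infection_matrix(infection_tsv) if infection_tsv else None
    result = run_pipeline(viruses, hosts, samples, cfg, infection=infection)
    if out_dir is not None:
        write_tables(
            result.tables,
            out_dir,
            config=cfg,
            input_paths=[p for p in (genomes_fasta, features_gff, sample_sheet) if p],
        )
        if result.tree_newick:
            (Path(out_dir) / "core_tree.nwk").write_text(result.tree_newick + "\n")
    return result
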