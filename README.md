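# sirvpop

Comparative genomics and CRISPR spacer biogeography for natural populations
of *Sulfolobus islandicus* rod-shaped viruses (SIRVs) — lytic rudiviruses
with ~35 kb linear, AT-rich (~26% G+C) dsDNA genomes isolated from hot
springs. The package is for virus ecologists and comparative genomicists who
want a reproducible, tested version of the analysis chain that turns a set
of virus genomes, host genomes and plaque assays into a pangenome, selection
statistics, and host–virus interaction predictions.

## What it computes

- **Pangenome.** ORFs are compared all-against-all by exact Smith–Waterman
  (BLOSUM62, affine gaps 11/1); raw scores become bits,
  `bits = (λS − ln K)/ln 2`, and pairs are kept when the bit-score ratio
  `bits(a,b)/min(bits(a,a), bits(b,b)) ≥ 0.3`. The graph is clustered by
  Markov clustering (inflation 2.0); absent cluster × genome cells are
  rescued by TBLASTN-style search of member proteins against six translated
  frames; clusters present in every genome are **core**, the rest
  **variable**.
- **Selection.** Within clusters of ≥ 5 members, Nei–Gojobori
  proportion-counting Pn/Ps (SNAP-style pathway averaging, stop-excluded),
  pooled over member pairs: `(ΣNd/ΣN)/(ΣSd/ΣS)`; Pn/Ps < 1 indicates
  purifying selection.
- **Phylogeny.** Jukes–Cantor distances `d = −(3/4) ln(1 − 4p/3)` on the
  concatenated core alignment after alignment-wide complete deletion, and a
  neighbor-joining tree.
- **CRISPR.** Repeat-spacer arrays detected by seed-and-extend, spacers
  oriented by their flanking repeat, then matched ungapped against virus
  genomes on both strands: whole-spacer, 5′-half and seed (8 nt,
  PAM-proximal) identities per window, with the protospacer-adjacent motif
  (default CCN, 5′ of the protospacer) checked per hit. Matches count when
  identity is strictly above 50% and the window shares an exact 12-mer with
  the spacer.
- **Immunity & biogeography.** A host is predicted immune to a virus iff
  some spacer has a qualifying match with a PAM; predictions are reconciled
  with plaque outcomes at three titers (anti-CRISPR and resistance
  candidates flagged). Matches aggregate into per-location match fractions,
  identity histograms, and the partition of matches over
  core / variable / non-coding sequence.

A bundled simulator generates two-region virus populations and host CRISPR
arrays with a full ground-truth ledger, so the entire pipeline is testable
without downloads. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
from sirvpop import SimulationConfig, run_demo

cfg = SimulationConfig(
    seed=7, viruses_per_region=3, hosts_per_region=2, spacers_per_host=12,
    genome_length=12000, genome_length_sd=400, n_core_genes=8,
    n_variable_pool=16, host_genome_length=5000,
)
result = run_demo(seed=7, sim_config=cfg)
m = result.metrics
print(f"gene clusters: {m['n_clusters_total']:.0f} total, {m['n_core_clusters']:.0f} core")
print(f"cluster ARI vs truth: {m['cluster_ari']:.2f}")
print(f"core Pn/Ps < 1: {m['frac_core_pnps_lt1']:.0%} of clusters")
print(f"same-region monophyly: {bool(m['same_region_monophyly'])}")
print(f"spacer identity, local {m['mean_identity_local_pct']:.1f}% vs foreign {m['mean_identity_foreign_pct']:.1f}%")
print(f"immunity concordance: {m['immunity_concordance']:.0%}")
```

prints

```
gene clusters: 18 total, 9 core
cluster ARI vs truth: 1.00
core Pn/Ps < 1: 100% of clusters
same-region monophyly: True
spacer identity, local 95.7% vs foreign 8.7%
immunity concordance: 100%
```

Reading: on this six-virus population the clustering reproduces the
simulated gene families exactly (adjusted Rand index 1.0) and labels the
universal ones core; every core cluster shows Pn/Ps below 1, matching the
purifying selection the simulator applied (ω = 0.2); the core-genome
neighbor-joining tree places each region's viruses in their own clade;
spacers match their local viruses at far higher identity than foreign ones
(the biogeographic signal); and every immunity prediction agrees with the
simulated plaque outcome.

The same pipeline runs from the shell:

```sh
sirvpop run --demo --seed 7 --out results/demo/          # synthetic end-to-end
sirvpop run --genomes sirv.fasta --features sirv.gff \
            --samples samples.tsv --hosts hosts.fasta \
            --infection infection.tsv --out results/real/
sirvpop cluster --genomes sirv.fasta --features sirv.gff --out results/pan/
sirvpop crispr-detect --host hosts.fasta --repeat <species-repeat> --out results/arrays/
```

Outputs are deterministic TSV/JSON tables plus a run manifest (config, seed,
input checksums); coordinates in emitted tables are 1-based inclusive.

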