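# Methods

`sirvpop` reimplements, as a tested pipeline, the comparative-genomics and
CRISPR-interaction analysis of a natural population of *Sulfolobus
islandicus* rod-shaped viruses (SIRVs): homologous gene clustering and the
core/variable pangenome partition, within-cluster selection and distance
statistics, CRISPR spacer detection and protospacer matching, immunity
prediction against plaque assays, and biogeographic summaries. This note
records the models, the numerical choices, and what the bundled simulator
does and does not emulate.

## Pangenome construction

ORFs are taken from CDS annotations (GFF3); a naive fallback caller (longest
ORF of at least 60 codons per stop-to-stop segment, ATG/GTG/TTG starts)
exists for FASTA-only input but annotation-driven extraction is the intended
path, since it makes cluster counts well defined.

All-against-all protein similarity uses exact Smith–Waterman local alignment
with BLOSUM62 and affine gaps in the BLAST convention (a gap of length k
costs 11 + k). Raw scores S become bits via the Karlin–Altschul form
`(λS − ln K)/ln 2` with the standard gapped BLOSUM62 11/1 constants
λ = 0.267, K = 0.041 (overridable; the constants largely cancel in the
ratio). Each unordered pair is screened by the bit-score ratio
`bits(a,b) / min(self_bits(a), self_bits(b))`, the usual length-normalized
score ratio in [0, 1]; pairs at ratio ≥ 0.3 become edges. The ambiguous
residue X scores 0 against everything. Pairs sharing no protein 4-mer are
skipped before alignment — at this threshold such pairs cannot produce an
edge, and the screen dominates cluster membership; the prefilter can be
disabled in `AlignmentParams`.

The weighted graph is clustered by Markov clustering: self-loops set to each
node's maximum incident weight, column-stochastic normalization, then
repeated expansion (matrix squaring) and inflation (elementwise power 2.0,
renormalization) with pruning below 1e-8, until the maximum entry change
falls below 1e-6 or 100 iterations. Clusters are the connected components of
the attractor matrix; isolated ORFs become singletons. Cluster ids c1…cN are
assigned by descending size, then lexicographically smallest member.
OrthoMCL's e-value normalization and best-hit preprocessing are deliberately
not replicated — the ratio screen determines membership here.

Missed or miscalled ORFs are rescued TBLASTN-style: for every
cluster × genome cell still absent, member proteins (longest first) are
aligned against all six translated frames of that genome; a hit whose
bits/self-bits reaches the same 0.3 threshold marks the cell
"present_no_start". A cluster is core iff no genome is absent after rescue.

## Selection and phylogeny

Cluster members are translation-aligned with a star strategy: each protein
is globally aligned (same scoring) to the longest member and gaps are merged
under "once a gap, always a gap", then every protein gap expands to a codon
triplet gap, so ungapping any row returns its CDS exactly. This replaces a
full progressive MSA; it is exact for the indel-free genes the simulator
produces and adequate for closely related natural clusters.

Pn/Ps follows Nei–Gojobori (1986) proportion counting as SNAP implements
it. Potential synonymous sites per codon are the per-position fractions of
the three possible changes that preserve the amino acid; changes creating
stops count as nonsynonymous, so sites always total 3 per codon. Observed
differences average over all equally weighted orderings of single-step
pathways, excluding pathways through stop codons; codon pairs whose pathways
are all excluded, or that contain gaps or N, are skipped pairwise. The
cluster-level ratio pools counts over all unordered member pairs,
`(ΣNd/ΣN) / (ΣSd/ΣS)`, rather than averaging per-pair ratios — near-identical
pairs would otherwise contribute unstable ratios. Clusters are summarized
when they have at least five members (configurable). Ps = 0 flags the result
undefined.

Nucleotide distances use the Jukes–Cantor model, `d = −(3/4) ln(1 − 4p/3)`,
after complete deletion applied alignment-wide (every column containing a
gap or N in any row is removed before any pair is compared); p ≥ 0.75 is
reported as a saturated (infinite) distance. Trees are built by neighbor
joining on the concatenated single-copy core alignment, with negative branch
lengths clamped to zero and taxa processed in sorted order for deterministic
tie-breaks. NJ stands in for maximum likelihood because the claims exercised
here (geographic monophyly) are topology-level; no bootstrap is computed.

## CRISPR detection and matching

Arrays are found by a CRT-style seed-and-extend scan: an exact 13-mer that
recurs at a spacing compatible with one repeat plus one spacer
(repeat 23–47 nt, spacer 17–50 nt) anchors a chain of repeat candidates,
whose boundaries extend while the column majority across copies stays at
80% or better. At least three repeats are required; the consensus is the
column majority. Spacers are oriented by comparing the consensus against a
reference repeat and its reverse complement (best sliding-offset Hamming
distance, up to 6 nt length slack); ties mark the array ambiguous and emit
both orientations.

Spacer-to-virus matching is ungapped: identity is computed for every window
of spacer length on both strands (vectorized byte comparison; N never
matches). A window is reported when identity strictly exceeds 50% **and**
the window contains an exact matching run of at least 12 bases — the anchor
any seeded search needs to find a hit at all. Without the word requirement,
26% G+C sequence produces chance identities above 50% essentially
everywhere, and the word is what guarantees decoy spacers (constructed to
share no 12-mer with any virus) can never match. Overlapping qualifying
windows collapse to the local identity maximum. On each reported window the
5′-half identity (ceil(L/2) bases from the crRNA 5′ end) and seed identity
(8 PAM-proximal bases, the Type I convention) are computed, and the PAM —
default CCN, read 5′ of the protospacer on the protospacer strand, all
configurable — is checked against its IUPAC motif.

A host is predicted immune to a virus iff at least one match exceeds the
identity threshold and carries a PAM (the PAM requirement is relaxable);
per-spacer and per-site match counts are both reported so alternative rules
can be applied downstream. Against observed plaque outcomes, a
predicted-immune host cleared even at low titer is an anti-CRISPR candidate;
a predicted-susceptible host with no clearing at high titer is a resistance
candidate.

## Biogeography

Match fractions use per-spacer denominators (a spacer counts once if any
reported match to any virus exceeds the threshold), per location and per
location × virus; identity histograms bin reported matches in 5-point bins
with 100% folded into the top bin. The region partition uses per-site
denominators: every base of a virus is exactly one of core gene, variable
gene (core wins overlaps) or non-coding; each reported match is assigned to
the category holding the majority of its protospacer bases (ties resolve
core > variable > non-coding), and bp coverage is the union of reported
windows within each category. Percentages are rounded half-up to one
decimal. Summary dispersions are means ± SD across viruses, and are labelled
as such.

## The synthetic population

The simulator generates the structure the analysis assumes, with a
ground-truth ledger for every gene and spacer:

- **Genomes.** Ten linear genomes by default (five per region, two regions
  named "Nymph Lake" and "Iceland"), length 35,000 ± 1,200 bp, 26.5% G+C.
  The codon sampler is calibrated so that sense codons (stop codons
  rejected) hit the target composition. Thirty core genes of 100–230 codons
  form a syntenic central block; a pool of 64 variable genes occupies two
  terminal zones, each present in a region's ancestor with probability 0.35
  and flipped per tip with probability 0.05, giving 45–60 ORFs per genome
  with core genes 50–60% of them. Intergenic sequence has its own ancestry,
  keyed by the downstream gene, and evolves neutrally.
- **Evolution.** A two-level tree: 60% of root-to-tip divergence on the
  shared regional branch, 40% on each tip branch; core genes at 0.05
  expected substitutions/site root-to-tip, variable genes at 0.10. Genes
  evolve by drawing a binomial number of substitutions per branch and
  accepting nonsynonymous proposals with probability ω (0.2 core,
  0.3 variable); stop-creating changes are rejected and replacements are
  proposed from the genome's base composition so G+C does not drift. This is
  a deliberately simple scheme — enough to make the realized substitution
  rate match its binomial expectation and Pn/Ps recover below 1 — not a full
  codon model. No recombination and no within-gene indels are simulated, so
  gapless cluster alignments and clean regional monophyly are expected by
  construction; real SIRV data contain recombination the simulator does not
  emulate, and passing these tests says nothing about recombination
  robustness.
- **Hosts and spacers.** Three hosts per region, 12 kb each, carrying one
  array of 30 spacers (39 nt) between 25-nt repeats, inserted on a random
  strand. 90% of spacers copy a protospacer from a virus (80% local-region,
  20% foreign), sampled at positions whose flanking bases already satisfy
  the PAM, then mutated per-base at 0.05 (local) or 0.25 (foreign) — the
  local-vs-foreign identity contrast in the real data is imposed through
  these divergences. 10% are decoys rejection-sampled to share no 12-mer
  with any virus. The observed infection matrix is derived from
  sequence-level protection: a host clears nothing if any of its true
  spacers has a qualifying (identity + PAM) hit in the virus, and clears all
  replicates at every titer otherwise; no anti-CRISPR discordance is
  planted, so concordant immunity calls are the expected outcome and the
  concordance check validates the detection → orientation → matching →
  calling chain, not an epidemiological claim.

Defaults were fixed once to mirror the study conditions (genome size, G+C,
ORF counts, core count, spacer counts, two regions) and, where no condition
is stated, to values giving clear test signal at desk scale; they are not
fitted quantities.

## Problem sizes and runtime

The test suite runs a reduced population (6 viruses of 12 kb, 8 core genes,
16-gene pool, 4 hosts with 12 spacers) so the whole suite completes in a few
minutes; `scripts/acceptance.py` runs the full default population
(10 × 35 kb, 30 core, 64 pool, 180 spacers), which takes a few minutes,
dominated by the all-vs-all alignment and the six-frame rescue. The
selection-recovery figure simulates 100 independent five-member clusters at
ω = 0.2.

## Known limitations

- MCL here is plain Markov clustering on the ratio-screened graph; exact
  agreement with OrthoMCL output is not claimed.
- The star codon aligner does not optimize a sum-of-pairs objective; for
  deeply diverged clusters with indels a progressive MSA would be better.
- Array detection assumes consecutive repeats share an exact 13-mer seed;
  heavily degenerate repeats would need a tolerant seed.
- The exact PAM motif and seed length of the original matching tool are not
  published; CCN and 8 nt are conventions, recorded in every run manifest,
  and configurable.
- Real-data reproduction (the deposited GenBank accessions) requires the
  user to download genomes and annotations; the library itself never
  fetches from the network.
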