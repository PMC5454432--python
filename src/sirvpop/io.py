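"""Readers and writers for every external format the pipeline touches.

Internal convention: all coordinates are 0-based half-open. GFF3 and every
emitted coordinate table use 1-based inclusive coordinates; the conversion
happens here and nowhere else.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

FLOAT_FMT = "%.6f"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FeatureRecord:
    """One genomic feature on a 0-based half-open interval."""

    feature_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"  # CDS | repeat | spacer | other

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with geography metadata and features."""

    id: str
    sequence: str
    location: str = ""
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feat: FeatureRecord) -> str:
        """Feature sequence in reading orientation (revcomp for minus strand)."""
        sub = self.sequence[feat.start : feat.end]
        return revcomp(sub) if feat.strand == "-" else sub

    def add_feature(self, feat: FeatureRecord) -> None:
        if feat.end > len(self.sequence):
            raise ValueError(
                f"feature {feat.feature_id} ends at {feat.end} beyond genome "
                f"{self.id} of length {len(self.sequence)}"
            )
        self.features.append(feat)


@dataclass
class InfectionMatrix:
    """Plaque-assay outcomes: replicate clearing counts per host x virus x titer.

    ``counts[host][virus]`` maps titer level ("high" > "medium" > "low") to the
    number of replicates (0-3) that formed a zone of clearing.
    """

    hosts: list[str]
    viruses: list[str]
    counts: dict[str, dict[str, dict[str, int]]]

    TITERS = ("high", "medium", "low")

    def get(self, host: str, virus: str) -> dict[str, int]:
        return self.counts[host][virus]

    def validate(self) -> None:
        for h in self.hosts:
            for v in self.viruses:
                for t in self.TITERS:
                    c = self.counts[h][v][t]
                    if c not in (0, 1, 2, 3):
                        raise ValueError(f"count {c} out of range for {h}x{v} {t}")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    Sequences are uppercased and U is mapped to T. Duplicate ids and empty
    files are errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_protein_fasta(proteins: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff(path: str | Path, genomes: list[GenomeRecord]) -> list[GenomeRecord]:
    """Attach GFF3 features (1-based inclusive) to genomes as 0-based half-open.

    Features referencing unknown sequence ids, inverted or out-of-bounds
    intervals are rejected.
    """
    by_id = {g.id: g for g in genomes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts[:9]
            if seqid not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown sequence id {seqid!r}")
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end {end1} < start {start1}")
            fid = _gff_attr(attrs, "ID") or f"{seqid}_feat{lineno}"
            kind = ftype if ftype in ("CDS", "repeat", "spacer") else "other"
            feat = FeatureRecord(
                feature_id=fid, start=start1 - 1, end=end1, strand=strand, kind=kind
            )
            by_id[seqid].add_feature(feat)
    return genomes


def _gff_attr(attrs: str, key: str) -> str | None:
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith(key + "="):
            return kv[len(key) + 1 :]
    return None


def write_gff(genomes: Iterable[GenomeRecord], path: str | Path, source: str = "sirvpop") -> None:
    """Write features back out as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            for feat in g.features:
                ftype = feat.kind if feat.kind != "other" else "region"
                fh.write(
                    "\t".join(
                        [
                            g.id,
                            source,
                            ftype,
                            str(feat.start + 1),
                            str(feat.end),
                            ".",
                            feat.strand,
                            "0" if feat.kind == "CDS" else ".",
                            f"ID={feat.feature_id}",
                        ]
                    )
                    + "\n"
                )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV mapping sequence ids to geography.

    Required columns: id, location. Optional: region, spring, role.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "location"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup}")
    return df


def apply_sample_sheet(genomes: list[GenomeRecord], sheet: pd.DataFrame) -> None:
    loc = dict(zip(sheet["id"], sheet["location"]))
    for g in genomes:
        if g.id in loc:
            g.location = loc[g.id]


def read_infection_matrix(path: str | Path) -> InfectionMatrix:
    """Read the infection-outcome TSV: host, virus, high, medium, low counts."""
    df = pd.read_csv(path, sep="\t", dtype={"host": str, "virus": str})
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for _, row in df.iterrows():
        counts.setdefault(row["host"], {})[row["virus"]] = {
            t: int(row[t]) for t in InfectionMatrix.TITERS
        }
    hosts = sorted(counts)
    viruses = sorted({v for hv in counts.values() for v in hv})
    m = InfectionMatrix(hosts=hosts, viruses=viruses, counts=counts)
    m.validate()
    return m


def write_infection_matrix(matrix: InfectionMatrix, path: str | Path) -> None:
    rows = []
    for h in matrix.hosts:
        for v in matrix.viruses:
            c = matrix.counts[h][v]
            rows.append({"host": h, "virus": v, **{t: c[t] for t in InfectionMatrix.TITERS}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tables(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    input_paths: Iterable[str | Path] = (),
) -> dict:
    """Write result tables as TSV plus a run-manifest JSON.

    Tables are emitted with deterministic column order (as given), rows sorted
    by all columns, and floats at fixed precision, so identical inputs produce
    byte-identical outputs. The manifest records the config, seed and sha256
    checksums of the inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        if len(df):
            df = df.sort_values(list(df.columns), kind="mergesort")
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    manifest = {
        "config": _jsonable(config or {}),
        "seed": seed,
        "tables": sorted(results),
        "inputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in input_paths
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return obj


def translate_cds(nt: str) -> str:
    """Standard-code translation of an in-frame CDS, trailing stop removed.

    Internal stops raise; a missing trailing stop is tolerated.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    prot = str(Seq(nt).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in CDS")
    return prot
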