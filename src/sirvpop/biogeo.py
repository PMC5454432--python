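"""Biogeographic summaries of spacer-to-virus matches.

Aggregates spacer matches into per-location match fractions (per-spacer
denominator), identity histograms per host-location x virus, and the
partition of matches and matched base pairs over core genes, variable genes
and non-coding sequence (per-site denominator). Percentages are rounded half
up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .crispr import Spacer, SpacerMatch
from .io import GenomeRecord

NONCODING, CORE, VARIABLE = 0, 1, 2
_CATEGORY = {CORE: "core", VARIABLE: "variable", NONCODING: "non_coding"}


def pct(x: float, decimals: int = 1) -> float:
    """Percentage rounded half up, matching the reporting convention."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * x).quantize(q, rounding=ROUND_HALF_UP))


def _dedup(matches: list[SpacerMatch]) -> list[SpacerMatch]:
    seen = set()
    out = []
    for m in matches:
        key = (m.spacer_id, m.virus_id, m.start, m.end, m.strand)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def _locations(spacers: list[Spacer], sample_sheet: pd.DataFrame) -> dict[str, str]:
    loc = dict(zip(sample_sheet["id"], sample_sheet["location"]))
    missing = {s.host_id for s in spacers if s.host_id not in loc}
    if missing:
        raise ValueError(f"spacer hosts missing from sample sheet: {sorted(missing)}")
    return loc


def match_fractions(
    spacers: list[Spacer],
    matches: list[SpacerMatch],
    sample_sheet: pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of spacers per location (and per location x virus) with any
    match strictly above the identity threshold."""
    loc = _locations(spacers, sample_sheet)
    matches = _dedup(matches)
    spacer_loc = {s.spacer_id: loc[s.host_id] for s in spacers}
    hit_any: dict[str, set[str]] = {}
    hit_virus: dict[tuple[str, str], set[str]] = {}
    for m in matches:
        if m.full_identity > threshold and m.spacer_id in spacer_loc:
            location = spacer_loc[m.spacer_id]
            hit_any.setdefault(location, set()).add(m.spacer_id)
            hit_virus.setdefault((location, m.virus_id), set()).add(m.spacer_id)
    totals: dict[str, int] = {}
    for s in spacers:
        totals[spacer_loc[s.spacer_id]] = totals.get(spacer_loc[s.spacer_id], 0) + 1
    viruses = sorted({m.virus_id for m in matches})
    per_loc = pd.DataFrame(
        [
            {
                "location": location,
                "n_spacers_total": n,
                "n_spacers_matching": len(hit_any.get(location, ())),
                "fraction": len(hit_any.get(location, ())) / n,
                "percent": pct(len(hit_any.get(location, ())) / n),
            }
            for location, n in sorted(totals.items())
        ]
    )
    per_loc_virus = pd.DataFrame(
        [
            {
                "location": location,
                "virus": v,
                "n_spacers_total": n,
                "n_spacers_matching": len(hit_virus.get((location, v), ())),
                "fraction": len(hit_virus.get((location, v), ())) / n,
            }
            for location, n in sorted(totals.items())
            for v in viruses
        ]
    )
    return per_loc, per_loc_virus


def identity_distribution(
    matches: list[SpacerMatch],
    spacers: list[Spacer],
    sample_sheet: pd.DataFrame,
    threshold: float = 0.5,
    bin_width: int = 5,
) -> pd.DataFrame:
    """Match counts per identity bin for every host-location x virus pair.

    Bins are [b, b+width) percent with 100% folded into the top bin; only
    matches strictly above the threshold contribute.
    """
    loc = _locations(spacers, sample_sheet)
    spacer_loc = {s.spacer_id: loc[s.host_id] for s in spacers}
    rows = []
    for m in _dedup(matches):
        if m.full_identity <= threshold or m.spacer_id not in spacer_loc:
            continue
        p = 100 * m.full_identity
        b = min(int(p // bin_width) * bin_width, 100 - bin_width)
        rows.append(
            {
                "host_location": spacer_loc[m.spacer_id],
                "virus": m.virus_id,
                "bin_start": b,
                "identity_pct": p,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["host_location", "virus", "bin_start", "n_matches"])
    df = pd.DataFrame(rows)
    hist = (
        df.groupby(["host_location", "virus", "bin_start"])
        .size()
        .reset_index(name="n_matches")
    )
    return hist


@dataclass
class RegionPartition:
    per_virus: pd.DataFrame  # match counts and bp coverage per category
    summary: pd.DataFrame  # mean +/- SD across viruses


def genome_categories(genome: GenomeRecord, orf_status: dict[str, str]) -> np.ndarray:
    """Per-base category array: core genes, variable genes, non-coding.

    Every base belongs to exactly one category; bases covered by both a core
    and a variable ORF count as core (core > variable precedence).
    """
    cats = np.zeros(len(genome.sequence), dtype=np.uint8)
    missing = [
        f.feature_id
        for f in genome.features
        if f.kind == "CDS" and f.feature_id not in orf_status
    ]
    if missing:
        raise ValueError(f"virus {genome.id} has ORFs without cluster status: {missing[:3]}")
    for f in genome.features:
        if f.kind == "CDS" and orf_status[f.feature_id] == "variable":
            cats[f.start : f.end] = VARIABLE
    for f in genome.features:
        if f.kind == "CDS" and orf_status[f.feature_id] == "core":
            cats[f.start : f.end] = CORE
    return cats


def region_partition(
    matches: list[SpacerMatch],
    viruses: list[GenomeRecord],
    orf_status: dict[str, str],
    threshold: float = 0.5,
) -> RegionPartition:
    """Partition reported matches and matched bp over core/variable/non-coding.

    Each match is assigned to the category holding the majority of its
    protospacer bases (ties resolve core > variable > non-coding); bp
    coverage is the fraction of each category's bases under the union of
    reported protospacer windows.
    """
    matches = [m for m in _dedup(matches) if m.full_identity > threshold]
    rows = []
    for v in viruses:
        cats = genome_categories(v, orf_status)
        covered = np.zeros(len(cats), dtype=bool)
        counts = {CORE: 0, VARIABLE: 0, NONCODING: 0}
        for m in matches:
            if m.virus_id != v.id:
                continue
            window = cats[m.start : m.end]
            covered[m.start : m.end] = True
            # ties resolve by precedence core > variable > non-coding
            precedence = {CORE: 2, VARIABLE: 1, NONCODING: 0}
            per_cat = [(int(np.sum(window == c)), c) for c in (CORE, VARIABLE, NONCODING)]
            best = max(per_cat, key=lambda t: (t[0], precedence[t[1]]))
            counts[best[1]] += 1
        total = sum(counts.values())
        row = {"virus": v.id, "n_matches": total}
        for c in (CORE, VARIABLE, NONCODING):
            name = _CATEGORY[c]
            size = int(np.sum(cats == c))
            row[f"n_matches_{name}"] = counts[c]
            row[f"pct_matches_{name}"] = pct(counts[c] / total) if total else 0.0
            row[f"bp_{name}"] = size
            row[f"bp_covered_{name}"] = int(np.sum(covered & (cats == c)))
            row[f"coverage_{name}"] = row[f"bp_covered_{name}"] / size if size else 0.0
        rows.append(row)
    per_virus = pd.DataFrame(rows)
    summary_rows = []
    for c in (CORE, VARIABLE, NONCODING):
        name = _CATEGORY[c]
        with_matches = per_virus[per_virus["n_matches"] > 0]
        vals = with_matches[f"pct_matches_{name}"]
        cov = per_virus[f"coverage_{name}"]
        summary_rows.append(
            {
                "category": name,
                "mean_pct_matches": float(vals.mean()) if len(vals) else 0.0,
                "sd_pct_matches": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "mean_pct_bp_covered": pct(float(cov.mean())) if len(cov) else 0.0,
                "sd_pct_bp_covered": float((100 * cov).std(ddof=1)) if len(cov) > 1 else 0.0,
            }
        )
    return RegionPartition(per_virus=per_virus, summary=pd.DataFrame(summary_rows))
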