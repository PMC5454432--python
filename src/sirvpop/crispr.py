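"""CRISPR repeat-spacer arrays, spacer-to-protospacer matching, immunity calls.

Array detection is a CRT-style seed-and-extend scan: an exact seed k-mer that
recurs at repeat+spacer periodicity anchors a chain of repeat candidates,
whose boundaries are then extended while columns agree across copies. Spacer
matching is ungapped: the best identity is computed for every window of
spacer length on both strands of the target genome with a vectorized
comparison, and windows above the reporting threshold are collapsed to local
maxima. The seed region and 5' half of the spacer, and the PAM adjacent to
the protospacer, follow the crRNA orientation conventions of Type I systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureRecord, GenomeRecord, InfectionMatrix, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(seq: str, motif: str) -> bool:
    """Whether seq matches an IUPAC motif of the same length (N never matches)."""
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC[m] for b, m in zip(seq, motif))


def _encode(seq: str) -> np.ndarray:
    """Bytes of the sequence with N (or anything non-ACGT) mapped to a
    non-matching sentinel so it can never count as an identity."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[~acgt] = 0
    return arr


# ---------------------------------------------------------------------------
# array detection


@dataclass
class RepeatSpacerArray:
    host_id: str
    start: int
    end: int
    repeat_consensus: str
    repeats: list[tuple[int, int]]
    spacers: list[tuple[int, int]]
    orientation: str = "forward"  # forward | reverse | ambiguous

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError("n_spacers must equal n_repeats - 1")


@dataclass
class Spacer:
    spacer_id: str
    host_id: str
    sequence: str
    array_id: str
    index: int
    orientation: str = "forward"


def detect_arrays(
    genome: GenomeRecord,
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = (23, 47),
    spacer_len: tuple[int, int] = (17, 50),
    max_repeat_mismatch: float = 0.2,
    seed_k: int = 13,
) -> list[RepeatSpacerArray]:
    """Detect repeat-spacer arrays by seed-and-extend.

    Consecutive repeats must share an exact `seed_k`-mer at a spacing within
    the repeat+spacer period bounds; boundaries extend while the column
    majority across copies stays above 1 - max_repeat_mismatch.
    """
    seq = genome.sequence
    n = len(seq)
    min_period = repeat_len[0] + spacer_len[0]
    max_period = repeat_len[1] + spacer_len[1]
    arrays: list[RepeatSpacerArray] = []
    i = 0
    while i <= n - seed_k:
        probe = seq[i : i + seed_k]
        if "N" in probe:
            i += 1
            continue
        j = seq.find(probe, i + min_period, min(n, i + max_period + seed_k))
        if j == -1:
            i += 1
            continue
        positions = [i, j]
        while True:
            p = positions[-1]
            q = seq.find(seq[p : p + seed_k], p + min_period, min(n, p + max_period + seed_k))
            if q == -1:
                break
            positions.append(q)
        if len(positions) >= min_repeats:
            arr = _extend_array(
                seq, positions, seed_k, repeat_len, spacer_len, max_repeat_mismatch, genome.id
            )
            if arr is not None:
                arrays.append(arr)
                i = arr.end
                continue
        i += 1
    return arrays


def _column_ok(seq: str, positions: list[int], offset: int, min_agree: float) -> bool:
    bases = [seq[p + offset] for p in positions if 0 <= p + offset < len(seq)]
    if len(bases) < len(positions):
        return False
    best = max(bases.count(b) for b in set(bases))
    return best / len(bases) >= min_agree


def _extend_array(seq, positions, seed_k, repeat_len, spacer_len, max_mm, host_id):
    min_agree = 1.0 - max_mm
    gaps = [b - a for a, b in zip(positions, positions[1:])]
    min_gap = min(gaps)
    left, width = 0, seed_k
    while (
        width < repeat_len[1]
        and min_gap - width > spacer_len[0]
        and positions[-1] + width < len(seq)
        and _column_ok(seq, positions, width, min_agree)
    ):
        width += 1
    while (
        width < repeat_len[1]
        and min_gap - width > spacer_len[0]
        and positions[0] - left > 0
        and _column_ok(seq, positions, -left - 1, min_agree)
    ):
        left += 1
        width += 1
    if width < repeat_len[0]:
        return None
    starts = [p - left for p in positions]
    repeats = [(s, s + width) for s in starts]
    spacers = [(repeats[k][1], repeats[k + 1][0]) for k in range(len(repeats) - 1)]
    if any(not spacer_len[0] <= e - s <= spacer_len[1] for s, e in spacers):
        return None
    cols = np.array([list(seq[s : s + width]) for s in starts])
    consensus = "".join(
        max("ACGT", key=lambda b, c=c: int(np.sum(c == b))) for c in cols.T
    )
    return RepeatSpacerArray(
        host_id=host_id,
        start=repeats[0][0],
        end=repeats[-1][1],
        repeat_consensus=consensus,
        repeats=repeats,
        spacers=spacers,
    )


def _best_hamming(a: str, b: str) -> int:
    """Minimum mismatches sliding the shorter sequence along the longer."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = len(short)
    for off in range(len(long_) - len(short) + 1):
        mm = sum(x != y for x, y in zip(short, long_[off : off + len(short)]))
        best = min(best, mm)
    return best


def orient_spacers(
    array: RepeatSpacerArray,
    genome: GenomeRecord,
    reference_repeat: str | None = None,
    max_length_diff: int = 6,
) -> list[Spacer]:
    """Orient the array by its repeat and emit spacers 5'->3' in crRNA sense.

    The consensus is compared (Hamming, best sliding offset) against the
    reference repeat and its reverse complement; the better orientation wins.
    Ties mark the array ambiguous and spacers are emitted in both
    orientations. Without a reference the array is taken as forward.
    """
    array_id = f"{array.host_id}:{array.start + 1}-{array.end}"
    seqs = [genome.sequence[s:e] for s, e in array.spacers]
    if reference_repeat is not None:
        if abs(len(reference_repeat) - len(array.repeat_consensus)) > max_length_diff:
            raise ValueError(
                f"reference repeat length {len(reference_repeat)} incompatible with "
                f"consensus length {len(array.repeat_consensus)}"
            )
        fwd = _best_hamming(array.repeat_consensus, reference_repeat)
        rev = _best_hamming(array.repeat_consensus, revcomp(reference_repeat))
        if rev < fwd:
            array.orientation = "reverse"
            seqs = [revcomp(s) for s in reversed(seqs)]
        elif rev == fwd:
            array.orientation = "ambiguous"
        else:
            array.orientation = "forward"
    spacers = [
        Spacer(
            spacer_id=f"{array_id}|sp{k + 1}",
            host_id=array.host_id,
            sequence=s,
            array_id=array_id,
            index=k,
            orientation=array.orientation,
        )
        for k, s in enumerate(seqs)
    ]
    if array.orientation == "ambiguous":
        spacers += [
            Spacer(
                spacer_id=f"{array_id}|sp{k + 1}rc",
                host_id=array.host_id,
                sequence=revcomp(s),
                array_id=array_id,
                index=k,
                orientation="ambiguous",
            )
            for k, s in enumerate(reversed(seqs))
        ]
    return spacers


# ---------------------------------------------------------------------------
# matching


@dataclass
class SpacerMatch:
    """One ungapped spacer-to-genome hit (protospacer window)."""

    spacer_id: str
    virus_id: str
    start: int
    end: int
    strand: str
    full_identity: float
    half5_identity: float = 0.0
    seed_identity: float = 0.0
    pam_present: bool = False
    pam_sequence: str = ""


def _window_identities(genome_arr: np.ndarray, spacer_arr: np.ndarray) -> np.ndarray:
    L = spacer_arr.size
    if genome_arr.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(genome_arr, L)
    return (win == spacer_arr).mean(axis=1)


def _longest_match_runs(genome_arr: np.ndarray, spacer_arr: np.ndarray) -> np.ndarray:
    """Longest exact run of matching bases per spacer-length window."""
    L = spacer_arr.size
    if genome_arr.size < L:
        return np.empty(0)
    eq = np.lib.stride_tricks.sliding_window_view(genome_arr, L) == spacer_arr
    best = np.zeros(eq.shape[0], dtype=np.int32)
    cur = np.zeros(eq.shape[0], dtype=np.int32)
    for j in range(L):
        cur = (cur + 1) * eq[:, j]
        np.maximum(best, cur, out=best)
    return best


def _collapse_local_maxima(ids: np.ndarray, qualifying: np.ndarray, L: int) -> list[int]:
    """Indices of per-run best windows among overlapping qualifying hits."""
    above = np.flatnonzero(qualifying)
    out: list[int] = []
    run: list[int] = []
    for idx in above:
        if run and idx - run[-1] >= L:
            out.append(int(run[np.argmax(ids[run])]))
            run = []
        run.append(idx)
    if run:
        out.append(int(run[np.argmax(ids[run])]))
    return out


def match_spacer(
    spacer: Spacer,
    virus: GenomeRecord,
    report_threshold: float = 0.5,
    seed_length: int = 8,
    pam_motif: str = "CCN",
    pam_side: str = "5prime",
    word_size: int = 12,
) -> list[SpacerMatch]:
    """All ungapped protospacer windows with identity strictly above threshold.

    Windows are scanned on both strands; a window qualifies when its identity
    exceeds the threshold AND it contains an exact matching run of at least
    word_size bases (the anchor a seeded search needs to find the hit at all;
    0 disables it). Overlapping qualifying windows collapse to the local
    identity maximum. Identity fractions over the 5' half and the
    PAM-proximal seed are computed on each reported window, and the PAM
    flanking the protospacer is checked against the IUPAC motif.
    """
    sp = _encode(spacer.sequence)
    L = sp.size
    if L > len(virus.sequence):
        return []
    g = _encode(virus.sequence)
    g_rc = _encode(revcomp(virus.sequence))
    n = g.size
    half = -(-L // 2)  # ceil
    matches: list[SpacerMatch] = []
    for strand, arr in (("+", g), ("-", g_rc)):
        ids = _window_identities(arr, sp)
        qualifying = ids > report_threshold
        if word_size > 0 and qualifying.any():
            qualifying &= _longest_match_runs(arr, sp) >= word_size
        for idx in _collapse_local_maxima(ids, qualifying, L):
            if strand == "+":
                start = idx
                win = g[idx : idx + L]
            else:
                # index on the rc sequence -> forward coordinates
                start = n - idx - L
                win = _encode(revcomp(virus.sequence[start : start + L]))
            per_base = win == sp
            m = SpacerMatch(
                spacer_id=spacer.spacer_id,
                virus_id=virus.id,
                start=start,
                end=start + L,
                strand=strand,
                full_identity=float(per_base.mean()),
                half5_identity=float(per_base[:half].mean()),
            )
            seed_slice = per_base[:seed_length] if pam_side == "5prime" else per_base[-seed_length:]
            m.seed_identity = float(seed_slice.mean())
            detect_pam(m, virus, motif=pam_motif, side=pam_side)
            matches.append(m)
    matches.sort(key=lambda m: (-m.full_identity, m.start, m.strand))
    return matches


def detect_pam(
    match: SpacerMatch, virus: GenomeRecord, motif: str = "CCN", side: str = "5prime"
) -> SpacerMatch:
    """Check the protospacer-adjacent motif on the protospacer strand.

    side="5prime": the |motif| bases immediately 5' of the protospacer in its
    own strand orientation. Out-of-bounds positions leave pam_present False.
    """
    k = len(motif)
    seq = virus.sequence
    want_upstream = (side == "5prime") == (match.strand == "+")
    if want_upstream:
        lo, hi = match.start - k, match.start
    else:
        lo, hi = match.end, match.end + k
    if lo < 0 or hi > len(seq):
        match.pam_present = False
        match.pam_sequence = ""
        return match
    adj = seq[lo:hi]
    if match.strand == "-":
        adj = revcomp(adj)
    match.pam_sequence = adj
    match.pam_present = iupac_match(adj, motif)
    return match


# ---------------------------------------------------------------------------
# immunity


@dataclass
class ImmunityCall:
    host_id: str
    virus_id: str
    n_matches_with_pam: int = 0
    n_matches_no_pam: int = 0
    n_spacers_with_pam: int = 0
    n_spacers_no_pam: int = 0
    best_full_identity: float = 0.0
    predicted: str = "susceptible"  # immune | susceptible
    observed: dict[str, int] | None = None
    discordance: str = ""  # concordant | anti-crispr-candidate | resistance-candidate


def call_immunity(
    host_id: str,
    virus_id: str,
    matches: list[SpacerMatch],
    observed: dict[str, int] | None = None,
    id_threshold: float = 0.5,
    require_pam: bool = True,
) -> ImmunityCall:
    """Predict immunity from qualifying matches and reconcile with infection.

    Predicted immune iff at least one match has full identity strictly above
    the threshold and (if required) a PAM. Predicted-immune hosts cleared even
    at low titer are anti-CRISPR candidates; predicted-susceptible hosts with
    no clearing at high titer are resistance candidates. Both per-site and
    per-spacer counts are reported.
    """
    call = ImmunityCall(host_id=host_id, virus_id=virus_id)
    qual_pam_spacers: set[str] = set()
    qual_nopam_spacers: set[str] = set()
    for m in matches:
        call.best_full_identity = max(call.best_full_identity, m.full_identity)
        if m.full_identity > id_threshold:
            if m.pam_present:
                call.n_matches_with_pam += 1
                qual_pam_spacers.add(m.spacer_id)
            else:
                call.n_matches_no_pam += 1
                qual_nopam_spacers.add(m.spacer_id)
    call.n_spacers_with_pam = len(qual_pam_spacers)
    call.n_spacers_no_pam = len(qual_nopam_spacers - qual_pam_spacers)
    qualifying = call.n_matches_with_pam if require_pam else (
        call.n_matches_with_pam + call.n_matches_no_pam
    )
    call.predicted = "immune" if qualifying >= 1 else "susceptible"
    if observed is not None:
        call.observed = dict(observed)
        if call.predicted == "immune" and observed.get("low", 0) > 0:
            call.discordance = "anti-crispr-candidate"
        elif call.predicted == "susceptible" and observed.get("high", 0) == 0:
            call.discordance = "resistance-candidate"
        else:
            call.discordance = "concordant"
    return call


def array_features(array: RepeatSpacerArray, prefix: str = "") -> list[FeatureRecord]:
    """Repeat and spacer FeatureRecords for an array (forward strand)."""
    feats = []
    for k, (s, e) in enumerate(array.repeats):
        feats.append(FeatureRecord(f"{prefix}rep{k + 1}", s, e, "+", "repeat"))
    for k, (s, e) in enumerate(array.spacers):
        feats.append(FeatureRecord(f"{prefix}sp{k + 1}", s, e, "+", "spacer"))
    return feats


def predicted_immune(
    spacers: list[Spacer],
    virus: GenomeRecord,
    id_threshold: float = 0.5,
    pam_motif: str = "CCN",
    require_pam: bool = True,
    word_size: int = 12,
) -> bool:
    """Whether any spacer has a qualifying (identity, PAM) hit in the virus."""
    for sp in spacers:
        for m in match_spacer(
            sp, virus, report_threshold=id_threshold, pam_motif=pam_motif, word_size=word_size
        ):
            if m.full_identity > id_threshold and (m.pam_present or not require_pam):
                return True
    return False


__all__ = [
    "RepeatSpacerArray",
    "Spacer",
    "SpacerMatch",
    "ImmunityCall",
    "InfectionMatrix",
    "detect_arrays",
    "orient_spacers",
    "match_spacer",
    "detect_pam",
    "call_immunity",
    "predicted_immune",
    "iupac_match",
    "array_features",
]
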