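"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written directly from the mathematical definition, in plain
Python, deliberately sharing no code with the package internals it checks.
"""

import itertools

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def sw_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Gotoh local-alignment DP; a gap of length k costs gap_open + k*gap_extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + blosum62(a[i - 1], b[j - 1]))
            best = max(best, M[i][j])
    return best


def nw_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Global (Needleman-Wunsch/Gotoh) score, end gaps penalized."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -gap_open - i * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = -gap_open - j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = diag + blosum62(a[i - 1], b[j - 1])
    return max(M[n][m], Ix[n][m], Iy[n][m])


# ---------------------------------------------------------------------------
# Nei-Gojobori


def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=1))


def ng_sites_oracle(codon: str) -> float:
    """Synonymous sites: per position, fraction of the 3 changes that keep the
    amino acid; changes into stops count toward the nonsynonymous side."""
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                s += 1.0 / 3.0
    return s


def ng_pathways_oracle(ca: str, cb: str):
    """(Sd, Nd) averaged over valid orderings; None if all pass through stops."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return (0.0, 0.0)
    results = []
    for order in itertools.permutations(positions):
        current = ca
        steps = []
        blocked = False
        for pos in order:
            following = current[:pos] + cb[pos] + current[pos + 1 :]
            if _aa(following) == "*":
                blocked = True
                break
            steps.append(_aa(current) == _aa(following))
            current = following
        if not blocked:
            results.append(steps)
    if not results:
        return None
    sd = sum(sum(1 for st in path if st) for path in results) / len(results)
    nd = sum(sum(1 for st in path if not st) for path in results) / len(results)
    return sd, nd


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_oracle(weights: dict[tuple[str, str], float], nodes: list[str], inflation: float = 2.0):
    """Step-by-step MCL in plain row/column loops; returns frozenset partition."""
    ids = sorted(nodes)
    n = len(ids)
    pos = {x: i for i, x in enumerate(ids)}
    mat = [[0.0] * n for _ in range(n)]
    for (u, v), w in weights.items():
        mat[pos[u]][pos[v]] = max(mat[pos[u]][pos[v]], w)
        mat[pos[v]][pos[u]] = max(mat[pos[v]][pos[u]], w)
    for j in range(n):
        col_max = max(mat[i][j] for i in range(n))
        mat[j][j] = col_max if col_max > 0 else 1.0
    _normalize_cols(mat)
    for _ in range(200):
        prev = [row[:] for row in mat]
        mat = _matmul(mat, mat)
        for i in range(n):
            for j in range(n):
                mat[i][j] = mat[i][j] ** inflation
                if mat[i][j] < 1e-8:
                    mat[i][j] = 0.0
        _normalize_cols(mat)
        delta = max(abs(mat[i][j] - prev[i][j]) for i in range(n) for j in range(n))
        if delta < 1e-6:
            break
    # connected components of the attractor graph
    seen = set()
    parts = []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            for y in range(n):
                if y not in comp and (mat[x][y] > 1e-8 or mat[y][x] > 1e-8):
                    stack.append(y)
        seen |= comp
        parts.append(frozenset(ids[i] for i in comp))
    return frozenset(parts)


def _normalize_cols(mat):
    n = len(mat)
    for j in range(n):
        s = sum(mat[i][j] for i in range(n))
        if s > 0:
            for i in range(n):
                mat[i][j] /= s


def _matmul(a, b):
    n = len(a)
    return [[sum(a[i][k] * b[k][j] for k in range(n)) for j in range(n)] for i in range(n)]


# ---------------------------------------------------------------------------
# spacer matching


def _rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spacer_match_oracle(spacer: str, genome: str, threshold: float = 0.5, word: int = 12):
    """Naive per-window scan: [(start, strand, identity)] of collapsed maxima."""
    L = len(spacer)
    out = []
    for strand in "+-":
        qualifying = []
        for i in range(len(genome) - L + 1):
            window = genome[i : i + L]
            proto = window if strand == "+" else _rc(window)
            eq = [x == y and x in "ACGT" for x, y in zip(proto, spacer)]
            ident = sum(eq) / L
            run = best_run = 0
            for e in eq:
                run = run + 1 if e else 0
                best_run = max(best_run, run)
            if ident > threshold and (word == 0 or best_run >= word):
                qualifying.append((i, ident))
        group = []
        for i, ident in qualifying:
            if group and i - group[-1][0] >= L:
                out.append(_best_of(group, strand))
                group = []
            group.append((i, ident))
        if group:
            out.append(_best_of(group, strand))
    return sorted(out)


def _best_of(group, strand):
    best = max(group, key=lambda t: t[1])
    # leftmost among ties, matching argmax semantics
    for i, ident in group:
        if ident == best[1]:
            return (i, strand, ident)


# ---------------------------------------------------------------------------
# six-frame search


def six_frame_contains(genome: str, protein: str) -> bool:
    for seq in (genome, _rc(genome)):
        for off in range(3):
            sub = seq[off : off + 3 * ((len(seq) - off) // 3)]
            if protein in str(Seq(sub).translate(table=1)):
                return True
    return False
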