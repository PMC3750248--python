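"""Independent brute-force oracles used to validate the implementation.

Everything here is written naively (explicit dynamic programs, explicit
enumeration) and never calls the code paths it checks.
"""
from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Exhaustive affine-gap Smith-Waterman score; a gap of length L
    costs gap_open + L * gap_extend."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def gotoh_global_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
    gap_open: float = 5.0, gap_extend: float = 2.0,
) -> float:
    """Exhaustive affine-gap Needleman-Wunsch score (terminal gaps
    penalized); a gap of length L costs gap_open + L * gap_extend."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(first + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0][j] = -(first + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def rbh_brute(hits_ab, hits_ba, evalue_max=1e-5, cov_min=0.7, pident_min=0.0):
    """Reciprocal-best-hit pairs by explicit enumeration."""

    def qualifying(hits):
        return [
            h for h in hits
            if h.evalue <= evalue_max
            and max(h.q_cov, h.s_cov) >= cov_min
            and h.pct_identity >= pident_min
        ]

    def best_of(hits, query):
        mine = [h for h in hits if h.query_id == query]
        if not mine:
            return None
        # max bit score, ties by identity, then smallest subject id
        return min(mine, key=lambda h: (-h.bit_score, -h.pct_identity, h.subject_id))

    q_ab = qualifying(hits_ab)
    q_ba = qualifying(hits_ba)
    pairs = set()
    for x in {h.query_id for h in q_ab}:
        bx = best_of(q_ab, x)
        by = best_of(q_ba, bx.subject_id)
        if by is not None and by.subject_id == x:
            pairs.add((x, bx.subject_id))
    return pairs


def collinear_runs(perm: list[int], min_size: int = 2) -> set[tuple[int, ...]]:
    """Maximal strictly-adjacent collinear runs (gap 0, inversions
    allowed) of the identity orthology a_i ~ b_i where gene b_i sits at
    position perm.index(i) in genome B. Returned as tuples of a-indices."""
    n = len(perm)
    inv = [0] * n
    for pos, g in enumerate(perm):
        inv[g] = pos
    runs = []
    cur = [0]
    d = 0
    for i in range(1, n):
        db = inv[i] - inv[i - 1]
        if abs(db) == 1 and (d == 0 or db == d):
            cur.append(i)
            d = db
        else:
            runs.append(cur)
            cur = [i]
            d = 0
    runs.append(cur)
    return {tuple(r) for r in runs if len(r) >= min_size}


def island_runs(flags: list[bool], min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, by regex on a 0/1 string."""
    import re

    s = "".join("1" if f else "0" for f in flags)
    return [
        (m.start(), m.end() - 1)
        for m in re.finditer(r"1+", s)
        if m.end() - m.start() >= min_run
    ]


def hamming_windows(seq: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    out = []
    k = len(pattern)
    for i in range(len(seq) - k + 1):
        d = sum(1 for x, y in zip(seq[i : i + k], pattern) if x != y)
        if d <= max_mismatch:
            out.append((i, d))
    return out


def copper_placements(seq: str, w1, w2, w3) -> list[tuple[int, int, int, int]]:
    """All valid H..C..H..M placements by exhaustive search."""
    out = []
    for h1, c, h2, m in itertools.product(range(len(seq)), repeat=4):
        if (
            seq[h1] == "H" and seq[c] == "C" and seq[h2] == "H" and seq[m] == "M"
            and w1[0] <= c - h1 <= w1[1]
            and w2[0] <= h2 - c <= w2[1]
            and w3[0] <= m - h2 <= w3[1]
        ):
            out.append((h1, c, h2, m))
    return sorted(out)
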