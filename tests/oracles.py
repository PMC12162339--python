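"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths (and the biotite library) that the
implementation uses: the substitution matrix comes from Biopython, alignment
scores from a hand-written DP / exhaustive path enumeration, and motif
matches from the ``re`` module.
"""

from __future__ import annotations

import re

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum(a: str, b: str) -> int:
    return int(_BLOSUM62[a][b])


def dp_local_affine(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith-Waterman with affine gaps; a gap of length k costs open + k*ext."""
    first = gap_open + gap_extend
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = diag + blosum(a[i - 1], b[j - 1])
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return int(best)


def dp_global_free_ends(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Needleman-Wunsch with affine internal gaps and free terminal gaps."""
    first = gap_open + gap_extend
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = 0.0  # free leading gaps
    for j in range(1, m + 1):
        Iy[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j] - gap_extend)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = diag + blosum(a[i - 1], b[j - 1])
    # free trailing gaps: best over the last row and column
    best = neg
    for i in range(n + 1):
        best = max(best, M[i][m], Ix[i][m], Iy[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], Ix[n][j], Iy[n][j])
    return int(best)


def enumerate_local(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive enumeration of every local alignment of a and b.

    Every substring pair is aligned by enumerating every monotone gapped
    path; affine gap runs cost open + k*ext.  Exponential — tiny inputs only.
    """
    first = gap_open + gap_extend

    def enum(x: str, y: str) -> int:
        best = [float("-inf")]

        def rec(i: int, j: int, score: float, last: str) -> None:
            if i == len(x) and j == len(y):
                best[0] = max(best[0], score)
                return
            if i < len(x) and j < len(y):
                rec(i + 1, j + 1, score + blosum(x[i], y[j]), "M")
            if i < len(x):
                cost = gap_extend if last == "X" else first
                rec(i + 1, j, score - cost, "X")
            if j < len(y):
                cost = gap_extend if last == "Y" else first
                rec(i, j + 1, score - cost, "Y")

        rec(0, 0, 0.0, "M")
        return int(best[0])

    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, enum(a[i1:i2], b[j1:j2]))
    return best


def trim_columns(rows: list[str], gap_threshold: float, cons_min: float) -> list[int]:
    """Reference column filter: occupancy threshold with a conserved floor."""
    import math
    ncols = len(rows[0]) if rows else 0
    occ = [sum(1 for r in rows if r[c] != "-") / len(rows) for c in range(ncols)]
    kept = [c for c in range(ncols) if occ[c] >= gap_threshold]
    floor = math.ceil(cons_min / 100.0 * ncols)
    if len(kept) < floor:
        ranked = sorted(range(ncols), key=lambda c: (-occ[c], c))
        kept = sorted(ranked[:floor])
    return kept


def motif_regex(anchors: list[str], gap_max: int = 20) -> re.Pattern:
    """Lazy bounded-gap regex for a gapped signature, e.g. F.{1,20}?I.{1,20}?KPDPP."""
    parts = []
    for k, anchor in enumerate(anchors):
        if "/" in anchor:
            parts.append("[" + "".join(anchor.split("/")) + "]")
        else:
            parts.append(re.escape(anchor))
        if k < len(anchors) - 1:
            parts.append(".{1,%d}?" % gap_max)
    return re.compile("".join(parts))


def regex_matches(seq: str, anchors: list[str], gap_max: int = 20) -> list[tuple[int, int]]:
    """Non-overlapping leftmost-lazy matches, 1-based inclusive coordinates."""
    pat = motif_regex(anchors, gap_max)
    return [(m.start() + 1, m.end()) for m in pat.finditer(seq)]
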