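"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, per-base
loops, textbook DP) and shares no code with the package internals.
"""

from __future__ import annotations

from math import comb, inf


def dinucleotide_cg_positions(sequence: str) -> list[int]:
    """Positions of C in every CG dinucleotide, by exhaustive window scan."""
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


def ccwgg_internal_c_positions(sequence: str) -> list[int]:
    """Assayed (internal) C of every CCWGG occurrence, exhaustively."""
    hits = []
    for i in range(len(sequence) - 4):
        w = sequence[i : i + 5]
        if w[0] == "C" and w[1] == "C" and w[2] in "AT" and w[3] == "G" and w[4] == "G":
            hits.append(i + 1)
    return hits


def convert_per_base(sequence: str, methylated: set[int]) -> str:
    out = []
    for i, base in enumerate(sequence):
        if base == "C" and i not in methylated:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


# --- textbook affine-gap global alignment (Gotoh), score only ---------------

MATCH, MISMATCH, OPEN, EXTEND = 2.0, -3.0, -5.0, -2.0


def _score(a: str, b: str) -> float:
    if "N" in (a, b):
        return -1.0
    if a == b:
        return MATCH
    if "Y" in (a, b) and {a, b} <= {"Y", "C", "T"}:
        return MATCH
    return MISMATCH


def global_alignment_score(x: str, y: str) -> float:
    """Optimal global affine-gap score; a gap of length L costs 5 + 2(L-1).

    End gaps are penalised (true Needleman-Wunsch). Matches the scoring
    convention of the package aligner without sharing any code with it.
    """
    n, m = len(x), len(y)
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    Ix = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in y (x base vs -)
    Iy = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in x (- vs y base)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = OPEN + (i - 1) * EXTEND
    for j in range(1, m + 1):
        Iy[0][j] = OPEN + (j - 1) * EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(x[i - 1], y[j - 1])
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + OPEN, Ix[i - 1][j] + EXTEND, Iy[i - 1][j] + OPEN)
            Iy[i][j] = max(M[i][j - 1] + OPEN, Iy[i][j - 1] + EXTEND, Ix[i][j - 1] + OPEN)
    return max(M[n][m], Ix[n][m], Iy[n][m])


# --- exact-test oracles ------------------------------------------------------


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> float:
        if k < max(0, c1 - r2) or k > min(r1, c1):
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    observed = pmf(a)
    return sum(p for k in range(0, min(r1, c1) + 1)
               if (p := pmf(k)) <= observed * (1 + 1e-9))


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p by tail enumeration (small-pmf method)."""
    def pmf(i: int) -> float:
        return comb(n, i) * p**i * (1 - p) ** (n - i)

    observed = pmf(k)
    return min(1.0, sum(q for i in range(n + 1) if (q := pmf(i)) <= observed * (1 + 1e-9)))
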