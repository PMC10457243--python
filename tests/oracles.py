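"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is a deliberately naive, transparent computation kept separate
from the library code paths it validates.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}


def naive_site_scan(seq: str, site: str, circular: bool = False) -> list[int]:
    """Expand-all-IUPAC sliding-window site scan over both strands."""

    def expand(s: str) -> set[str]:
        pats = {""}
        for code in s:
            pats = {p + b for p in pats for b in IUPAC[code]}
        return pats

    rc = "".join(_COMP[c] for c in reversed(site))
    concrete = expand(site) | expand(rc)
    search = seq + seq[: len(site) - 1] if circular else seq
    hits = set()
    for p in range(len(search) - len(site) + 1):
        if search[p : p + len(site)] in concrete:
            hits.add(p % len(seq) + 1)
    return sorted(hits)


def gotoh_local_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                      gap_open: int = 11, gap_extend: int = 1) -> float:
    """Affine-gap Smith-Waterman score by the three-state Gotoh recursion.

    A gap of length k costs gap_open + k * gap_extend (BLAST convention).
    """
    subs = substitution_matrices.load(matrix_name)
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # match state
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to -)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            s = subs[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def enumerate_tandem_arrays(seq: str, unit_range: tuple[int, int], min_copies: int,
                            max_mismatch_frac: float) -> list[tuple[int, int, int]]:
    """All (start0, unit, copies) with copies >= min_copies where every copy
    matches the column-majority consensus within the mismatch budget and the
    array is maximal in copy count at that (start, unit). Exhaustive."""
    from collections import Counter

    def majority(copies):
        out = []
        for i in range(len(copies[0])):
            c = Counter(x[i] for x in copies)
            out.append(min(c, key=lambda bb: (-c[bb], bb)))
        return "".join(out)

    results = []
    n = len(seq)
    for unit in range(unit_range[0], unit_range[1] + 1):
        budget = int(max_mismatch_frac * unit)
        for s in range(n - unit * min_copies + 1):
            max_c = (n - s) // unit
            best = 0
            for c in range(min_copies, max_c + 1):
                copies = [seq[s + k * unit : s + (k + 1) * unit] for k in range(c)]
                cons = majority(copies)
                if all(sum(x != y for x, y in zip(cp, cons)) <= budget for cp in copies):
                    best = c
            if best:
                results.append((s, unit, best))
    return results
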