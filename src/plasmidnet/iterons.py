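"""Tandem iteron detection and degenerate consensus notation.

Iterons are short direct repeats (typically 17-22 bp) in a plasmid's
replication origin, bound by the Rep initiator protein. The origin usually
sits immediately upstream of the *rep* gene and carries a small tandem array
of them (three to four copies in theta-replicating plasmids of the Rep_3
class). This module finds such arrays, summarizes each as a degenerate
consensus in (X/Y) notation — variable columns list the observed bases,
majority first — and exposes the upstream-window extraction used to aim the
detector at candidate oriV regions.

Copies within an array may differ from the array consensus by at most
``max_mismatch_frac`` of their positions; "tandem" means adjacent copies by
default (``max_spacer = 0``), configurable up to a short spacer.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .seqio import GeneFeature, PlasmidRecord, clean_dna, extract_region, reverse_complement


class IteronError(ValueError):
    pass


# -- degenerate consensus ------------------------------------------------------


@dataclass(frozen=True)
class DegenerateConsensus:
    """Per-column base sets of a repeat alignment.

    Each position holds the bases observed in that column, ordered by
    descending count then alphabetically. Rendered as the plain base for
    invariant columns and ``(X/Y)`` for variable ones; rendering and parsing
    are mutual inverses.
    """

    positions: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        for col in self.positions:
            if not col or any(b not in "ACGT" for b in col):
                raise IteronError(f"invalid consensus column {col!r}")

    def __len__(self) -> int:
        return len(self.positions)

    def render(self) -> str:
        out = []
        for col in self.positions:
            out.append(col[0] if len(col) == 1 else "(" + "/".join(col) + ")")
        return "".join(out)

    def __str__(self) -> str:
        return self.render()


_CONSENSUS_TOKEN = re.compile(r"\(([ACGT](?:/[ACGT])+)\)|([ACGT])")


def parse_consensus(text: str) -> DegenerateConsensus:
    """Parse an (X/Y)-notation consensus string back into column sets."""
    cols: list[tuple[str, ...]] = []
    pos = 0
    for m in _CONSENSUS_TOKEN.finditer(text):
        if m.start() != pos:
            raise IteronError(f"cannot parse consensus at {text[pos:]!r}")
        cols.append(tuple(m.group(1).split("/")) if m.group(1) else (m.group(2),))
        pos = m.end()
    if pos != len(text) or not cols:
        raise IteronError(f"cannot parse consensus at {text[pos:]!r}")
    return DegenerateConsensus(tuple(cols))


def build_consensus(copies: list[str]) -> DegenerateConsensus:
    """Column-wise degenerate consensus of equal-length repeat copies."""
    if len(copies) < 2:
        raise IteronError("need at least two copies")
    length = len(copies[0])
    if any(len(c) != length for c in copies):
        raise IteronError("copies have unequal lengths")
    copies = [clean_dna(c) for c in copies]
    cols = []
    for i in range(length):
        counts = Counter(c[i] for c in copies)
        ordered = sorted(counts, key=lambda b: (-counts[b], b))
        cols.append(tuple(ordered))
    return DegenerateConsensus(tuple(cols))


def _majority(copies: list[str]) -> str:
    """Majority base per column, ties broken alphabetically."""
    out = []
    for i in range(len(copies[0])):
        counts = Counter(c[i] for c in copies)
        out.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(out)


# -- array detection -----------------------------------------------------------


@dataclass
class IteronArray:
    """A detected tandem repeat array."""

    plasmid_id: str
    unit_length: int
    copy_count: int
    copy_starts: list[int]  # 1-based, on the searched strand
    copies: list[str]
    consensus: DegenerateConsensus
    mean_mismatch_frac: float
    strand: str = "+"

    @property
    def start(self) -> int:
        return self.copy_starts[0]

    @property
    def end(self) -> int:
        return self.copy_starts[-1] + self.unit_length - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _qualifies(copies: list[str], budget: int) -> bool:
    cons = _majority(copies)
    return all(_mismatches(c, cons) <= budget for c in copies)


def _grow_array(seq: str, start: int, unit: int, budget: int, max_spacer: int):
    """Greedy rightward extension of a tandem array anchored at *start*.

    Returns (starts, copies) or None if fewer than two copies qualify.
    """
    n = len(seq)
    starts = [start]
    copies = [seq[start : start + unit]]
    pos = start + unit
    while True:
        added = False
        for spacer in range(max_spacer + 1):
            p = pos + spacer
            if p + unit > n:
                continue
            cand = copies + [seq[p : p + unit]]
            if _qualifies(cand, budget):
                starts.append(p)
                copies = cand
                pos = p + unit
                added = True
                break
        if not added:
            break
    return (starts, copies) if len(copies) >= 2 else None


def find_iteron_arrays(
    seq: str,
    unit_range: tuple[int, int] = (18, 24),
    min_copies: int = 3,
    max_mismatch_frac: float = 0.15,
    max_spacer: int = 0,
    plasmid_id: str = "",
    strand: str = "+",
) -> list[IteronArray]:
    """Detect maximal tandem iteron arrays on one strand of *seq*.

    Every copy of a reported array differs from the array's column-majority
    consensus at no more than ``floor(max_mismatch_frac * unit_length)``
    positions. Arrays are maximal (no further qualifying copy to the left or
    right) and overlapping reports are resolved by keeping, in order of
    preference: higher copy count, lower mean mismatch fraction, smaller
    unit length, leftmost start. Candidate units with fewer than three
    distinct bases are suppressed as low-complexity.
    """
    seq = clean_dna(seq)
    lo, hi = unit_range
    if lo > hi or lo < 2:
        raise IteronError(f"bad unit_range {unit_range}")
    if not 0 <= max_mismatch_frac < 0.5:
        raise IteronError("max_mismatch_frac must be in [0, 0.5)")
    n = len(seq)
    candidates: list[IteronArray] = []
    for unit in range(lo, hi + 1):
        budget = int(max_mismatch_frac * unit)
        for s in range(0, n - 2 * unit + 1):
            grown = _grow_array(seq, s, unit, budget, max_spacer)
            if grown is None:
                continue
            starts, copies = grown
            if len(copies) < min_copies:
                continue
            # left-maximality: skip if a qualifying copy precedes the anchor
            left_ok = False
            for spacer in range(max_spacer + 1):
                p = s - unit - spacer
                if p >= 0 and _qualifies([seq[p : p + unit]] + copies, budget):
                    left_ok = True
                    break
            if left_ok:
                continue
            cons = _majority(copies)
            if len(set(cons)) < 3:
                continue  # low-complexity unit
            mm = sum(_mismatches(c, cons) for c in copies) / (len(copies) * unit)
            candidates.append(
                IteronArray(
                    plasmid_id=plasmid_id,
                    unit_length=unit,
                    copy_count=len(copies),
                    copy_starts=[p + 1 for p in starts],
                    copies=copies,
                    consensus=build_consensus(copies),
                    mean_mismatch_frac=mm,
                    strand=strand,
                )
            )
    return _dedupe_overlaps(candidates)


def _dedupe_overlaps(candidates: list[IteronArray]) -> list[IteronArray]:
    ranked = sorted(
        candidates,
        key=lambda a: (-a.copy_count, a.mean_mismatch_frac, a.unit_length, a.start),
    )
    kept: list[IteronArray] = []
    for cand in ranked:
        if all(cand.end < k.start or cand.start > k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda a: a.start)
    return kept


def find_iteron_arrays_both_strands(
    seq: str,
    unit_range: tuple[int, int] = (18, 24),
    min_copies: int = 3,
    max_mismatch_frac: float = 0.15,
    max_spacer: int = 0,
    plasmid_id: str = "",
) -> list[IteronArray]:
    """Scan both strands; minus-strand coordinates are on the reverse
    complement of the input. An array and its reverse complement are the
    same physical repeat, so a minus-strand call whose span overlaps a
    plus-strand call is collapsed to the plus-strand one.
    """
    fwd = find_iteron_arrays(
        seq, unit_range, min_copies, max_mismatch_frac, max_spacer, plasmid_id, "+"
    )
    rev = find_iteron_arrays(
        reverse_complement(seq),
        unit_range,
        min_copies,
        max_mismatch_frac,
        max_spacer,
        plasmid_id,
        "-",
    )
    n = len(seq)
    out = list(fwd)
    for a in rev:
        lo, hi = n - a.end + 1, n - a.start + 1  # span in + coordinates
        if all(hi < f.start or lo > f.end for f in fwd):
            out.append(a)
    return out


# -- upstream window -----------------------------------------------------------


def upstream_window(record: PlasmidRecord, rep_feature: GeneFeature, window: int = 500) -> str:
    """The *window* bp immediately 5' of a gene's start codon, on its coding
    strand. Wraps through the origin on circular records; on the minus strand
    the plus-strand 3' flank is taken and reverse-complemented. A window
    longer than the plasmid is truncated to the full plasmid with a warning.
    """
    n = record.length
    if window < 1:
        raise IteronError("window must be positive")
    if window > n:
        warnings.warn(
            f"upstream window {window} exceeds plasmid length {n}; truncated", stacklevel=2
        )
        window = n
    if rep_feature.strand == "+":
        five_prime = rep_feature.start
        if record.circular:
            s = (five_prime - 1 - window) % n + 1
            e = (five_prime - 2) % n + 1
            return extract_region(record, s, e)
        s = max(1, five_prime - window)
        return record.sequence[s - 1 : five_prime - 1]
    # minus strand: 5' end is at feature end in plus coordinates
    five_prime = rep_feature.end
    if record.circular:
        s = five_prime % n + 1
        e = (five_prime + window - 1) % n + 1
        return reverse_complement(extract_region(record, s, e))
    e = min(n, five_prime + window)
    return reverse_complement(record.sequence[five_prime:e])
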