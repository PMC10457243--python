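"""All-vs-all protein comparison and reciprocated similarity networks.

Every ordered pair of proteins is compared by gapped local alignment
(Smith-Waterman, BLOSUM62, BLAST-style affine gap costs: opening a gap of
length k costs ``gap_open + k * gap_extend``). Each comparison yields one
best-scoring high-scoring segment pair (HSP) from which identity, positives
(aligned pairs with positive substitution score — the basis of BLAST's
"similarity" percentage), coverage and a Karlin-Altschul E-value are taken.

An undirected network is built over the proteins: an edge joins p and q iff
BOTH directed comparisons pass the E-value, identity and coverage
thresholds ("reciprocated similarity"), and its weight is the product of
identity and coverage (averaged over the two directions). Connected
components of this network define protein families. Coverage is measured
against the shorter of the two sequences; per-direction query/subject
coverages are also kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# Published Karlin-Altschul parameters for gapped BLOSUM62 with 11/1 gaps.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


class ProtnetError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinSeq:
    """A protein with its replicon/strain provenance."""

    id: str
    sequence: str
    plasmid_id: str = ""
    strain: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().rstrip("*")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ProtnetError(f"{self.id}: empty sequence")
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise ProtnetError(f"{self.id}: non-amino-acid characters {sorted(bad)!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One directed local-alignment result (single best HSP)."""

    query_id: str
    subject_id: str
    raw_score: float
    identity: float  # identical residue pairs / aligned columns
    positives: float  # positively-scoring residue pairs / aligned columns
    coverage: float  # aligned span / min(query, subject) length
    query_coverage: float
    subject_coverage: float
    evalue: float


def _aligner(matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length k costs gap_open + k*gap_extend, so
    # the first gapped position carries gap_open + gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: ProteinSeq,
    b: ProteinSeq,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    kparams: tuple[float, float] = (DEFAULT_LAMBDA, DEFAULT_K),
) -> AlignmentHit:
    """Optimal gapped local alignment of *a* (query) against *b* (subject).

    Identity, positives and coverage are computed on the single best-scoring
    HSP; no HSP tiling is attempted. Coverage is relative to the shorter
    protein, with both per-sequence coverages retained.
    """
    aligner = _aligner(matrix, gap_open, gap_extend)
    subs = aligner.substitution_matrix
    alignments = aligner.align(a.sequence, b.sequence)
    score = float(alignments.score)
    if score <= 0:
        lam, k = kparams
        return AlignmentHit(a.id, b.id, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                            estimate_evalue(0.0, a.length, b.length, lam, k))
    best = alignments[0]
    ident = pos = columns = 0
    qa, qb = best[0], best[1]  # aligned strings with gaps
    for x, y in zip(qa, qb):
        if x == "-" or y == "-":
            columns += 1
            continue
        columns += 1
        if x == y:
            ident += 1
        if subs[x, y] > 0:
            pos += 1
    qspan = sum(1 for x in qa if x != "-")
    sspan = sum(1 for y in qb if y != "-")
    qcov = qspan / a.length
    scov = sspan / b.length
    cov = qcov if a.length <= b.length else scov  # vs the shorter protein
    lam, k = kparams
    return AlignmentHit(
        query_id=a.id,
        subject_id=b.id,
        raw_score=score,
        identity=ident / columns if columns else 0.0,
        positives=pos / columns if columns else 0.0,
        coverage=cov,
        query_coverage=qcov,
        subject_coverage=scov,
        evalue=estimate_evalue(score, a.length, b.length, lam, k),
    )


def estimate_evalue(
    raw_score: float,
    m: int,
    n: int,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S).

    m and n are the query and database lengths in residues. Used here as a
    similarity filter, not a database-search statistic, so no length or
    composition corrections are applied.
    """
    if m <= 0 or n <= 0:
        raise ProtnetError("sequence lengths must be positive")
    return k * m * n * math.exp(-lam * raw_score)


# -- network -------------------------------------------------------------------


@dataclass
class SimilarityNetwork:
    """Weighted undirected protein graph; components are families."""

    graph: nx.Graph

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def component_labels(self) -> dict[str, int]:
        """Deterministic node → component-index map (components ordered by
        their lexicographically smallest member)."""
        comps = sorted(self.components, key=lambda c: min(c))
        return {node: i for i, comp in enumerate(comps) for node in comp}


def _passes(hit: AlignmentHit, evalue_max: float, identity_min: float, coverage_min: float) -> bool:
    return (
        hit.evalue <= evalue_max
        and hit.identity >= identity_min
        and hit.coverage >= coverage_min
    )


def build_network(
    proteins: list[ProteinSeq],
    evalue_max: float = 1e-10,
    identity_min: float = 0.30,
    coverage_min: float = 0.90,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> SimilarityNetwork:
    """All-vs-all reciprocated similarity network.

    An edge (p, q) exists iff both directed hits p→q and q→p pass all three
    thresholds; its weight is the mean over the two directions of
    identity × coverage. Isolated proteins stay as singleton nodes, so
    connected components partition the full input set.
    """
    if not proteins:
        raise ProtnetError("empty protein set")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ProtnetError("duplicate protein ids")
    g = nx.Graph()
    for p in proteins:
        g.add_node(p.id, plasmid=p.plasmid_id, strain=p.strain, length=p.length)
    for i, p in enumerate(proteins):
        for q in proteins[i + 1 :]:
            fwd = local_align(p, q, matrix, gap_open, gap_extend)
            rev = local_align(q, p, matrix, gap_open, gap_extend)
            if _passes(fwd, evalue_max, identity_min, coverage_min) and _passes(
                rev, evalue_max, identity_min, coverage_min
            ):
                w = (fwd.identity * fwd.coverage + rev.identity * rev.coverage) / 2
                g.add_edge(p.id, q.id, weight=round(w, 6))
    return SimilarityNetwork(graph=g)


def reciprocal_similarity(a: ProteinSeq, b: ProteinSeq, **align_kw) -> dict[str, float]:
    """Both-direction identity/positives/coverage percentages for one pair.

    BLAST reports "positives" as its similarity percentage, so the
    ``similarity_pct`` entries are percent positives over the best HSP;
    identity is reported alongside.
    """
    fwd = local_align(a, b, **align_kw)
    rev = local_align(b, a, **align_kw)
    return {
        "identity_pct_fwd": 100 * fwd.identity,
        "identity_pct_rev": 100 * rev.identity,
        "similarity_pct_fwd": 100 * fwd.positives,
        "similarity_pct_rev": 100 * rev.positives,
        "coverage_fwd": fwd.coverage,
        "coverage_rev": rev.coverage,
    }


# -- reference classification --------------------------------------------------


def classify_protein(
    query: ProteinSeq,
    references: Mapping[str, list[ProteinSeq]],
    evalue_max: float = 1e-2,
    **align_kw,
) -> str:
    """Assign *query* the label of its best reference hit.

    *references* maps a family label (Rep_3, MOB_Q, ...) to its reference
    proteins. The best hit is the highest raw score passing the E-value
    threshold; ties break by higher identity, then lexicographic reference
    id. Returns "unclassified" when nothing passes.
    """
    if not references or not any(references.values()):
        raise ProtnetError("empty reference set")
    best: tuple[float, float, str, str] | None = None
    for label, refs in references.items():
        for ref in refs:
            hit = local_align(query, ref, **align_kw)
            if hit.evalue > evalue_max:
                continue
            key = (-hit.raw_score, -hit.identity, ref.id)
            if best is None or key < best[:3]:
                best = (*key, label)
    return best[3] if best else "unclassified"


def read_protein_fasta(
    path: str | Path, plasmid_id: str = "", strain: str = ""
) -> list[ProteinSeq]:
    return [
        ProteinSeq(rec.id, str(rec.seq), plasmid_id, strain)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_reference_dir(path: str | Path) -> dict[str, list[ProteinSeq]]:
    """Load a directory of labeled reference FASTAs; the file stem is the
    family label (e.g. ``MOB_Q.faa`` → label MOB_Q)."""
    refs: dict[str, list[ProteinSeq]] = {}
    for f in sorted(Path(path).glob("*.fa*")):
        refs[f.stem] = read_protein_fasta(f)
    if not refs:
        raise ProtnetError(f"no reference FASTAs under {path}")
    return refs
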