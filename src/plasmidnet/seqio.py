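"""Record model and IO for small circular replicons.

Coordinates are 1-based inclusive throughout (GenBank convention). A feature
or region whose ``start`` exceeds its ``end`` wraps forward through the
sequence origin, which is only legal on circular records. Sequences are
uppercased on read and restricted to the {A, C, G, T, N} alphabet.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqioError(ValueError):
    """Malformed input: bad alphabet, bad coordinates, or a bad flat file."""


def clean_dna(seq: str) -> str:
    """Uppercase *seq* and reject characters outside {A,C,G,T,N}."""
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise SeqioError(f"sequence contains non-DNA characters: {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on a replicon.

    ``start``/``end`` are 1-based inclusive; ``start > end`` marks a feature
    wrapping through the origin of a circular record. ``strand`` is '+' or '-'.
    """

    locus_tag: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SeqioError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise SeqioError("feature coordinates are 1-based and positive")


@dataclass(frozen=True)
class ModuleRegion:
    """A labeled span (REP, MOB, ...) on a replicon; may wrap the origin."""

    plasmid_id: str
    start: int
    end: int
    label: str = "other"

    VALID_LABELS = ("REP", "MOB", "DPR", "GCV", "SMR", "RM", "MSC", "MRS", "other")

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise SeqioError("region coordinates are 1-based and positive")

    @property
    def wraps(self) -> bool:
        return self.start > self.end


@dataclass
class PlasmidRecord:
    """A plasmid replicon: sequence, topology and annotated genes."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[GeneFeature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = clean_dna(self.sequence)
        if not self.sequence:
            raise SeqioError("empty sequence")
        if self.topology not in ("circular", "linear"):
            raise SeqioError(f"topology must be circular|linear, got {self.topology!r}")
        for f in self.features:
            if f.start > len(self.sequence) or f.end > len(self.sequence):
                raise SeqioError(
                    f"feature {f.locus_tag} outside record {self.id} "
                    f"(length {len(self.sequence)})"
                )
            if f.start > f.end and self.topology != "circular":
                raise SeqioError(
                    f"origin-wrapping feature {f.locus_tag} on linear record {self.id}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def rotated(self, k: int) -> "PlasmidRecord":
        """Return the record with its origin moved forward by *k* bp.

        Position p on the original maps to ((p - 1 - k) mod length) + 1 on the
        rotation. Only meaningful for circular records.
        """
        if not self.circular:
            raise SeqioError("cannot rotate a linear record")
        n = self.length
        k %= n
        seq = self.sequence[k:] + self.sequence[:k]

        def shift(p: int) -> int:
            return (p - 1 - k) % n + 1

        feats = [replace(f, start=shift(f.start), end=shift(f.end)) for f in self.features]
        return PlasmidRecord(self.id, seq, self.topology, feats, self.description)


def extract_region(record: PlasmidRecord, start: int, end: int) -> str:
    """Extract positions start..end (1-based inclusive), wrapping through the
    origin when start > end on a circular record.

    The returned fragment has length ``end - start + 1`` or, for a wrapping
    span, ``(length - start + 1) + end``.
    """
    n = record.length
    if not (1 <= start <= n and 1 <= end <= n):
        raise SeqioError(f"coordinates ({start}, {end}) outside [1, {n}]")
    if start <= end:
        return record.sequence[start - 1 : end]
    if not record.circular:
        raise SeqioError("origin-wrapping extraction requested on a linear record")
    return record.sequence[start - 1 :] + record.sequence[:end]


def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases, to one decimal.

    N bases are excluded from numerator and denominator; an all-N (or empty)
    sequence has no defined GC content and raises.
    """
    s = clean_dna(seq)
    counted = sum(s.count(b) for b in "ACGT")
    if counted == 0:
        raise SeqioError("GC content undefined: no unambiguous bases")
    gc = s.count("G") + s.count("C")
    return round(100.0 * gc / counted, 1)


# -- GenBank / FASTA -----------------------------------------------------------


def _feature_from_biopython(feat: SeqFeature, record_length: int) -> GeneFeature:
    loc = feat.location
    q = feat.qualifiers
    locus = (q.get("locus_tag") or q.get("gene") or [""])[0]
    product = (q.get("product") or [""])[0]
    translation = (q.get("translation") or [""])[0]
    strand = "-" if loc.strand == -1 else "+"
    # A CDS join over the origin arrives as a compound location whose parts
    # bracket the sequence end; encode it as start > end.
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) > 1 and int(parts[-1].end) == record_length and int(parts[0].start) == 0:
        start = int(parts[-1].start) + 1
        end = int(parts[0].end)
    else:
        start = int(loc.start) + 1
        end = int(loc.end)
    return GeneFeature(locus, start, end, strand, product, translation)


def read_genbank(path: str | Path) -> list[PlasmidRecord]:
    """Read a GenBank flat file into PlasmidRecords, one per LOCUS.

    Topology is taken from the LOCUS line; records not explicitly marked
    linear default to circular (these are plasmid replicons). Only CDS
    features are retained; a CDS without a deposited translation keeps an
    empty one rather than having it recomputed silently.
    """
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise SeqioError(f"malformed GenBank file {path}: {exc}") from exc
    for rec in parsed:
        topology = rec.annotations.get("topology", "circular")
        if topology not in ("circular", "linear"):
            topology = "circular"
        feats = [
            _feature_from_biopython(f, len(rec.seq))
            for f in rec.features
            if f.type == "CDS"
        ]
        records.append(
            PlasmidRecord(rec.id or rec.name, str(rec.seq), topology, feats, rec.description)
        )
    if not records:
        raise SeqioError(f"no GenBank records in {path}")
    return records


def _feature_to_biopython(f: GeneFeature, record_length: int) -> SeqFeature:
    strand = -1 if f.strand == "-" else 1
    if f.start > f.end:  # wraps the origin
        loc = FeatureLocation(f.start - 1, record_length, strand) + FeatureLocation(
            0, f.end, strand
        )
    else:
        loc = FeatureLocation(f.start - 1, f.end, strand)
    quals = {"locus_tag": [f.locus_tag]}
    if f.product:
        quals["product"] = [f.product]
    if f.translation:
        quals["translation"] = [f.translation]
    return SeqFeature(loc, type="CDS", qualifiers=quals)


def write_genbank(records: Iterable[PlasmidRecord], path: str | Path) -> None:
    out = []
    for r in records:
        rec = SeqRecord(
            Seq(r.sequence),
            id=r.id,
            name=r.id.split(".")[0][:16],
            description=r.description,
            annotations={"molecule_type": "DNA", "topology": r.topology},
        )
        rec.features = [_feature_to_biopython(f, r.length) for f in r.features]
        out.append(rec)
    SeqIO.write(out, str(path), "genbank")


def read_fasta(path: str | Path, topology: str = "circular") -> list[PlasmidRecord]:
    return [
        PlasmidRecord(rec.id, str(rec.seq), topology, [], rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[PlasmidRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} {r.description}".rstrip() + "\n")
            for i in range(0, r.length, 70):
                fh.write(r.sequence[i : i + 70] + "\n")


# -- network export ------------------------------------------------------------


def write_network(net, path: str | Path, format: str = "graphml") -> None:
    """Export a similarity network as GraphML or a tab-separated edge list.

    Node attributes (plasmid, strain) and edge weights survive a round-trip;
    weights are written to 6 decimals in the TSV form.
    """
    graph = net.graph if hasattr(net, "graph") else net
    if format == "graphml":
        nx.write_graphml(graph, str(path))
    elif format == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6f}\n")
    else:
        raise SeqioError(f"unknown network format {format!r} (graphml|edge-tsv)")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
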