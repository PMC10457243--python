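"""Truth-tracked synthetic plasmids and protein sets.

Small circular plasmids (a few kb to ~14 kb) are assembled from i.i.d.
background DNA at a requested GC content plus planted modules: a rep gene
with an upstream tandem-iteron array (perfect copies or with per-copy
substitutions), a mob (relaxase) gene, recognition sites inserted at known
positions, and module regions guaranteed free of a given enzyme panel's
sites. Protein sets are built as families descending from random ancestors
with controlled within- and between-family identity. Every generated object
is paired with a SyntheticTruth record sufficient to score any detector,
and identical inputs plus seed reproduce identical output byte for byte.

The background is compositionally i.i.d. — no codon bias, no indels, no
recombination — which is what the detectors under test assume; see the
methods note for what that does and does not exercise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .iterons import IteronArray, build_consensus
from .protnet import ProteinSeq
from .restriction import MCS_ENZYMES, RestrictionEnzyme, scan_sites
from .seqio import GeneFeature, ModuleRegion, PlasmidRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = {"TAA", "TAG", "TGA"}


class SynthError(ValueError):
    pass


# -- module specs --------------------------------------------------------------


@dataclass(frozen=True)
class IteronSpec:
    """A tandem iteron array planted immediately upstream of the rep gene."""

    unit: str | None = None  # explicit unit; random when None
    unit_length: int = 22
    copies: int = 4
    substitution_prob: float = 0.0  # per-base, independently per copy
    upstream_gap: int = 120  # bp between array end and rep start codon


@dataclass(frozen=True)
class RepModuleSpec:
    gene_length: int = 900  # bp incl. start and stop codons; multiple of 3
    iterons: IteronSpec | None = field(default_factory=IteronSpec)
    site_free: bool = False  # keep the whole REP region free of panel sites
    enzymes: tuple[RestrictionEnzyme, ...] = MCS_ENZYMES


@dataclass(frozen=True)
class MobModuleSpec:
    gene_length: int = 1200


@dataclass(frozen=True)
class SitePlantSpec:
    """Insert an enzyme's concrete recognition sequence into the backbone."""

    enzyme: RestrictionEnzyme
    count: int = 1


@dataclass
class SyntheticTruth:
    """Ground truth for one generated artifact, serializable to JSON."""

    seed: int
    planted_iterons: list[IteronArray] = field(default_factory=list)
    planted_sites: dict[str, list[int]] = field(default_factory=dict)
    module_regions: list[ModuleRegion] = field(default_factory=list)
    family_labels: dict[str, str] = field(default_factory=dict)
    pairwise_identity_targets: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_iterons": [
                {
                    "plasmid_id": a.plasmid_id,
                    "unit_length": a.unit_length,
                    "copy_count": a.copy_count,
                    "copy_starts": a.copy_starts,
                    "copies": a.copies,
                    "consensus": a.consensus.render(),
                    "strand": a.strand,
                }
                for a in self.planted_iterons
            ],
            "planted_sites": self.planted_sites,
            "module_regions": [asdict(r) for r in self.module_regions],
            "family_labels": self.family_labels,
            "pairwise_identity_targets": self.pairwise_identity_targets,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# -- DNA helpers ---------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _random_iteron_unit(rng: np.random.Generator, length: int, gc: float) -> str:
    """A random unit with at least 3 distinct bases (complexity guard) that
    does not tandem-match itself at a shorter period."""
    while True:
        unit = _random_dna(rng, length, gc)
        if len(set(unit)) < 3:
            continue
        if any(unit[:-p] == unit[p:] for p in range(1, length // 2 + 1)):
            continue
        return unit


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + random non-stop codons + one stop codon, *length* bp total."""
    if length % 3 or length < 9:
        raise SynthError("gene_length must be a multiple of 3, at least 9")
    codons = ["ATG"]
    bases = "ACGT"
    probs = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    for _ in range(length // 3 - 2):
        codon = _random_dna(rng, 3, gc)
        if codon in STOP_CODONS:
            # resample only the third base, keeping composition on track
            banned = {c[2] for c in STOP_CODONS if c[:2] == codon[:2]}
            allowed = [b for b in bases if b not in banned]
            w = np.array([probs[b] for b in allowed])
            codon = codon[:2] + str(rng.choice(allowed, p=w / w.sum()))
        codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _mutate_copy(rng: np.random.Generator, unit: str, prob: float) -> str:
    out = list(unit)
    for i in range(len(out)):
        if rng.random() < prob:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _scrub_sites(
    rng: np.random.Generator,
    seq: str,
    enzymes: tuple[RestrictionEnzyme, ...],
    gc: float,
    max_rounds: int = 200,
) -> str:
    """Re-randomize bases until no panel enzyme matches anywhere in *seq*."""
    s = list(seq)
    for _ in range(max_rounds):
        dirty = False
        for enz in enzymes:
            for pos in scan_sites("".join(s), enz, circular=False):
                i = pos - 1 + int(rng.integers(len(enz.site)))
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
                dirty = True
        if not dirty:
            return "".join(s)
    raise SynthError("could not scrub restriction sites from region")


# -- plasmid generation --------------------------------------------------------


def generate_plasmid(
    length: int,
    gc: float = 0.40,
    rep: RepModuleSpec | None = None,
    mob: MobModuleSpec | None = None,
    plant_sites: tuple[SitePlantSpec, ...] = (),
    seed: int = 0,
    plasmid_id: str = "synth_plasmid",
) -> tuple[PlasmidRecord, SyntheticTruth]:
    """Assemble one circular plasmid with the requested planted modules.

    Layout (all on the plus strand, from position 1): [backbone filler]
    [iteron array][gap][rep ORF][filler][mob ORF][filler to *length*].
    Realized GC tracks the request to within about two percentage points for
    kb-scale plasmids. Returns the record and the ground truth.
    """
    if not 1_000 <= length <= 100_000:
        raise SynthError("plasmid length must be between 1 kb and 100 kb")
    if not 0.2 <= gc <= 0.8:
        raise SynthError("gc must be in [0.2, 0.8]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    features: list[GeneFeature] = []

    parts: list[str] = []
    lead = max(50, length // 20)
    parts.append(_random_dna(rng, lead, gc))
    pos = lead  # 0-based length so far

    if rep is not None:
        rep_region_start = pos + 1
        it = rep.iterons
        if it is not None:
            unit = (it.unit or _random_iteron_unit(rng, it.unit_length, gc)).upper()
            copies = [_mutate_copy(rng, unit, it.substitution_prob) for _ in range(it.copies)]
            array_seq = "".join(copies)
            starts = [pos + 1 + i * len(unit) for i in range(it.copies)]
            truth.planted_iterons.append(
                IteronArray(
                    plasmid_id=plasmid_id,
                    unit_length=len(unit),
                    copy_count=it.copies,
                    copy_starts=starts,
                    copies=copies,
                    consensus=build_consensus(copies) if it.copies >= 2 else None,
                    mean_mismatch_frac=0.0,
                    strand="+",
                )
            )
            parts.append(array_seq)
            pos += len(array_seq)
            gap = _random_dna(rng, it.upstream_gap, gc)
            parts.append(gap)
            pos += it.upstream_gap
        orf = _random_orf(rng, rep.gene_length, gc)
        features.append(
            GeneFeature(
                locus_tag=f"{plasmid_id}_rep",
                start=pos + 1,
                end=pos + len(orf),
                strand="+",
                product="replication initiator protein RepB",
                translation=str(Seq(orf[:-3]).translate(table=11)),
            )
        )
        parts.append(orf)
        pos += len(orf)
        region = ModuleRegion(plasmid_id, rep_region_start, pos, "REP")
        truth.module_regions.append(region)
        if rep.site_free:
            planted = "".join(parts)
            head = planted[: rep_region_start - 1]
            body = _scrub_sites(rng, planted[rep_region_start - 1 :], rep.enzymes, gc)
            parts = [head + body]
            # scrubbing may touch iteron copies; refresh truth from sequence
            if it is not None and truth.planted_iterons:
                arr = truth.planted_iterons[-1]
                arr.copies = [
                    (head + body)[s - 1 : s - 1 + arr.unit_length] for s in arr.copy_starts
                ]
                arr.consensus = build_consensus(arr.copies)

    if mob is not None:
        spacer = _random_dna(rng, max(100, length // 30), gc)
        parts.append(spacer)
        pos = sum(len(p) for p in parts)
        orf = _random_orf(rng, mob.gene_length, gc)
        features.append(
            GeneFeature(
                locus_tag=f"{plasmid_id}_mobA",
                start=pos + 1,
                end=pos + len(orf),
                strand="+",
                product="relaxase MobA",
                translation=str(Seq(orf[:-3]).translate(table=11)),
            )
        )
        parts.append(orf)
        pos += len(orf)
        truth.module_regions.append(ModuleRegion(plasmid_id, pos - len(orf) + 1, pos, "MOB"))

    assembled = "".join(parts)
    if len(assembled) > length:
        raise SynthError(
            f"planted modules ({len(assembled)} bp) exceed requested length {length}"
        )
    tail = _random_dna(rng, length - len(assembled), gc)
    # plant requested recognition sites in the tail filler
    if plant_sites:
        tail_list = list(tail)
        offset = len(assembled)
        used: set[int] = set()
        for spec in plant_sites:
            concrete = spec.enzyme.site  # defaults are concrete 6-mers
            positions = []
            for _ in range(spec.count):
                for _try in range(100):
                    p = int(rng.integers(0, len(tail) - len(concrete)))
                    if all(abs(p - u) > len(concrete) for u in used):
                        used.add(p)
                        tail_list[p : p + len(concrete)] = concrete
                        positions.append(offset + p + 1)
                        break
                else:
                    raise SynthError("no room to plant requested sites")
            truth.planted_sites.setdefault(spec.enzyme.name, []).extend(sorted(positions))
        tail = "".join(tail_list)
    record = PlasmidRecord(plasmid_id, assembled + tail, "circular", features)
    return record, truth


# -- proteins ------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _substitute(
    rng: np.random.Generator, seq: str, n_sub: int, mode: str = "identity"
) -> str:
    """Apply *n_sub* point substitutions at distinct positions.

    mode="identity": replacements uniform over the 19 alternatives.
    mode="similarity": replacements restricted to residues scoring <= 0
    against the original in BLOSUM62, so each substitution also removes a
    "positive" from any alignment — used to plant pairs at a target
    percent-similarity rather than percent-identity.
    """
    out = list(seq)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for i in positions:
        orig = out[i]
        if mode == "identity":
            choices = [a for a in AA20 if a != orig]
        else:
            choices = [a for a in AA20 if a != orig and _BLOSUM62[orig, a] <= 0]
        out[i] = rng.choice(choices)
    return "".join(out)


def mutate_to_identity(
    protein: ProteinSeq,
    target_identity: float,
    seed: int = 0,
    mode: str = "identity",
    new_id: str | None = None,
) -> ProteinSeq:
    """Derive a variant at a controlled global identity to *protein*.

    Exactly ``round((1 - target) * length)`` positions are substituted, so
    the realized global identity equals the target to within rounding
    (within three percentage points for proteins of 200 residues or more).
    With mode="similarity" the substituted residues are additionally chosen
    to score non-positively against the originals, making the target govern
    the percent-positives (BLAST similarity) of the pair instead.
    """
    if not 0 < target_identity <= 1:
        raise SynthError("target identity must be in (0, 1]")
    if protein.length < 50:
        raise SynthError("protein too short to mutate controllably (< 50 aa)")
    if mode not in ("identity", "similarity"):
        raise SynthError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_sub = round((1 - target_identity) * protein.length)
    seq = _substitute(rng, protein.sequence, n_sub, mode) if n_sub else protein.sequence
    return ProteinSeq(
        new_id or f"{protein.id}_mut{int(100 * target_identity)}",
        seq,
        protein.plasmid_id,
        protein.strain,
    )


def random_protein(rng_or_seed, length: int) -> str:
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    return "".join(rng.choice(list(AA20), size=length))


def generate_protein_families(
    n_families: int,
    members_per_family: int,
    within_identity: float = 0.85,
    between_identity: float = 0.15,
    length: int = 300,
    seed: int = 0,
) -> tuple[list[ProteinSeq], SyntheticTruth]:
    """Protein families descending from independent random ancestors.

    Two sequences that each substitute a fraction d of their positions
    independently retain pairwise identity (1-d)^2 (plus a 1/19 chance
    coincidence term), so the per-lineage divergence for a pairwise target t
    is d = 1 - sqrt(t). Members diverge that way from their family ancestor
    for ``within_identity``; ``between_identity`` above the random
    background (a few percent) is realized by deriving the ancestors from a
    common root with the same rule. Family labels and pairwise targets are
    recorded as ground truth.
    """
    if not 0 < between_identity < within_identity <= 1:
        raise SynthError("need 0 < between_identity < within_identity <= 1")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    background = 1.0 / len(AA20)
    if between_identity > 0.10:
        root = random_protein(rng, length)
        d_anc = round((1 - math.sqrt(between_identity)) * length)
        ancestors = [_substitute(rng, root, d_anc) for _ in range(n_families)]
    else:
        ancestors = [random_protein(rng, length) for _ in range(n_families)]
    proteins: list[ProteinSeq] = []
    d_mem = round((1 - math.sqrt(within_identity)) * length)
    for fi, anc in enumerate(ancestors):
        fam = f"fam{fi}"
        for mi in range(members_per_family):
            pid = f"{fam}_p{mi}"
            seq = _substitute(rng, anc, d_mem) if d_mem else anc
            proteins.append(ProteinSeq(pid, seq, plasmid_id=f"plasmid_{fi}_{mi}"))
            truth.family_labels[pid] = fam
    for i, p in enumerate(proteins):
        for q in proteins[i + 1 :]:
            same = truth.family_labels[p.id] == truth.family_labels[q.id]
            target = within_identity if same else max(between_identity, background)
            truth.pairwise_identity_targets[f"{p.id}|{q.id}"] = target
    return proteins, truth
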