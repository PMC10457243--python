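"""Restriction-site scanning on circular DNA and module availability screens.

A replicon module is a candidate building block for a cloning vector only if
most multiple-cloning-site (MCS) enzymes do not cut inside it: every enzyme
absent from the module remains available in the vector's MCS. The screen
extracts a (possibly origin-wrapping) module from its circular plasmid,
scans it for each recognition site on both strands, and partitions the
enzyme panel into cutting / non-cutting.

The default panel is the 13 six-cutters common in vector MCS regions. The
extracted module is treated as linear — a cloned fragment is interrupted at
its ends — while circular scanning (sites spanning the origin) is available
for whole-plasmid scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .seqio import ModuleRegion, PlasmidRecord, clean_dna, extract_region, reverse_complement

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class RestrictionError(ValueError):
    pass


@dataclass(frozen=True)
class RestrictionEnzyme:
    """An endonuclease identified by name and IUPAC recognition sequence."""

    name: str
    site: str

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4:
            raise RestrictionError(f"{self.name}: site {site!r} shorter than 4 bp")
        if any(c not in IUPAC_DNA for c in site):
            raise RestrictionError(f"{self.name}: non-IUPAC character in {site!r}")

    @property
    def rc_site(self) -> str:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
                "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B",
                "N": "N"}
        return "".join(comp[c] for c in reversed(self.site))

    @property
    def palindromic(self) -> bool:
        return self.site == self.rc_site


#: The 13 MCS six-cutters screened against every REP module.
MCS_ENZYMES: tuple[RestrictionEnzyme, ...] = tuple(
    RestrictionEnzyme(n, s)
    for n, s in [
        ("BamHI", "GGATCC"), ("EcoRI", "GAATTC"), ("EcoRV", "GATATC"),
        ("HindIII", "AAGCTT"), ("KpnI", "GGTACC"), ("NcoI", "CCATGG"),
        ("NheI", "GCTAGC"), ("PstI", "CTGCAG"), ("SacI", "GAGCTC"),
        ("SalI", "GTCGAC"), ("SphI", "GCATGC"), ("XbaI", "TCTAGA"),
        ("XhoI", "CTCGAG"),
    ]
)


def _iupac_match(seq: str, pos: int, site: str) -> bool:
    for i, code in enumerate(site):
        if seq[pos + i] not in IUPAC_DNA[code]:
            return False
    return True


def scan_sites(seq: str, enzyme: RestrictionEnzyme, circular: bool = False) -> list[int]:
    """All 1-based start positions where the recognition site occurs on
    either strand of *seq*.

    Minus-strand occurrences are reported at the plus-strand start of the
    site's reverse complement, so palindromic sites yield one position per
    physical site. A circular scan additionally matches sites spanning the
    fragment origin (equivalent to scanning ``seq`` extended by its first
    ``len(site) - 1`` bases); reported positions stay within ``len(seq)``.
    """
    seq = clean_dna(seq)
    m = len(enzyme.site)
    if m > len(seq):
        return []
    search = seq + seq[: m - 1] if circular else seq
    hits = set()
    sites = {enzyme.site, enzyme.rc_site}
    for site in sites:
        for p in range(len(search) - m + 1):
            if _iupac_match(search, p, site):
                hits.add(p % len(seq) + 1)
    return sorted(hits)


@dataclass
class ScreenResult:
    """Cutting/non-cutting partition of an enzyme panel over one module."""

    module: ModuleRegion
    cutting: dict[str, list[int]]
    non_cutting: list[str]

    @property
    def available(self) -> int:
        """Number of panel enzymes left available for the vector MCS."""
        return len(self.non_cutting)


def screen_module(
    record: PlasmidRecord,
    region: ModuleRegion,
    enzymes: tuple[RestrictionEnzyme, ...] = MCS_ENZYMES,
) -> ScreenResult:
    """Screen one module region of a plasmid against an enzyme panel.

    The module fragment is extracted (wrapping through the plasmid origin
    when region.start > region.end) and scanned as linear DNA; positions are
    1-based on the extracted fragment, 5'→3' from the region start.
    """
    fragment = extract_region(record, region.start, region.end)
    cutting: dict[str, list[int]] = {}
    non_cutting: list[str] = []
    for enz in enzymes:
        hits = scan_sites(fragment, enz, circular=False)
        if hits:
            cutting[enz.name] = hits
        else:
            non_cutting.append(enz.name)
    return ScreenResult(module=region, cutting=cutting, non_cutting=non_cutting)


def load_enzyme_table(path: str | Path) -> tuple[RestrictionEnzyme, ...]:
    """Read a two-column TSV (name, IUPAC site); '#' lines are comments."""
    enzymes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise RestrictionError(f"bad enzyme line: {line!r}")
        enzymes.append(RestrictionEnzyme(parts[0], parts[1]))
    if not enzymes:
        raise RestrictionError(f"no enzymes in {path}")
    return tuple(enzymes)
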