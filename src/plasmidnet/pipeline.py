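"""End-to-end replicon characterization and reporting.

For a set of plasmid records the pipeline (i) classifies annotated proteins
against labeled reference sets when provided, (ii) hunts for tandem iteron
arrays upstream of each replication-initiator gene, (iii) screens module
regions for restriction-site availability, and (iv) builds the reciprocated
protein-similarity network, then emits a per-replicon summary table, a
screen table, and network family counts, all deterministically for fixed
inputs and parameters.

Reference values for the Psychrobacter sp. ANT_H3 plasmid set (sizes, GC,
module inventories, REP-module coordinates and iteron consensus strings)
ship as packaged TSVs and can seed a synthetic look-alike of that study
set for pipeline exercises without any downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .iterons import IteronArray, find_iteron_arrays_both_strands, upstream_window
from .protnet import ProteinSeq, SimilarityNetwork, build_network, classify_protein
from .restriction import MCS_ENZYMES, RestrictionEnzyme, ScreenResult, screen_module
from .seqio import ModuleRegion, PlasmidRecord, gc_content
from .synth import IteronSpec, MobModuleSpec, RepModuleSpec, generate_plasmid


@dataclass
class PipelineParams:
    """All thresholds of the characterization run, with study defaults."""

    evalue_max: float = 1e-10
    identity_min: float = 0.30
    coverage_min: float = 0.90
    classify_evalue_max: float = 1e-2
    iteron_window: int = 500
    iteron_unit_range: tuple[int, int] = (18, 24)
    iteron_min_copies: int = 3
    iteron_max_mismatch: float = 0.15
    iteron_max_spacer: int = 0
    region_flank: int = 300  # inferred-module flank when no region file given
    enzymes: tuple[RestrictionEnzyme, ...] = MCS_ENZYMES

    def provenance(self) -> dict:
        return {
            "tool_version": __version__,
            "evalue_max": self.evalue_max,
            "identity_min": self.identity_min,
            "coverage_min": self.coverage_min,
            "classify_evalue_max": self.classify_evalue_max,
            "iteron_window": self.iteron_window,
            "iteron_unit_range": list(self.iteron_unit_range),
            "iteron_min_copies": self.iteron_min_copies,
            "iteron_max_mismatch": self.iteron_max_mismatch,
            "region_flank": self.region_flank,
            "enzymes": [e.name for e in self.enzymes],
        }


@dataclass
class RepliconReport:
    """Aggregated output of one characterization run."""

    rows: pd.DataFrame  # per-plasmid summary
    screens: list[ScreenResult]
    iterons: list[IteronArray]
    network: SimilarityNetwork | None
    protein_labels: dict[str, str]
    family_counts: dict[str, int]
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "report.tsv", sep="\t", index=False)
        screen_rows = [
            {
                "plasmid": s.module.plasmid_id,
                "label": s.module.label,
                "start": s.module.start,
                "end": s.module.end,
                "n_available": s.available,
                "non_cutting": ",".join(s.non_cutting),
                "cutting": ",".join(sorted(s.cutting)),
            }
            for s in self.screens
        ]
        pd.DataFrame(screen_rows).to_csv(out / "screen.tsv", sep="\t", index=False)
        it_rows = [
            {
                "plasmid": a.plasmid_id,
                "start": a.start,
                "unit_length": a.unit_length,
                "copies": a.copy_count,
                "consensus": a.consensus.render(),
                "mismatch_frac": round(a.mean_mismatch_frac, 4),
                "strand": a.strand,
            }
            for a in self.iterons
        ]
        pd.DataFrame(
            it_rows,
            columns=["plasmid", "start", "unit_length", "copies", "consensus",
                     "mismatch_frac", "strand"],
        ).to_csv(out / "iterons.tsv", sep="\t", index=False)
        summary = {
            "n_plasmids": int(len(self.rows)),
            "network": None
            if self.network is None
            else {
                "nodes": self.network.n_nodes,
                "edges": self.network.n_edges,
                "components": len(self.network.components),
            },
            "family_counts": self.family_counts,
            "provenance": self.provenance,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
        if self.network is not None:
            from .seqio import write_network

            write_network(self.network, out / "network.graphml", "graphml")


REP_PRODUCT_WORDS = ("replication", "repb", "repa", "rep_1", "rep63", "initiator")
MOB_PRODUCT_WORDS = ("relaxase", "moba", "mobiliz", "mobc")


def _proteins_of(records: list[PlasmidRecord]) -> list[ProteinSeq]:
    prots = []
    for rec in records:
        for f in rec.features:
            if f.translation:
                prots.append(ProteinSeq(f"{rec.id}|{f.locus_tag}", f.translation, rec.id))
    return prots


def _rep_features(record: PlasmidRecord):
    for f in record.features:
        if any(w in f.product.lower() for w in REP_PRODUCT_WORDS):
            yield f


def run_characterization(
    records: list[PlasmidRecord],
    references: dict[str, list[ProteinSeq]] | None = None,
    regions: list[ModuleRegion] | None = None,
    params: PipelineParams | None = None,
) -> RepliconReport:
    """Characterize a set of plasmid replicons end to end.

    Module regions for the restriction screen come from *regions* when
    given; otherwise each rep-annotated gene ± ``region_flank`` bp is
    screened. Failures of individual stages on individual replicons are
    recorded in the report rather than aborting the run.
    """
    if not records:
        raise ValueError("need at least one record")
    params = params or PipelineParams()
    references = references or {}
    errors: dict[str, str] = {}

    # protein classification
    labels: dict[str, str] = {}
    proteins = _proteins_of(records)
    if references:
        for p in proteins:
            try:
                labels[p.id] = classify_protein(p, references, params.classify_evalue_max)
            except Exception as exc:  # pragma: no cover - defensive
                labels[p.id] = "unclassified"
                errors[p.id] = str(exc)
    else:
        labels = {p.id: "unclassified" for p in proteins}

    # iteron hunt upstream of rep genes
    iterons: list[IteronArray] = []
    for rec in records:
        for repf in _rep_features(rec):
            try:
                window = upstream_window(rec, repf, params.iteron_window)
                found = find_iteron_arrays_both_strands(
                    window,
                    params.iteron_unit_range,
                    params.iteron_min_copies,
                    params.iteron_max_mismatch,
                    params.iteron_max_spacer,
                    plasmid_id=rec.id,
                )
                iterons.extend(found)
            except Exception as exc:
                errors[f"{rec.id}:iterons"] = str(exc)

    # restriction screen
    screens: list[ScreenResult] = []
    by_id = {r.id: r for r in records}
    screen_regions = list(regions) if regions else []
    if not screen_regions:
        for rec in records:
            for repf in _rep_features(rec):
                n = rec.length
                start = (repf.start - 1 - params.region_flank) % n + 1 if rec.circular else max(
                    1, repf.start - params.region_flank
                )
                end = (repf.end - 1 + params.region_flank) % n + 1 if rec.circular else min(
                    n, repf.end + params.region_flank
                )
                screen_regions.append(ModuleRegion(rec.id, start, end, "REP"))
    for region in screen_regions:
        rec = by_id.get(region.plasmid_id)
        if rec is None:
            errors[f"{region.plasmid_id}:screen"] = "region names unknown plasmid"
            continue
        try:
            screens.append(screen_module(rec, region, params.enzymes))
        except Exception as exc:
            errors[f"{region.plasmid_id}:screen"] = str(exc)

    # similarity network
    network = None
    if proteins:
        network = build_network(
            proteins,
            params.evalue_max,
            params.identity_min,
            params.coverage_min,
        )

    rows = pd.DataFrame(
        [
            {
                "plasmid": rec.id,
                "size_bp": rec.length,
                "gc_pct": gc_content(rec.sequence),
                "n_genes": len(rec.features),
                "modules": ",".join(
                    sorted(
                        {r.label for r in screen_regions if r.plasmid_id == rec.id}
                        | ({"MOB"} if any(
                            any(w in f.product.lower() for w in MOB_PRODUCT_WORDS)
                            for f in rec.features
                        ) else set())
                    )
                )
                or "unclassified",
            }
            for rec in records
        ]
    )
    family_counts = count_families(network, labels, proteins) if network else {}
    prov = params.provenance()
    if errors:
        prov["stage_errors"] = errors
    return RepliconReport(rows, screens, iterons, network, labels, family_counts, prov)


def count_families(
    net: SimilarityNetwork,
    labels: dict[str, str],
    proteins: list[ProteinSeq] | None = None,
) -> dict[str, int]:
    """Count plasmids (not proteins) per classified family.

    A composite replicon carrying proteins of two families counts once in
    each. Proteins absent from *labels* count as "unclassified".
    """
    plasmid_of: dict[str, str] = {}
    if proteins:
        plasmid_of = {p.id: p.plasmid_id for p in proteins}
    else:
        plasmid_of = {n: d.get("plasmid", "") for n, d in net.graph.nodes(data=True)}
    seen: dict[str, set[str]] = {}
    for node in net.graph.nodes:
        fam = labels.get(node, "unclassified")
        seen.setdefault(fam, set()).add(plasmid_of.get(node, node))
    return {fam: len(plasmids) for fam, plasmids in sorted(seen.items())}


# -- packaged study-set data ---------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("plasmidnet") / "data" / name)


def load_ant_h3_table() -> pd.DataFrame:
    """Published per-plasmid features of the ANT_H3 set (size, GC, genes)."""
    return pd.read_csv(
        _data_path("ant_h3_plasmids.tsv"),
        sep="\t",
        comment="#",
        names=["plasmid", "accession", "size_bp", "gc_pct", "n_genes", "modules"],
    )


def load_ant_h3_regions() -> list[ModuleRegion]:
    """Published REP-module coordinates of the ANT_H3 set (origin-wrapping)."""
    df = pd.read_csv(
        _data_path("ant_h3_rep_regions.tsv"),
        sep="\t",
        comment="#",
        names=["plasmid", "accession", "start", "end", "label", "non_cutting"],
    )
    return [
        ModuleRegion(r.plasmid, int(r.start), int(r.end), r.label)
        for r in df.itertuples()
    ]


def load_ant_h3_region_table() -> pd.DataFrame:
    return pd.read_csv(
        _data_path("ant_h3_rep_regions.tsv"),
        sep="\t",
        comment="#",
        names=["plasmid", "accession", "start", "end", "label", "non_cutting"],
    )


def load_ant_h3_iterons() -> pd.DataFrame:
    """Published iteron consensus strings of the ANT_H3 oriV regions."""
    return pd.read_csv(
        _data_path("ant_h3_iterons.tsv"),
        sep="\t",
        comment="#",
        names=["plasmid", "unit_bp", "copies", "consensus"],
    )


def build_ant_h3_like_set(seed: int = 0) -> tuple[list[PlasmidRecord], list]:
    """Synthetic look-alike of the ANT_H3 plasmid set.

    Eleven circular plasmids with the published sizes and GC contents, each
    carrying a rep gene with a four-copy tandem iteron array (the published
    unit lengths per plasmid) and, where the published module inventory says
    so, a mob gene. Returns (records, truths).
    """
    table = load_ant_h3_table()
    iteron_units = dict(zip(load_ant_h3_iterons().plasmid, load_ant_h3_iterons().unit_bp))
    records, truths = [], []
    for i, row in enumerate(table.itertuples()):
        unit_bp = int(iteron_units.get(row.plasmid, 22))
        rep = RepModuleSpec(
            gene_length=900,
            iterons=IteronSpec(unit_length=unit_bp, copies=4, substitution_prob=0.0),
        )
        mob = MobModuleSpec() if "MOB" in row.modules else None
        rec, truth = generate_plasmid(
            length=int(row.size_bp),
            gc=float(row.gc_pct) / 100,
            rep=rep,
            mob=mob,
            seed=seed * 1000 + i,
            plasmid_id=row.plasmid,
        )
        records.append(rec)
        truths.append(truth)
    return records, truths
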