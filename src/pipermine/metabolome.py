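"""Multi-source composite metabolome ("meta-metabolome") assembly.

Published knowledge of a medicinal species' secondary metabolites is
scattered over literature compilations, chemical databases and individual
extraction studies, each reporting partially overlapping compound lists under
inconsistent identifiers.  This module merges per-source compound lists into
one reconciled compound set, keeps a per-source presence matrix, assigns each
compound to one of eight phytochemical class bins, and produces the
provenance table (study → extraction method → solvent → compound) that feeds
Sankey-style renderings.

The eight bins: alkaloid, benzenoid, terpene, cinnamic acid, flavonoid,
kavalactone, chalcone, and miscellaneous (the total fallback).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import CompoundRecord, reconcile_compounds

logger = logging.getLogger(__name__)

CLASS_BINS = (
    "alkaloid", "benzenoid", "terpene", "cinnamic acid",
    "flavonoid", "kavalactone", "chalcone", "miscellaneous",
)

SOURCE_KINDS = ("literature-compilation", "database", "extraction-study")


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class SourceRecord:
    """Provenance of one compound list (a study, database or compilation)."""

    source_id: str
    source_kind: str
    extraction_method: str | None = None
    solvent: str | None = None

    def __post_init__(self) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise AssemblyError(
                f"source {self.source_id!r}: unknown kind {self.source_kind!r}"
            )


@dataclass
class ClassMap:
    """Two-layer classification rule: identifier overrides, then keywords.

    ``overrides`` maps a compound identifier (InChIKey, CID string or
    normalised name) straight to a bin; ``keywords`` are (substring, bin)
    rules applied case-insensitively to the source-supplied class string.
    Anything unmatched falls through to ``miscellaneous``.
    """

    overrides: dict[str, str] = field(default_factory=dict)
    keywords: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def default(cls) -> "ClassMap":
        ref = resources.files("pipermine.data") / "class_map.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassMap":
        overrides: dict[str, str] = {}
        keywords: list[tuple[str, str]] = []
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                bin_ = row["bin"].strip()
                if bin_ not in CLASS_BINS:
                    raise AssemblyError(f"unknown class bin {bin_!r}")
                if row["match_kind"].strip() == "id":
                    overrides[row["pattern_or_id"].strip()] = bin_
                else:
                    keywords.append((row["pattern_or_id"].strip().lower(), bin_))
        return cls(overrides=overrides, keywords=keywords)


def classify_compound(record: CompoundRecord, class_map: ClassMap) -> str:
    """Assign one compound to a phytochemical class bin.

    Identifier-level overrides win over keyword rules on the raw class
    string; an unmatched compound is miscellaneous.
    """
    for ident in (record.inchikey, str(record.cid) if record.cid else None,
                  record.name, record.compound_key):
        if ident and ident in class_map.overrides:
            return class_map.overrides[ident]
    raw = (record.chem_class_raw or "").lower()
    if raw:
        for keyword, bin_ in class_map.keywords:
            if keyword in raw:
                return bin_
    return "miscellaneous"


@dataclass
class MetaMetabolome:
    species: str
    compounds: dict[str, CompoundRecord]
    presence: dict[tuple[str, str], bool]  # (compound_key, source_id)
    class_bins: dict[str, str]
    sources: dict[str, SourceRecord]

    @property
    def class_tally(self) -> dict[str, int]:
        tally = {b: 0 for b in CLASS_BINS}
        for bin_ in self.class_bins.values():
            tally[bin_] += 1
        return tally

    @property
    def total(self) -> int:
        return len(self.compounds)


def assemble_meta_metabolome(
    species: str,
    source_tables: Mapping[SourceRecord, Iterable[CompoundRecord]],
    class_map: ClassMap | None = None,
) -> MetaMetabolome:
    """Merge per-source compound lists into one reconciled metabolome.

    Compounds are reconciled across sources by identifier precedence
    (InChIKey, then CID, then normalised name); the presence matrix records
    which sources report each merged compound.  Within-source duplicates
    count once — the unit is the compound, not the report.
    """
    if class_map is None:
        class_map = ClassMap.default()
    sources = {src.source_id: src for src in source_tables}
    flat: list[CompoundRecord] = []
    origin: list[str] = []
    for src, records in source_tables.items():
        for rec in records:
            flat.append(rec)
            origin.append(src.source_id)
    if not flat:
        raise AssemblyError(f"no compounds supplied for {species!r}")

    assignment, merged, conflicts = reconcile_compounds(flat)
    for msg in conflicts:
        logger.warning("meta-metabolome %s: %s", species, msg)

    presence: dict[tuple[str, str], bool] = {}
    for i, source_id in enumerate(origin):
        presence[(assignment[i], source_id)] = True

    class_bins = {
        key: classify_compound(rec, class_map) for key, rec in merged.items()
    }
    return MetaMetabolome(
        species=species,
        compounds=merged,
        presence=presence,
        class_bins=class_bins,
        sources=sources,
    )


def solvent_provenance_table(meta: MetaMetabolome) -> pd.DataFrame:
    """(source_id, extraction_method, solvent, compound_key) rows.

    Only extraction-study sources appear — one row per (study, compound)
    pair.  This long table is the input for Sankey-style provenance plots.
    """
    rows = []
    for (compound_key, source_id), present in meta.presence.items():
        if not present:
            continue
        src = meta.sources[source_id]
        if src.source_kind != "extraction-study":
            continue
        rows.append(
            (source_id, src.extraction_method or "", src.solvent or "",
             compound_key)
        )
    return pd.DataFrame(
        sorted(rows),
        columns=["source_id", "extraction_method", "solvent", "compound_key"],
    )


def metabolome_tables(meta: MetaMetabolome) -> dict[str, pd.DataFrame]:
    """Interchange tables: compound list with bins, and presence matrix."""
    compounds = pd.DataFrame(
        sorted(
            (key, rec.name or "", meta.class_bins[key])
            for key, rec in meta.compounds.items()
        ),
        columns=["compound_key", "name", "bin"],
    )
    presence = pd.DataFrame(
        sorted((ck, sid) for (ck, sid), p in meta.presence.items() if p),
        columns=["compound_key", "source_id"],
    )
    return {"meta_metabolome": compounds, "presence": presence}


def read_source_tables(
    sources_csv: str | Path, compounds_dir: str | Path
) -> dict[SourceRecord, list[CompoundRecord]]:
    """Load a sources.csv metadata table plus per-source compound CSVs.

    ``sources.csv`` columns: source_id, source_kind, extraction_method,
    solvent, file.  Each referenced file needs a compound_key column and may
    carry name/cid/inchikey/smiles/chem_class_raw columns.
    """
    compounds_dir = Path(compounds_dir)
    out: dict[SourceRecord, list[CompoundRecord]] = {}
    meta = pd.read_csv(sources_csv, dtype=str, keep_default_na=False)
    for _, row in meta.iterrows():
        src = SourceRecord(
            source_id=row["source_id"],
            source_kind=row["source_kind"],
            extraction_method=row.get("extraction_method") or None,
            solvent=row.get("solvent") or None,
        )
        table = pd.read_csv(
            compounds_dir / row["file"], dtype=str, keep_default_na=False
        )
        records = []
        for _, c in table.iterrows():
            records.append(
                CompoundRecord(
                    compound_key=c.get("compound_key", "") or f"row{len(records)}",
                    name=c.get("name") or None,
                    cid=int(c["cid"]) if c.get("cid") else None,
                    inchikey=c.get("inchikey") or None,
                    smiles=c.get("smiles") or None,
                    chem_class_raw=c.get("chem_class_raw") or None,
                )
            )
        out[src] = records
    return out
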