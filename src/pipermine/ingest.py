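"""Loading and normalisation of traditional-medicine formula tables.

Pharmacopeia exports arrive as flat delimited tables in which each row ties a
formula to one ingredient species, optionally to compounds reported for that
species, and to free-text indication strings.  This module turns such tables
into a canonical in-memory dataset (formulas, species, compounds and their
links), reconciles compound identities across identifier systems, and
round-trips the dataset through a directory of long-format CSV tables that all
downstream analyses consume.

Compound attribution follows the any-member-species rule: a formula contains a
compound whenever at least one of its ingredient species is linked to that
compound.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: genus treated as the focal genus throughout the analyses
TARGET_GENUS = "Piper"


class IngestError(ValueError):
    """Fatal configuration or validation problem during ingestion."""


@dataclass(frozen=True)
class SpeciesRecord:
    """A normalised binomial with its genus split out."""

    scientific_name: str
    genus: str

    @property
    def is_target_genus(self) -> bool:
        return self.genus == TARGET_GENUS


@dataclass
class CompoundRecord:
    """One chemical entity under a canonical key.

    At least one of ``name``/``cid``/``inchikey``/``smiles`` must be present;
    an InChIKey, when given, must match the standard 14-10-1 block pattern.
    """

    compound_key: str
    name: str | None = None
    cid: int | None = None
    inchikey: str | None = None
    smiles: str | None = None
    chem_class_raw: str | None = None

    def __post_init__(self) -> None:
        if not any([self.name, self.cid, self.inchikey, self.smiles]):
            raise IngestError(
                f"compound {self.compound_key!r}: no identifier present"
            )
        if self.inchikey and not _INCHIKEY_RE.match(self.inchikey):
            raise IngestError(
                f"compound {self.compound_key!r}: malformed InChIKey "
                f"{self.inchikey!r}"
            )


@dataclass
class FormulaRecord:
    """One traditional-medicine formula.

    ``species`` is the set of normalised ingredient binomials; ``indications``
    keeps the raw free-text strings in input order (duplicates dropped).  A
    formula with no indications is retained — it still contributes to species
    and compound counts — but can never match an indication category.
    """

    formula_id: str
    txm_system: str = ""
    region: str = ""
    species: set[str] = field(default_factory=set)
    indications: list[str] = field(default_factory=list)


@dataclass
class LoadReport:
    rows_read: int = 0
    rows_rejected: int = 0
    rejected_details: list[str] = field(default_factory=list)
    n_formulas: int = 0
    n_species: int = 0
    n_compounds: int = 0
    unmapped_regions: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class Dataset:
    """Canonical container for one ingested pharmacopeia dataset."""

    formulas: dict[str, FormulaRecord] = field(default_factory=dict)
    species: dict[str, SpeciesRecord] = field(default_factory=dict)
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    #: species scientific_name -> set of compound_keys
    species_compounds: dict[str, set[str]] = field(default_factory=dict)
    report: LoadReport = field(default_factory=LoadReport)

    # -- derived views -----------------------------------------------------
    def formula_compounds(self, formula_id: str) -> set[str]:
        """Compounds attributed to a formula via any member species."""
        formula = self.formulas[formula_id]
        out: set[str] = set()
        for sp in formula.species:
            out |= self.species_compounds.get(sp, set())
        return out

    def compound_species(self, compound_key: str) -> set[str]:
        """Distinct species linked to a compound."""
        if compound_key not in self.compounds:
            raise KeyError(f"unknown compound {compound_key!r}")
        return {
            sp
            for sp, keys in self.species_compounds.items()
            if compound_key in keys
        }

    def compound_formulas(self, compound_key: str) -> set[str]:
        species = self.compound_species(compound_key)
        return {
            fid
            for fid, f in self.formulas.items()
            if f.species & species
        }

    def add_species(self, scientific_name: str) -> SpeciesRecord:
        rec = self.species.get(scientific_name)
        if rec is None:
            genus = scientific_name.split()[0]
            rec = SpeciesRecord(scientific_name, genus)
            self.species[scientific_name] = rec
            self.species_compounds.setdefault(scientific_name, set())
        return rec

    def link(self, species_name: str, compound_key: str) -> None:
        self.add_species(species_name)
        self.species_compounds[species_name].add(compound_key)

    def __eq__(self, other: object) -> bool:  # report excluded on purpose
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.formulas == other.formulas
            and self.species == other.species
            and self.compounds == other.compounds
            and {k: v for k, v in self.species_compounds.items() if v}
            == {k: v for k, v in other.species_compounds.items() if v}
        )


@dataclass
class IngestConfig:
    """How to read one delimited pharmacopeia export.

    ``columns`` maps canonical names (``formula_id``, ``txm_system``,
    ``region``, ``species``, ``compound``, ``cid``, ``inchikey``, ``smiles``,
    ``chem_class``, ``indications``) onto the file's header names.  Multi-value
    cells (compounds, indications) are split on ``list_separator``.
    """

    delimiter: str = "\t"
    columns: Mapping[str, str] = field(default_factory=dict)
    list_separator: str = ";"
    synonyms: Mapping[str, str] = field(default_factory=dict)
    region_map: Mapping[str, str] = field(default_factory=dict)

    REQUIRED = ("formula_id", "species")

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def normalize_species_name(
    raw: str, synonyms: Mapping[str, str] | None = None
) -> str:
    """Reduce a raw species string to a clean ``Genus epithet`` binomial.

    Authority strings ("G. Forst.") and infraspecific ranks beyond the
    binomial are stripped, whitespace collapsed, genus capitalised and epithet
    lowercased.  An optional synonym table is applied after normalisation.
    """
    if not raw or not raw.strip():
        raise IngestError("empty species name")
    tokens = raw.split()
    genus = tokens[0].strip().capitalize()
    parts = [genus]
    if len(tokens) > 1:
        epithet = tokens[1].strip().lower()
        # an authority abbreviation directly after the genus is not an epithet
        if epithet.rstrip(".").isalpha() and "." not in tokens[1]:
            parts.append(epithet)
    name = " ".join(parts)
    if synonyms:
        name = synonyms.get(name, name)
    return name


def _normalize_compound_name(name: str) -> str:
    """Case-fold and collapse punctuation/whitespace for name matching."""
    folded = name.casefold()
    folded = re.sub(r"[^\w]+", " ", folded)
    return " ".join(folded.split())


def reconcile_compounds(
    records: Iterable[CompoundRecord],
) -> tuple[dict[int, str], dict[str, CompoundRecord], list[str]]:
    """Merge raw compound records into canonical compounds.

    Two records merge iff they share an InChIKey; failing that, iff both lack
    an InChIKey and share a CID; failing that, iff both lack InChIKey and CID
    and their normalised names agree.  InChIKey is the most structure-specific
    identifier, so it takes precedence; records holding conflicting CIDs under
    one InChIKey are merged under the InChIKey with the conflict logged.

    Returns ``(assignment, merged, conflicts)`` where ``assignment`` maps the
    positional index of each input record to its canonical compound_key.
    """
    records = list(records)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(records):
        if rec.inchikey:
            key = ("inchikey", rec.inchikey)
        elif rec.cid is not None:
            key = ("cid", str(rec.cid))
        elif rec.name:
            key = ("name", _normalize_compound_name(rec.name))
        else:
            key = ("smiles", rec.smiles or "")
        groups.setdefault(key, []).append(i)

    assignment: dict[int, str] = {}
    merged: dict[str, CompoundRecord] = {}
    conflicts: list[str] = []
    for (kind, value), members in sorted(groups.items()):
        member_recs = [records[i] for i in members]
        canonical = _merge_group(kind, value, member_recs, conflicts)
        merged[canonical.compound_key] = canonical
        for i in members:
            assignment[i] = canonical.compound_key
    return assignment, merged, conflicts


def _merge_group(
    kind: str,
    value: str,
    members: Sequence[CompoundRecord],
    conflicts: list[str],
) -> CompoundRecord:
    def first(attr: str):
        vals = [getattr(r, attr) for r in members if getattr(r, attr) is not None]
        distinct = sorted({str(v) for v in vals})
        if len(distinct) > 1:
            conflicts.append(
                f"{kind}={value}: conflicting {attr} values {distinct}; "
                f"keeping {vals[0]!r}"
            )
        return vals[0] if vals else None

    name = first("name")
    cid = first("cid")
    inchikey = first("inchikey")
    smiles = first("smiles")
    chem_class = first("chem_class_raw")
    if kind == "inchikey":
        key = value
    elif kind == "cid":
        key = f"CID{value}"
    else:
        key = _normalize_compound_name(name) if name else value
    return CompoundRecord(
        compound_key=key,
        name=name,
        cid=int(cid) if cid is not None else None,
        inchikey=inchikey,
        smiles=smiles,
        chem_class_raw=chem_class,
    )


def load_formula_table(path: str | Path, config: IngestConfig) -> Dataset:
    """Read one delimited formula table into a canonical :class:`Dataset`.

    One :class:`FormulaRecord` is produced per distinct ``formula_id``; rows
    lacking a formula id are rejected and counted in the load report.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=config.delimiter)
        header = reader.fieldnames or []
        for canonical in IngestConfig.REQUIRED:
            if config.column(canonical) not in header:
                raise IngestError(
                    f"required column {config.column(canonical)!r} "
                    f"(canonical {canonical!r}) missing from {path.name}"
                )
        rows = list(reader)

    ds = Dataset()
    raw_compounds: list[CompoundRecord] = []
    compound_rows: list[tuple[int, str]] = []  # (raw index, species)
    report = ds.report

    def cell(row: dict, canonical: str) -> str:
        return (row.get(config.column(canonical)) or "").strip()

    for lineno, row in enumerate(rows, start=2):
        report.rows_read += 1
        fid = cell(row, "formula_id")
        if not fid:
            report.rows_rejected += 1
            report.rejected_details.append(f"line {lineno}: missing formula_id")
            continue
        try:
            species_name = normalize_species_name(
                cell(row, "species"), config.synonyms
            )
        except IngestError as exc:
            report.rows_rejected += 1
            report.rejected_details.append(f"line {lineno}: {exc}")
            continue

        region = cell(row, "region")
        if region and config.region_map:
            mapped = config.region_map.get(region)
            if mapped is None:
                if region not in report.unmapped_regions:
                    report.unmapped_regions.append(region)
                    logger.warning("region %r has no ISO 3166 mapping", region)
            else:
                region = mapped

        formula = ds.formulas.setdefault(fid, FormulaRecord(formula_id=fid))
        if not formula.txm_system:
            formula.txm_system = cell(row, "txm_system")
        if not formula.region:
            formula.region = region
        formula.species.add(species_name)
        ds.add_species(species_name)

        for indication in _split(cell(row, "indications"), config.list_separator):
            if indication not in formula.indications:
                formula.indications.append(indication)

        names = _split(cell(row, "compound"), config.list_separator)
        cids = _split(cell(row, "cid"), config.list_separator)
        inchikeys = _split(cell(row, "inchikey"), config.list_separator)
        smiles_list = _split(cell(row, "smiles"), config.list_separator)
        classes = _split(cell(row, "chem_class"), config.list_separator)
        n = max(len(names), len(cids), len(inchikeys), len(smiles_list))
        for j in range(n):
            try:
                rec = CompoundRecord(
                    compound_key=f"raw{len(raw_compounds)}",
                    name=_at(names, j),
                    cid=int(_at(cids, j)) if _at(cids, j) else None,
                    inchikey=_at(inchikeys, j),
                    smiles=_at(smiles_list, j),
                    chem_class_raw=_at(classes, j),
                )
            except (IngestError, ValueError) as exc:
                report.rows_rejected += 1
                report.rejected_details.append(f"line {lineno}: {exc}")
                continue
            compound_rows.append((len(raw_compounds), species_name))
            raw_compounds.append(rec)

    assignment, merged, conflicts = reconcile_compounds(raw_compounds)
    for msg in conflicts:
        logger.warning("compound reconciliation: %s", msg)
    ds.compounds = merged
    for idx, species_name in compound_rows:
        ds.link(species_name, assignment[idx])

    report.n_formulas = len(ds.formulas)
    report.n_species = len(ds.species)
    report.n_compounds = len(ds.compounds)
    logger.info(
        "loaded %s: %d rows, %d rejected, %d formulas / %d species / %d compounds",
        path.name, report.rows_read, report.rows_rejected,
        report.n_formulas, report.n_species, report.n_compounds,
    )
    return ds


def _split(value: str, sep: str) -> list[str]:
    return [v.strip() for v in value.split(sep) if v.strip()] if value else []


def _at(items: list[str], j: int) -> str | None:
    return items[j] if j < len(items) else None


# ---------------------------------------------------------------------------
# interchange directory (the contract consumed by every downstream module)
# ---------------------------------------------------------------------------

_TABLES = (
    "formulas", "formula_species", "species_compounds",
    "formula_indications", "compounds",
)


def write_dataset(ds: Dataset, outdir: str | Path) -> Path:
    """Serialise a dataset as a directory of long-format CSV tables.

    Rows are written in sorted order so identical datasets always serialise to
    identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        sorted(
            (f.formula_id, f.txm_system, f.region)
            for f in ds.formulas.values()
        ),
        columns=["formula_id", "txm_system", "region"],
    ).to_csv(outdir / "formulas.csv", index=False)

    pd.DataFrame(
        sorted(
            (f.formula_id, sp)
            for f in ds.formulas.values()
            for sp in f.species
        ),
        columns=["formula_id", "species"],
    ).to_csv(outdir / "formula_species.csv", index=False)

    pd.DataFrame(
        sorted(
            (sp, ck)
            for sp, keys in ds.species_compounds.items()
            for ck in keys
        ),
        columns=["species", "compound_key"],
    ).to_csv(outdir / "species_compounds.csv", index=False)

    pd.DataFrame(
        sorted(
            (f.formula_id, i, text)
            for f in ds.formulas.values()
            for i, text in enumerate(f.indications)
        ),
        columns=["formula_id", "position", "indication"],
    ).to_csv(outdir / "formula_indications.csv", index=False)

    pd.DataFrame(
        sorted(
            (c.compound_key, c.name or "", c.cid if c.cid is not None else "",
             c.inchikey or "", c.smiles or "", c.chem_class_raw or "")
            for c in ds.compounds.values()
        ),
        columns=["compound_key", "name", "cid", "inchikey", "smiles",
                 "chem_class_raw"],
    ).to_csv(outdir / "compounds.csv", index=False)

    (outdir / "load_report.json").write_text(ds.report.to_json() + "\n")
    return outdir


def load_dataset(indir: str | Path) -> Dataset:
    """Load a dataset previously written by :func:`write_dataset`."""
    indir = Path(indir)
    for name in _TABLES:
        if not (indir / f"{name}.csv").exists():
            raise IngestError(f"interchange table {name}.csv missing in {indir}")

    def read(name: str) -> pd.DataFrame:
        return pd.read_csv(indir / f"{name}.csv", dtype=str, keep_default_na=False)

    ds = Dataset()
    for _, row in read("formulas").iterrows():
        ds.formulas[row.formula_id] = FormulaRecord(
            formula_id=row.formula_id,
            txm_system=row.txm_system,
            region=row.region,
        )
    for _, row in read("formula_species").iterrows():
        ds.formulas[row.formula_id].species.add(row.species)
        ds.add_species(row.species)
    fi = read("formula_indications")
    if len(fi):
        fi["position"] = fi["position"].astype(int)
        for fid, grp in fi.sort_values(["formula_id", "position"]).groupby(
            "formula_id", sort=False
        ):
            ds.formulas[fid].indications = list(grp["indication"])
    for _, row in read("compounds").iterrows():
        ds.compounds[row.compound_key] = CompoundRecord(
            compound_key=row.compound_key,
            name=row["name"] or None,
            cid=int(row.cid) if row.cid else None,
            inchikey=row.inchikey or None,
            smiles=row.smiles or None,
            chem_class_raw=row.chem_class_raw or None,
        )
    for _, row in read("species_compounds").iterrows():
        ds.link(row.species, row.compound_key)
    ds.report.n_formulas = len(ds.formulas)
    ds.report.n_species = len(ds.species)
    ds.report.n_compounds = len(ds.compounds)
    return ds
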