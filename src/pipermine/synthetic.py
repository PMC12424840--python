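"""Synthetic pharmacopeia datasets and molecule panels with known ground truth.

Real pharmacopeia exports cannot be redistributed, so every pipeline stage is
exercised on generated data whose true structure is stored alongside it:

* :func:`generate_gims_dataset` emits a formula/species/compound dataset with
  per-category prevalences, planted compound–category association uplifts and
  an indication phrase bank whose phrases are guaranteed to match (or, for
  decoys, not match) the packaged term dictionary;
* :func:`generate_molecule_panel` enumerates valid molecules from a packaged
  fragment library and labels them with a documented linear function of their
  descriptors plus seeded Gaussian noise, on the NP-likeness scale;
* :func:`generate_source_tables` builds per-source compound lists with a known
  compound partition and class-bin sizes, for metabolome-assembly tests.

Every draw comes from one :class:`numpy.random.Generator` seeded from the
spec, so a fixed seed reproduces identical datasets byte for byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger

from .dictionary import CATEGORIES
from .ingest import CompoundRecord, Dataset, FormulaRecord
from .metabolome import CLASS_BINS, SourceRecord

RDLogger.DisableLog("rdApp.*")


# ---------------------------------------------------------------------------
# indication phrase bank
# ---------------------------------------------------------------------------

#: phrases that match exactly one dictionary category (whole-token semantics)
POSITIVE_PHRASES: dict[str, tuple[str, ...]] = {
    "Anxiety/Mood": (
        "anxiety and worry", "agitated mood", "panic and fear",
        "for depression", "nervousness of the heart",
    ),
    "Movement/Seizure": (
        "seizure disorder", "muscle spasm", "trembling limbs",
        "epileptic fits", "tremor of the hands",
    ),
    "Pain": (
        "chronic headache", "joint pain", "myalgia of the back",
        "aching joints", "rheumatism",
    ),
    "Sleep": (
        "insomnia", "sedative tonic", "promotes sleep",
        "hypnotic remedy", "soporific draught",
    ),
}

#: phrases matching no category; several are near-miss traps that pin the
#: whole-token matching rule ("benefits" vs literal "fits", "calmness" vs
#: literal "calm", "restlessness" vs literal "restless")
DECOY_PHRASES: tuple[str, ...] = (
    "general benefits", "calmness of digestion", "painting of the skin",
    "first aid", "restlessness remedies none", "stressful seasons tonic",
)

_EPITHETS = (
    "album", "nigrum", "longum", "aduncum", "betle", "cubeba", "kadsura",
    "guineense", "umbellatum", "borbonense", "methysticum", "sarmentosum",
    "retrofractum", "auritum", "amalago", "hispidum", "arboreum", "caninum",
    "colubrinum", "darienense", "marginatum", "peltatum", "tuberculatum",
    "umbellatum", "attenuatum", "hancei", "mullesua", "obliquum",
)
_OTHER_GENERA = (
    "Zingiber", "Curcuma", "Valeriana", "Passiflora", "Withania", "Bacopa",
    "Centella", "Ocimum", "Glycyrrhiza", "Scutellaria",
)


class SpecError(ValueError):
    pass


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic pharmacopeia dataset."""

    n_formulas: int = 200
    n_species: int = 30
    target_genus_fraction: float = 0.5
    n_compounds: int = 40
    #: per-category probability that a formula treats the category
    category_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.3 for c in CATEGORIES}
    )
    #: (compound_key, category) -> probability uplift for category-treating
    #: formulas; keys absent from the mapping have zero uplift
    association_matrix: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    baseline_inclusion: float = 0.05
    species_compound_density: float = 0.05
    species_per_formula: tuple[int, int] = (1, 3)
    #: give every formula its own dedicated species, so planted formula-level
    #: compound attachments never leak between formulas via shared species
    dedicated_species: bool = False
    decoy_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_formulas < 1 or self.n_compounds < 1:
            raise SpecError("need at least one formula and one compound")
        if self.n_species < 1 and not self.dedicated_species:
            raise SpecError("need at least one species")
        probs = [
            self.baseline_inclusion, self.species_compound_density,
            self.target_genus_fraction, self.decoy_rate,
            *self.category_prevalence.values(),
            *self.association_matrix.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise SpecError("all probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to recompute downstream statistics independently."""

    formula_categories: dict[str, set[str]]
    formula_species: dict[str, set[str]]
    species_compounds: dict[str, set[str]]
    formula_compounds: dict[str, set[str]]
    association_matrix: dict[tuple[str, str], float]
    species_is_target: dict[str, bool]


def compound_key(i: int) -> str:
    return f"cmp{i:04d}"


def _inchikey(i: int) -> str:
    """Deterministic, collision-free synthetic InChIKey for compound i."""
    def enc(n: int, width: int) -> str:
        out = []
        for _ in range(width):
            out.append(chr(ord("A") + n % 26))
            n //= 26
        return "".join(reversed(out))

    return f"{enc(i, 14)}-{enc(i, 10)}-N"


def _species_pool(spec: GeneratorSpec, rng: np.random.Generator) -> list[str]:
    n_target = round(spec.n_species * spec.target_genus_fraction)
    names = []
    for i in range(spec.n_species):
        if i < n_target:
            genus = "Piper"
            epithet = _EPITHETS[i % len(_EPITHETS)]
            suffix = "" if i < len(_EPITHETS) else f"{i // len(_EPITHETS)}"
        else:
            genus = _OTHER_GENERA[(i - n_target) % len(_OTHER_GENERA)]
            epithet = _EPITHETS[(i * 7) % len(_EPITHETS)]
            suffix = (
                "" if (i - n_target) < len(_OTHER_GENERA)
                else f"{(i - n_target) // len(_OTHER_GENERA)}"
            )
        names.append(f"{genus} {epithet}{suffix}")
    # qualify duplicates deterministically
    seen: dict[str, int] = {}
    out = []
    for name in names:
        k = seen.get(name, 0)
        seen[name] = k + 1
        out.append(name if k == 0 else f"{name}{k}")
    return out


def generate_gims_dataset(spec: GeneratorSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one synthetic formula/species/compound dataset.

    Formulas draw their category set independently per category prevalence;
    indication strings come from the phrase bank, so the packaged dictionary
    recovers the drawn categories exactly.  Compounds attach to formulas
    through species memberships: a background species–compound membership
    layer at ``species_compound_density``, plus formula-level attachments
    drawn at ``baseline_inclusion`` (+ the largest applicable association
    uplift) and routed through one member species.  With shared species the
    routed attachments are visible to every formula using that species;
    ``dedicated_species`` avoids this when clean planting is required.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ds = Dataset()

    if spec.dedicated_species:
        pool = [f"Piper synthetica{i}" for i in range(spec.n_formulas)]
    else:
        pool = _species_pool(spec, rng)
    for name in pool:
        ds.add_species(name)

    for i in range(spec.n_compounds):
        key = compound_key(i)
        ds.compounds[key] = CompoundRecord(
            compound_key=key,
            name=f"synthanoid {i}",
            cid=100000 + i,
            inchikey=_inchikey(i),
        )

    compounds = sorted(ds.compounds)
    # background species -> compound memberships
    if not spec.dedicated_species and spec.species_compound_density > 0:
        draws = rng.random((len(pool), len(compounds)))
        for si, sp in enumerate(pool):
            for ci, ck in enumerate(compounds):
                if draws[si, ci] < spec.species_compound_density:
                    ds.link(sp, ck)

    formula_categories: dict[str, set[str]] = {}
    for i in range(spec.n_formulas):
        fid = f"F{i:05d}"
        if spec.dedicated_species:
            members = {pool[i]}
        else:
            lo, hi = spec.species_per_formula
            k = int(rng.integers(lo, hi + 1))
            members = set(rng.choice(pool, size=min(k, len(pool)), replace=False))
        cats = {
            cat for cat in CATEGORIES
            if rng.random() < spec.category_prevalence.get(cat, 0.0)
        }
        indications = [
            POSITIVE_PHRASES[cat][int(rng.integers(len(POSITIVE_PHRASES[cat])))]
            for cat in CATEGORIES if cat in cats
        ]
        if rng.random() < spec.decoy_rate:
            indications.append(
                DECOY_PHRASES[int(rng.integers(len(DECOY_PHRASES)))]
            )
        ds.formulas[fid] = FormulaRecord(
            formula_id=fid,
            txm_system="SYN",
            region="XX",
            species=members,
            indications=indications,
        )
        formula_categories[fid] = cats

        # planted formula-level compound attachments, routed through a species
        member_list = sorted(members)
        for ck in compounds:
            uplift = max(
                (spec.association_matrix.get((ck, cat), 0.0) for cat in cats),
                default=0.0,
            )
            p = min(spec.baseline_inclusion + uplift, 1.0)
            if p > 0 and rng.random() < p:
                carrier = member_list[int(rng.integers(len(member_list)))]
                ds.link(carrier, ck)

    ds.report.n_formulas = len(ds.formulas)
    ds.report.n_species = len(ds.species)
    ds.report.n_compounds = len(ds.compounds)

    truth = GroundTruth(
        formula_categories=formula_categories,
        formula_species={f.formula_id: set(f.species) for f in ds.formulas.values()},
        species_compounds={
            sp: set(keys) for sp, keys in ds.species_compounds.items()
        },
        formula_compounds={
            fid: ds.formula_compounds(fid) for fid in ds.formulas
        },
        association_matrix=dict(spec.association_matrix),
        species_is_target={
            sp: rec.is_target_genus for sp, rec in ds.species.items()
        },
    )
    return ds, truth


# ---------------------------------------------------------------------------
# molecule panel
# ---------------------------------------------------------------------------

#: documented linear label-generating function over the descriptor block.
#: Hydroxyl/amine-rich rigid structures score natural-product-like (high),
#: flexible structures score low; the non-zero coefficients sit on discrete
#: descriptors so a depth-capped forest can recover the function essentially
#: exactly from a finite molecule library (recoverable by construction).
NP_LABEL_COEFFS = {
    "intercept": 0.4,
    "molecular_weight": 0.0,
    "alogp": 0.0,
    "h_bond_donors": 0.75,
    "h_bond_acceptors": 0.0,
    "polar_surface_area": 0.0,
    "rotatable_bonds": -0.28,
}


def _fragment_library() -> tuple[list[str], list[str]]:
    ref = resources.files("pipermine.data") / "fragments.csv"
    cores, subs = [], []
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            (cores if row["kind"] == "core" else subs).append(row["smiles"])
    return cores, subs


@lru_cache(maxsize=2)
def _enumerate_all() -> tuple[str, ...]:
    return tuple(_enumerate_panel_smiles_uncached(None))


def enumerate_panel_smiles(limit: int | None = None) -> list[str]:
    """Deterministic enumeration of valid, distinct panel molecules."""
    if limit is None:
        return list(_enumerate_all())
    return list(_enumerate_all()[:limit])


def _enumerate_panel_smiles_uncached(limit: int | None = None) -> list[str]:
    cores, subs = _fragment_library()
    seen: set[str] = set()
    out: list[str] = []
    for core in cores:
        for r1 in subs:
            for r2 in subs:
                smi = core.replace("{R1}", r1).replace("{R2}", r2)
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                canonical = Chem.MolToSmiles(mol)
                if canonical in seen:
                    continue
                seen.add(canonical)
                out.append(canonical)
                if limit is not None and len(out) >= limit:
                    return out
    return out


def np_label(descriptors, coeffs: Mapping[str, float] | None = None) -> float:
    """The noise-free linear NP-likeness label for one descriptor vector."""
    c = dict(NP_LABEL_COEFFS)
    if coeffs:
        c.update(coeffs)
    raw = (
        c["intercept"]
        + c["molecular_weight"] * (descriptors.molecular_weight - 300.0)
        + c["alogp"] * descriptors.alogp
        + c["h_bond_donors"] * descriptors.h_bond_donors
        + c["h_bond_acceptors"] * descriptors.h_bond_acceptors
        + c["polar_surface_area"] * (descriptors.polar_surface_area - 60.0)
        + c["rotatable_bonds"] * descriptors.rotatable_bonds
    )
    return float(np.clip(raw, -5.0, 5.0))


def generate_molecule_panel(
    n: int,
    seed: int = 0,
    sigma: float = 0.25,
    label_mode: str = "linear",
) -> tuple[list[tuple[str, "DescriptorVector", float]], dict]:
    """Molecules with SMILES, descriptors and NP-likeness labels.

    ``label_mode`` is ``linear`` (the documented descriptor function plus
    N(0, sigma²) noise, clipped to [−5, 5]) or ``noise`` (labels independent
    of the structure — a null panel for imputer sanity checks).
    """
    from .druggability import compute_descriptors

    if n < 1:
        raise SpecError("n must be >= 1")
    if label_mode not in ("linear", "noise"):
        raise SpecError(f"unknown label_mode {label_mode!r}")
    smiles = enumerate_panel_smiles()
    if n > len(smiles):
        raise SpecError(
            f"panel library holds {len(smiles)} distinct molecules, "
            f"cannot draw {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(smiles), size=n, replace=False)
    panel = []
    for idx in sorted(chosen):
        smi = smiles[idx]
        d = compute_descriptors(smi)
        if label_mode == "linear":
            label = np_label(d)
            if sigma > 0:
                label = float(
                    np.clip(label + rng.normal(0.0, sigma), -5.0, 5.0)
                )
        else:
            label = float(np.clip(rng.normal(0.0, 1.0), -5.0, 5.0))
        panel.append((smi, d, label))
    truth = {
        "coefficients": dict(NP_LABEL_COEFFS),
        "sigma": sigma,
        "label_mode": label_mode,
        "seed": seed,
    }
    return panel, truth


# ---------------------------------------------------------------------------
# per-source compound tables (metabolome assembly)
# ---------------------------------------------------------------------------

#: raw class strings that the default keyword rules map to each bin
_RAW_CLASS_STRINGS = {
    "alkaloid": "Alkaloids",
    "benzenoid": "Benzenoids",
    "terpene": "Sesquiterpenoids",
    "cinnamic acid": "Cinnamic acids and derivatives",
    "flavonoid": "Flavonoids",
    "kavalactone": "Kavalactones",
    "chalcone": "Chalcones",
    "miscellaneous": "Unclassified",
}

#: the eight-bin composition of the packaged composite-metabolome fixture
FIXTURE_CLASS_SIZES = {
    "alkaloid": 29, "benzenoid": 31, "terpene": 39, "cinnamic acid": 28,
    "flavonoid": 10, "kavalactone": 35, "chalcone": 17, "miscellaneous": 79,
}


def generate_source_tables(
    class_sizes: Mapping[str, int] | None = None,
    n_sources: int = 3,
    overlap: float = 0.5,
    blank_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[SourceRecord, list[CompoundRecord]], dict]:
    """Per-source compound lists with a known partition and class tally.

    Each true compound appears in one anchor source and, independently with
    probability ``overlap``, in every other source.  ``blank_rate`` blanks
    identifier tiers per record while keeping each compound's records
    mergeable under the identifier-precedence rule, so reconciliation must
    recover exactly the true partition.
    """
    sizes = dict(class_sizes or FIXTURE_CLASS_SIZES)
    for bin_, n in sizes.items():
        if bin_ not in CLASS_BINS:
            raise SpecError(f"unknown class bin {bin_!r}")
        if n < 0:
            raise SpecError("class sizes must be >= 0")
    rng = np.random.default_rng(seed)

    kinds = ["extraction-study", "database", "literature-compilation"]
    methods = ["sonication", "SFE", "SPME", "crude extraction"]
    solvents = ["water", "ethanol", "methanol", "acetone"]
    sources = []
    for s in range(n_sources):
        kind = kinds[s % len(kinds)]
        sources.append(SourceRecord(
            source_id=f"SRC{s:02d}",
            source_kind=kind,
            extraction_method=methods[s % len(methods)]
            if kind == "extraction-study" else None,
            solvent=solvents[s % len(solvents)]
            if kind == "extraction-study" else None,
        ))

    tables: dict[SourceRecord, list[CompoundRecord]] = {s: [] for s in sources}
    truth_partition: dict[str, list[tuple[str, str]]] = {}
    truth_bins: dict[str, str] = {}
    i = 0
    for bin_ in CLASS_BINS:
        for _ in range(sizes.get(bin_, 0)):
            key = compound_key(i)
            truth_bins[key] = bin_
            present_in = [sources[i % n_sources]]
            for src in sources:
                if src is present_in[0]:
                    continue
                if rng.random() < overlap:
                    present_in.append(src)
            # pick the identifier tier every record of this compound keeps
            tier = "inchikey"
            if blank_rate > 0 and rng.random() < blank_rate:
                tier = "cid" if rng.random() < 0.5 else "name"
            truth_partition[key] = []
            for src in present_in:
                rec = CompoundRecord(
                    compound_key=f"{src.source_id}:{key}",
                    name=f"synthanoid {i}",
                    cid=100000 + i,
                    inchikey=_inchikey(i),
                    smiles=None,
                    chem_class_raw=_RAW_CLASS_STRINGS[bin_],
                )
                if tier != "inchikey":
                    rec.inchikey = None
                    if tier == "name":
                        rec.cid = None
                    elif blank_rate > 0 and rng.random() < blank_rate:
                        rec.name = None
                tables[src].append(rec)
                truth_partition[key].append((src.source_id, rec.compound_key))
            i += 1

    truth = {
        "n_compounds": i,
        "class_sizes": sizes,
        "class_bins": truth_bins,
        "partition": truth_partition,
        "seed": seed,
    }
    return tables, truth
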