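"""Association statistics linking compounds and species to indication categories.

Two distinct percentage statistics are computed and must never be conflated:

* the **association profile** of a compound — for each category, the
  percentage of the formulas *containing the compound* whose indications
  match that category (the bubble-heatmap statistic);
* the **compound index** — the mean, over the four categories, of the
  percentage of *all category-treating formulas* that contain the compound
  (the scatter-plot statistic).

On top of these sit the candidate filter (sum of the four association
percentages strictly greater than 300), species–category linkage counts for
chord diagrams, a species over-representation ratio, and per-compound species
source counts split by the focal genus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dictionary import CATEGORIES
from .ingest import Dataset

CategoryMap = Mapping[str, set[str]]  # formula_id -> matched categories


@dataclass
class AssociationProfile:
    """Per-compound indication percentages over its containing formulas."""

    compound_key: str
    n_formulas: int
    pct_by_category: dict[str, float]
    undefined: bool = False  # no containing formulas: percentages undefined

    @property
    def pct_sum(self) -> float:
        return sum(self.pct_by_category.values())

    @property
    def passes_filter(self) -> bool:
        return not self.undefined and self.pct_sum > 300.0


@dataclass
class CompoundIndex:
    compound_key: str
    per_category_containment: dict[str, float]
    excluded_categories: list[str] = field(default_factory=list)

    @property
    def index(self) -> float:
        vals = [
            v for c, v in self.per_category_containment.items()
            if c not in self.excluded_categories
        ]
        return sum(vals) / len(vals) if vals else float("nan")


@dataclass(frozen=True)
class LinkageCount:
    species: str
    category: str
    linkages: int


@dataclass(frozen=True)
class SourceCount:
    compound_key: str
    n_piper_species: int
    n_non_piper_species: int


def association_profile(
    dataset: Dataset, compound_key: str, categories: CategoryMap
) -> AssociationProfile:
    """Percentage of a compound's containing formulas matching each category.

    The denominator is the set of formulas containing the compound (via any
    member species); the numerator per category is the subset of those whose
    category set includes the category.  Percentages are on the 0–100 scale.
    """
    containing = dataset.compound_formulas(compound_key)  # KeyError if unknown
    n = len(containing)
    if n == 0:
        return AssociationProfile(
            compound_key, 0, {c: 0.0 for c in CATEGORIES}, undefined=True
        )
    pct = {
        cat: 100.0 * sum(1 for fid in containing if cat in categories[fid]) / n
        for cat in CATEGORIES
    }
    return AssociationProfile(compound_key, n, pct)


def compound_index(
    dataset: Dataset,
    compound_key: str,
    categories: CategoryMap,
    strict: bool = False,
) -> CompoundIndex:
    """Mean over categories of the containment percentage of a compound.

    Per-category containment is 100 × |formulas treating the category and
    containing the compound| / |formulas treating the category|.  A category
    no formula treats has an undefined containment: under ``strict`` this is
    an error, otherwise the category is excluded from the mean.
    """
    containing = dataset.compound_formulas(compound_key)
    containment: dict[str, float] = {}
    excluded: list[str] = []
    for cat in CATEGORIES:
        treating = {fid for fid, cs in categories.items() if cat in cs}
        if not treating:
            if strict:
                raise ValueError(f"no formula treats category {cat!r}")
            excluded.append(cat)
            containment[cat] = float("nan")
            continue
        containment[cat] = 100.0 * len(treating & containing) / len(treating)
    return CompoundIndex(compound_key, containment, excluded)


def candidate_filter(
    profiles: Iterable[AssociationProfile], threshold: float = 300.0
) -> list[AssociationProfile]:
    """Profiles whose percentage sum strictly exceeds the threshold.

    Output is sorted by pct_sum descending, ties broken by n_formulas
    descending then compound_key ascending, so listings are byte-stable.
    """
    passing = [
        p for p in profiles if not p.undefined and p.pct_sum > threshold
    ]
    return sorted(
        passing, key=lambda p: (-p.pct_sum, -p.n_formulas, p.compound_key)
    )


def species_indication_linkages(
    dataset: Dataset,
    categories: CategoryMap,
    genus_filter: str | None = None,
) -> list[LinkageCount]:
    """Count (species, category) linkages over all formulas.

    Every qualifying member species of a formula is paired with every
    category the formula treats, so a formula with s species and c categories
    contributes s × c linkages — each pairing counted individually.
    """
    counts: dict[tuple[str, str], int] = {}
    for fid, formula in dataset.formulas.items():
        cats = categories.get(fid, set())
        for sp in formula.species:
            if genus_filter and dataset.species[sp].genus != genus_filter:
                continue
            for cat in cats:
                counts[(sp, cat)] = counts.get((sp, cat), 0) + 1
    return [
        LinkageCount(sp, cat, n)
        for (sp, cat), n in sorted(counts.items())
    ]


def species_enrichment(
    dataset: Dataset, categories: CategoryMap, species: str
) -> float:
    """Over-representation of a species in category-treating formulas.

    The unit is the (formula, species) membership.  The ratio divides the
    species' share of category-linked memberships by its share of all
    memberships; a value above 1 flags a species used disproportionately in
    formulas treating the four categories.
    """
    all_memberships = [
        (fid, sp)
        for fid, f in dataset.formulas.items()
        for sp in f.species
    ]
    linked = [(fid, sp) for fid, sp in all_memberships if categories.get(fid)]
    mine_all = sum(1 for _, sp in all_memberships if sp == species)
    if mine_all == 0:
        raise ValueError(f"species {species!r} appears in no formula")
    overall_share = mine_all / len(all_memberships)
    if not linked:
        return 0.0
    linked_share = sum(1 for _, sp in linked if sp == species) / len(linked)
    return linked_share / overall_share


def compound_source_counts(dataset: Dataset, compound_key: str) -> SourceCount:
    """Distinct species containing a compound, split by the focal genus."""
    species = dataset.compound_species(compound_key)
    n_target = sum(1 for sp in species if dataset.species[sp].is_target_genus)
    return SourceCount(compound_key, n_target, len(species) - n_target)


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def profiles_table(profiles: Sequence[AssociationProfile]) -> pd.DataFrame:
    rows = [
        (p.compound_key, cat, p.n_formulas, p.pct_by_category[cat])
        for p in profiles
        for cat in CATEGORIES
    ]
    return pd.DataFrame(rows, columns=["compound_key", "category", "n", "pct"])


def index_table(indices: Sequence[CompoundIndex]) -> pd.DataFrame:
    return pd.DataFrame(
        [(ci.compound_key, ci.index) for ci in indices],
        columns=["compound_key", "index"],
    )


def linkages_table(linkages: Sequence[LinkageCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.species, l.category, l.linkages) for l in linkages],
        columns=["species", "category", "linkages"],
    )


def circos_links(linkages: Sequence[LinkageCount]) -> str:
    """Tab-delimited (species, category, weight) link file for chord plots."""
    lines = [
        f"{l.species}\t{l.category}\t{l.linkages}"
        for l in sorted(linkages, key=lambda l: (l.species, l.category))
    ]
    return "\n".join(lines) + ("\n" if lines else "")
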