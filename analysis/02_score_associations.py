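#!/usr/bin/env python
"""Score compound- and species-level indication associations.

Reads results/data/gims (built by 01_simulate_dataset.py), categorises every
formula with the packaged four-category indication dictionary, and writes:

* ``associations.csv`` — per compound and category, the number of containing
  formulas and the percentage of them treating the category;
* ``compound_index.csv`` — the category-denominator containment average;
* ``candidates.csv`` — compounds whose four-percentage sum exceeds 300;
* ``linkages.csv`` + ``circos_links.txt`` — species-category linkage counts,
  each (formula, species, category) pairing counted individually.

Run after 01: python analysis/02_score_associations.py
"""

from pathlib import Path

from pipermine.dictionary import categorize_dataset, compile_dictionary
from pipermine.ingest import load_dataset
from pipermine.scoring import (
    association_profile,
    candidate_filter,
    circos_links,
    compound_index,
    index_table,
    linkages_table,
    profiles_table,
    species_indication_linkages,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    ds = load_dataset(out / "data" / "gims")
    dictionary = compile_dictionary()
    cats = categorize_dataset(ds, dictionary)
    n_categorized = sum(1 for cs in cats.values() if cs)
    print(f"{n_categorized}/{len(cats)} formulas match >=1 category")

    profiles = [
        association_profile(ds, ck, cats) for ck in sorted(ds.compounds)
    ]
    profiles_table(profiles).to_csv(out / "associations.csv", index=False)

    indices = [compound_index(ds, ck, cats) for ck in sorted(ds.compounds)]
    index_table(indices).to_csv(out / "compound_index.csv", index=False)
    top = max(indices, key=lambda ci: ci.index)
    print(f"highest compound index: {top.compound_key} at {top.index:.1f}")

    passing = candidate_filter(profiles)
    profiles_table(passing).to_csv(out / "candidates.csv", index=False)
    print(f"{len(passing)}/{len(profiles)} compounds exceed the 300 filter")

    linkages = species_indication_linkages(ds, cats, genus_filter="Piper")
    linkages_table(linkages).to_csv(out / "linkages.csv", index=False)
    (out / "circos_links.txt").write_text(circos_links(linkages))
    print(f"{sum(l.linkages for l in linkages)} Piper species-category "
          f"linkages across {len(linkages)} pairs")


if __name__ == "__main__":
    main()
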