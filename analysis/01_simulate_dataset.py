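#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes three artefacts under results/data/:

* ``gims/`` — a synthetic pharmacopeia dataset (400 formulas, 30 species
  half of them Piper, 20 compounds) in the CSV interchange layout;
* ``sources/`` — per-source compound lists reproducing the eight-class
  composite-metabolome fixture (268 compounds across 3 sources);
* ``molecules.csv`` — a 2500-molecule panel with NP-likeness labels drawn
  from the documented linear ground truth (sigma = 0.25).

Run: python analysis/01_simulate_dataset.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from pipermine.ingest import write_dataset
from pipermine.synthetic import (
    FIXTURE_CLASS_SIZES,
    GeneratorSpec,
    generate_gims_dataset,
    generate_molecule_panel,
    generate_source_tables,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)

    spec = GeneratorSpec(
        n_formulas=400, n_species=30, n_compounds=20, seed=args.seed
    )
    ds, _ = generate_gims_dataset(spec)
    write_dataset(ds, out / "gims")
    print(
        f"gims: {len(ds.formulas)} formulas, {len(ds.species)} species, "
        f"{len(ds.compounds)} compounds -> {out / 'gims'}"
    )

    tables, _ = generate_source_tables(
        FIXTURE_CLASS_SIZES, n_sources=3, overlap=0.5, seed=args.seed
    )
    srcdir = out / "sources"
    srcdir.mkdir(exist_ok=True)
    meta_rows = []
    for src, records in tables.items():
        fname = f"{src.source_id}.csv"
        pd.DataFrame(
            sorted(
                (r.compound_key, r.name or "", r.cid or "", r.inchikey or "",
                 r.chem_class_raw or "")
                for r in records
            ),
            columns=["compound_key", "name", "cid", "inchikey",
                     "chem_class_raw"],
        ).to_csv(srcdir / fname, index=False)
        meta_rows.append(
            (src.source_id, src.source_kind, src.extraction_method or "",
             src.solvent or "", fname)
        )
    pd.DataFrame(
        sorted(meta_rows),
        columns=["source_id", "source_kind", "extraction_method", "solvent",
                 "file"],
    ).to_csv(srcdir / "sources.csv", index=False)
    print(f"sources: {sum(len(v) for v in tables.values())} records "
          f"over {len(tables)} sources -> {srcdir}")

    panel, truth = generate_molecule_panel(2500, seed=args.seed, sigma=0.25)
    pd.DataFrame(
        [(f"mol{i:05d}", smi, round(label, 6))
         for i, (smi, _, label) in enumerate(panel)],
        columns=["compound_key", "smiles", "np_likeness"],
    ).to_csv(out / "molecules.csv", index=False)
    print(f"molecules: {len(panel)} labelled structures "
          f"(sigma={truth['sigma']}) -> {out / 'molecules.csv'}")


if __name__ == "__main__":
    main()
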