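#!/usr/bin/env python
"""Assemble the composite metabolome from the per-source compound lists.

Reads results/data/sources (three overlapping sources over a 268-compound
eight-class fixture), reconciles compound identities across sources, bins
every compound into its phytochemical class, and writes:

* ``meta_metabolome.csv`` — one row per reconciled compound with its bin;
* ``presence.csv`` — the compound x source presence matrix (long format);
* ``sankey_links.csv`` — (study, extraction method, solvent, compound) rows
  for provenance rendering;
* ``class_tally.json`` — the eight-bin census.

Run after 01: python analysis/03_assemble_metabolome.py
"""

import json
from pathlib import Path

from pipermine.metabolome import (
    assemble_meta_metabolome,
    metabolome_tables,
    read_source_tables,
    solvent_provenance_table,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    srcdir = out / "data" / "sources"
    tables = read_source_tables(srcdir / "sources.csv", srcdir)
    meta = assemble_meta_metabolome("Piper methysticum", tables)

    for name, table in metabolome_tables(meta).items():
        table.to_csv(out / f"{name}.csv", index=False)
    provenance = solvent_provenance_table(meta)
    provenance.to_csv(out / "sankey_links.csv", index=False)
    (out / "class_tally.json").write_text(
        json.dumps(
            {"total": meta.total, "class_tally": meta.class_tally},
            indent=2, sort_keys=True,
        ) + "\n"
    )
    print(f"composite metabolome: {meta.total} compounds from "
          f"{len(meta.sources)} sources")
    for bin_, n in sorted(meta.class_tally.items()):
        print(f"  {bin_:14s} {n:3d}")
    print(f"{len(provenance)} extraction-study provenance rows")


if __name__ == "__main__":
    main()
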