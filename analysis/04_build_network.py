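#!/usr/bin/env python
"""Build and export the species-compound network and its projection.

Reads results/data/gims, builds the bipartite species-compound graph (one
edge per distinct species-compound link), projects it onto species with
shared-compound counts and Jaccard weights, and writes edge-list TSV plus
GraphML files under results/network/.

Run after 01: python analysis/04_build_network.py
"""

from pathlib import Path

from pipermine.ingest import load_dataset
from pipermine.network import build_bipartite, export_network, project_species

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "network"
    ds = load_dataset(ROOT / "results" / "data" / "gims")

    g = build_bipartite(ds)
    files = export_network(g, out / "bipartite")
    n_species = sum(
        1 for _, d in g.nodes(data=True) if d["bipartite"] == "species"
    )
    print(f"bipartite graph: {n_species} species, "
          f"{g.number_of_nodes() - n_species} compounds, "
          f"{g.number_of_edges()} edges")

    proj = project_species(g, min_shared=1)
    files += export_network(proj, out / "species_projection")
    if proj.number_of_edges():
        a, b, data = max(
            proj.edges(data=True), key=lambda e: e[2]["jaccard"]
        )
        print(f"projection: {proj.number_of_edges()} species pairs share "
              f"compounds; most similar {a} / {b} "
              f"(jaccard {data['jaccard']:.2f}, shared {data['shared']})")
    for f in files:
        print(f"wrote {f.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
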