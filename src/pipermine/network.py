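"""Species–compound bipartite network and its species-level projection.

The bipartite graph has one node per species and per compound, with an edge
wherever a species is reported to contain a compound.  The species projection
quantifies chemical "sharedness" between species pairs both as a raw shared
compound count and as a Jaccard fraction of the union of their compound sets
(the normalised view damps the dominance of chemically over-studied species).
Rendering is delegated to external viewers; this module only guarantees the
graph objects and their exports (edge-list TSV and GraphML).
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import networkx as nx

from .ingest import Dataset


def build_bipartite(
    dataset: Dataset,
    species_filter: str | None = None,
    class_bins: dict[str, str] | None = None,
) -> nx.Graph:
    """One edge per distinct (species, compound) link.

    ``species_filter`` restricts the species side to a genus; compound nodes
    carry their class bin (for styling) when ``class_bins`` is given.
    """
    g = nx.Graph()
    for sp in sorted(dataset.species):
        if species_filter and dataset.species[sp].genus != species_filter:
            continue
        g.add_node(
            sp, bipartite="species",
            genus=dataset.species[sp].genus,
            target_genus=dataset.species[sp].is_target_genus,
        )
        for ck in sorted(dataset.species_compounds.get(sp, ())):
            if ck not in g:
                g.add_node(
                    ck, bipartite="compound",
                    class_bin=(class_bins or {}).get(ck, "miscellaneous"),
                )
            g.add_edge(sp, ck)
    return g


def project_species(network: nx.Graph, min_shared: int = 1) -> nx.Graph:
    """Weighted species–species graph from shared compound sets.

    An edge joins every species pair sharing at least ``min_shared``
    compounds, weighted by the shared count and by the Jaccard fraction
    shared / |union|.  Self-edges never occur and weights are symmetric by
    construction.
    """
    species = sorted(
        n for n, d in network.nodes(data=True) if d.get("bipartite") == "species"
    )
    proj = nx.Graph()
    for sp in species:
        proj.add_node(sp, **network.nodes[sp])
    neighbours = {sp: set(network.adj[sp]) for sp in species}
    for a, b in combinations(species, 2):
        shared = len(neighbours[a] & neighbours[b])
        if shared < min_shared:
            continue
        union = len(neighbours[a] | neighbours[b])
        proj.add_edge(a, b, shared=shared, jaccard=shared / union)
    return proj


def export_network(
    network: nx.Graph, out_prefix: str | Path, fmt: str = "both"
) -> list[Path]:
    """Write edge-list TSV and/or GraphML with node attributes.

    Node and edge ordering is sorted, so the same graph always produces the
    same bytes.  ``fmt`` is ``edgelist``, ``graphml`` or ``both``.
    """
    if fmt not in ("edgelist", "graphml", "both"):
        raise ValueError(f"unknown export format {fmt!r}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # rebuild with sorted insertion order for deterministic serialisation
    ordered = nx.Graph()
    for n in sorted(network.nodes):
        ordered.add_node(n, **network.nodes[n])
    for u, v in sorted(tuple(sorted(e)) for e in network.edges):
        ordered.add_edge(u, v, **network.edges[u, v])

    if fmt in ("edgelist", "both"):
        path = out_prefix.with_suffix(".edges.tsv")
        with path.open("w", encoding="utf-8") as fh:
            for u, v, data in ordered.edges(data=True):
                attrs = "\t".join(
                    str(data[k]) for k in sorted(data)
                )
                fh.write(f"{u}\t{v}" + (f"\t{attrs}" if attrs else "") + "\n")
        written.append(path)
    if fmt in ("graphml", "both"):
        path = out_prefix.with_suffix(".graphml")
        nx.write_graphml(ordered, path, named_key_ids=True)
        written.append(path)
    return written


def load_edgelist(path: str | Path) -> set[tuple[str, str]]:
    """Read back an exported edge list as a set of sorted node pairs."""
    edges = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.split("\t")
        if len(parts) >= 2:
            edges.add(tuple(sorted(parts[:2])))
    return edges
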