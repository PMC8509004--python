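"""Cross-region DEGA set algebra.

Overlap matrix (region-by-region intersection counts), shared-in-k profiles
(how many regions each DEGA recurs in), per-gene direction profiles, and the
bipartite gene-region network.  Overlap membership ignores direction: a gene
downregulated in one region and upregulated in another still counts in their
intersection.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .age_screen import DegaSets


def overlap_matrix(dega_sets: DegaSets) -> pd.DataFrame:
    """Region x region intersection counts; diagonal = per-region set size."""
    regions = list(dega_sets.regions)
    if len(regions) < 2:
        raise ValueError("need DEGA sets for at least 2 regions")
    sets = {r: dega_sets.genes(r) for r in regions}
    counts = np.zeros((len(regions), len(regions)), dtype=int)
    for i, ri in enumerate(regions):
        for j, rj in enumerate(regions):
            counts[i, j] = len(sets[ri] & sets[rj])
    return pd.DataFrame(counts, index=regions, columns=regions)


def shared_in_k(
    dega_sets: DegaSets,
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Recurrence profile of DEGAs across regions.

    Returns ``(gene_k, k_counts, genes_in_all)``: for each union gene the
    number of regions where it is a DEGA; the histogram of those counts; and
    the sorted list of genes present in every region.
    """
    regions = list(dega_sets.regions)
    tally: dict[str, int] = {}
    for r in regions:
        for gene in dega_sets.genes(r):
            tally[gene] = tally.get(gene, 0) + 1
    gene_k = pd.Series(tally, dtype=int).sort_index()
    k_counts = gene_k.value_counts().sort_index()
    k_counts.index.name = "k"
    genes_in_all = sorted(g for g, k in tally.items() if k == len(regions))
    return gene_k, k_counts, genes_in_all


def direction_profile(gene: str, dega_sets: DegaSets) -> dict[str, str]:
    """Per-region direction vector for one gene: up / down / absent.

    Raises
    ------
    KeyError
        If the gene is not a DEGA in any region.
    """
    profile = {
        region: dega_sets.by_region[region].get(gene, "absent")
        for region in dega_sets.regions
    }
    if all(d == "absent" for d in profile.values()):
        raise KeyError(f"{gene!r} is not a DEGA in any region")
    return profile


def build_network(dega_sets: DegaSets) -> nx.Graph:
    """Bipartite gene-region graph: an edge marks DEGA membership.

    Gene nodes carry ``kind='gene'``, region nodes ``kind='region'``
    (regions with zero DEGAs are kept as isolated nodes); every node gets a
    ``size`` attribute equal to its degree, mirroring size-by-connectedness
    display conventions.
    """
    union = dega_sets.union_genes()
    if not union:
        raise ValueError("empty DEGA union: nothing to build")
    G = nx.Graph()
    for region in dega_sets.regions:
        G.add_node(region, kind="region", bipartite=1)
    for gene in sorted(union):
        G.add_node(gene, kind="gene", bipartite=0)
    for region in dega_sets.regions:
        for gene, direction in sorted(dega_sets.by_region[region].items()):
            G.add_edge(gene, region, direction=direction)
    for node in G.nodes:
        G.nodes[node]["size"] = G.degree[node]
    return G


def export_network(G: nx.Graph, graphml_path, edges_tsv_path) -> None:
    """Write the network as GraphML plus a plain edge-list TSV."""
    graphml_path = Path(graphml_path)
    graphml_path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(G, graphml_path)
    rows = [
        {"gene": u if G.nodes[u]["kind"] == "gene" else v,
         "region": v if G.nodes[u]["kind"] == "gene" else u,
         "direction": data.get("direction", "")}
        for u, v, data in G.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["gene", "region", "direction"])
    frame = frame.sort_values(["region", "gene"], kind="mergesort")
    frame.to_csv(edges_tsv_path, sep="\t", index=False)


def write_overlap(counts: pd.DataFrame, path) -> Path:
    """Write the overlap matrix as TSV with region header row/column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, sep="\t", index_label="region")
    return path


def write_shared_in_k(gene_k: pd.Series, path) -> Path:
    """Write the per-gene region counts as TSV (gene, k)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = gene_k.rename("k").rename_axis("gene").reset_index()
    frame.to_csv(path, sep="\t", index=False)
    return path
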