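"""Species assignment for unlabelled genomes via a Mash similarity network.

Genomes lacking a reference species label are connected by an edge whenever
their genome-wide similarity (1 - Mash distance) exceeds 95%, a typical
species threshold.  Louvain modularity communities of that graph (fixed
seed) become novel species, named ``MASH_sp_<n>``; isolated genomes form
singleton species.  Connected components are reported alongside as the
coarser alternative partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .sketch_distance import DistanceMatrix

DEFAULT_SIMILARITY_THRESHOLD = 0.95


@dataclass
class SpeciesAssignment:
    genome_id: str
    species_id: str
    source: str  # 'input' (reference label) or 'network'


def similarity_graph(
    dm: DistanceMatrix,
    unlabeled_ids: list[str],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> nx.Graph:
    """Graph on the unlabelled genomes; edge iff 1 - D strictly exceeds the
    threshold (D < 0.05 at the default)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("similarity threshold must lie in (0, 1)")
    missing = [g for g in unlabeled_ids if g not in dm.ids]
    if missing:
        raise ValueError(f"ids absent from the distance matrix: {missing}")
    G = nx.Graph()
    G.add_nodes_from(unlabeled_ids)
    index = {g: i for i, g in enumerate(dm.ids)}
    for i, a in enumerate(unlabeled_ids):
        for b in unlabeled_ids[i + 1 :]:
            d = dm.D[index[a], index[b]]
            if 1.0 - d > threshold:
                G.add_edge(a, b, similarity=1.0 - d)
    return G


def detect_species(graph: nx.Graph, seed: int = 0) -> list[SpeciesAssignment]:
    """Louvain communities of the similarity graph, one novel species each.

    Communities are numbered deterministically by their smallest member id;
    isolated nodes come out as singleton species.
    """
    if graph.number_of_nodes() == 0:
        return []
    communities = nx.community.louvain_communities(graph, seed=seed)
    ordered = sorted(communities, key=lambda c: min(c))
    assignments = []
    for n, members in enumerate(ordered, start=1):
        for g in sorted(members):
            assignments.append(SpeciesAssignment(g, f"MASH_sp_{n}", "network"))
    return assignments


def connected_component_species(graph: nx.Graph) -> list[SpeciesAssignment]:
    """The coarser partition: connected components as species."""
    ordered = sorted(nx.connected_components(graph), key=min)
    return [
        SpeciesAssignment(g, f"MASH_cc_{n}", "network")
        for n, members in enumerate(ordered, start=1)
        for g in sorted(members)
    ]


def merge_species(
    labeled: dict[str, str],
    network_assignments: list[SpeciesAssignment],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Combine reference labels with network-derived novel species.

    Returns the full assignment table and a summary with the total species
    count and the number of singleton species.  The two genome sets must be
    disjoint.
    """
    network_ids = {a.genome_id for a in network_assignments}
    overlap = set(labeled) & network_ids
    if overlap:
        raise ValueError(f"genomes present in both labelled and network sets: {sorted(overlap)}")
    rows = [(g, sp, "input") for g, sp in labeled.items()]
    rows += [(a.genome_id, a.species_id, a.source) for a in network_assignments]
    table = pd.DataFrame(rows, columns=["genome_id", "species_id", "source"])
    counts = table.species_id.value_counts()
    summary = {
        "total_species": int(counts.size),
        "singleton_species": int((counts == 1).sum()),
        "input_species": int(table.loc[table.source == "input", "species_id"].nunique()),
        "novel_species": int(table.loc[table.source == "network", "species_id"].nunique()),
    }
    return table, summary
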