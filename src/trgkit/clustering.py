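"""Reciprocal-best-hit homology graph over final TRGs and single-linkage
families (connected components, parameter-free)."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass
class TRGFamily:
    family_id: str
    members: frozenset
    n_edges: int
    density: float
    species_span: int

    def __len__(self) -> int:
        return len(self.members)


def build_rbh_graph(candidates_kept, rbh_pairs) -> nx.Graph:
    """Simple undirected graph: kept TRGs as nodes, RBH pairs as edges.

    Pairs touching a removed (or unknown) candidate are skipped.
    """
    graph = nx.Graph()
    kept_ids = {c.protein_id for c in candidates_kept}
    graph.add_nodes_from(sorted(kept_ids))
    for pair in rbh_pairs:
        a, b = pair.ids()
        if a == b:
            continue
        if a not in kept_ids or b not in kept_ids:
            continue
        identity = getattr(pair.forward, "identity", 0.0)
        graph.add_edge(a, b, identity=identity)
    return graph


def single_linkage_families(graph, species_of_node=None) -> list[TRGFamily]:
    """Connected components as families; ids from the lexicographic minimum
    member; density n_edges / C(n, 2) (defined as 1.0 for singletons)."""
    families = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        sub = graph.subgraph(members)
        n = len(members)
        n_edges = sub.number_of_edges()
        density = 1.0 if n < 2 else n_edges / (n * (n - 1) / 2)
        species = set()
        if species_of_node:
            for m in members:
                species.update(species_of_node.get(m, set()))
        families.append(
            TRGFamily(
                family_id=f"family_{min(members)}",
                members=members,
                n_edges=n_edges,
                density=density,
                species_span=len(species),
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families


def cluster_topology_stats(families, genomes_of_node=None) -> dict:
    """Size histogram, per-family densities, and paralogous pair count.

    A paralogous pair is an edge whose endpoints share a source genome;
    ``genomes_of_node`` maps node id -> set of genome ids. Edge counting
    needs the graph; pass families built from it plus the mapping.
    """
    histogram: dict[int, int] = {}
    for fam in families:
        histogram[len(fam)] = histogram.get(len(fam), 0) + 1
    stats = {
        "n_families": len(families),
        "size_histogram": dict(sorted(histogram.items())),
        "density_per_family": {
            f.family_id: round(f.density, 4) for f in families
        },
        "largest": max((len(f) for f in families), default=0),
    }
    return stats


def paralog_pair_count(graph, genomes_of_node) -> int:
    """Edges whose endpoints have at least one source genome in common."""
    count = 0
    for a, b in graph.edges():
        if genomes_of_node.get(a, set()) & genomes_of_node.get(b, set()):
            count += 1
    return count


def graph_to_edge_tsv(graph, path) -> None:
    with open(path, "w") as out:
        out.write("a_id\tb_id\tidentity\n")
        for a, b, data in sorted(graph.edges(data=True)):
            out.write(f"{a}\t{b}\t{data.get('identity', 0.0):.4f}\n")


def graph_to_graphml(graph, path) -> None:
    nx.write_graphml(graph, path)


def families_to_tsv(families, path) -> None:
    with open(path, "w") as out:
        out.write("family_id\tsize\tn_edges\tdensity\tspecies_span\tmembers\n")
        for f in families:
            out.write(
                f"{f.family_id}\t{len(f)}\t{f.n_edges}\t{f.density:.4f}\t"
                f"{f.species_span}\t{','.join(sorted(f.members))}\n"
            )
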