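"""Homology-graph families: components vs a union-find oracle, planted
topology signatures, histogram and paralog-pair bookkeeping."""

import numpy as np
import networkx as nx

from trgkit.clustering import (
    build_rbh_graph,
    cluster_topology_stats,
    paralog_pair_count,
    single_linkage_families,
)

from _oracles import UnionFind


class FakePair:
    def __init__(self, a, b):
        self.a_id, self.b_id = a, b
        self.forward = type("F", (), {"identity": 0.9})()
        self.reverse = None

    def ids(self):
        return (self.a_id, self.b_id)


class FakeCand:
    def __init__(self, pid):
        self.protein_id = pid


def test_path_and_isolate_components():
    cands = [FakeCand(x) for x in "ABCD"]
    graph = build_rbh_graph(cands, [FakePair("A", "B"), FakePair("B", "C")])
    fams = single_linkage_families(graph)
    assert sorted(sorted(f.members) for f in fams) == [["A", "B", "C"], ["D"]]


def test_pair_referencing_removed_candidate_skipped():
    cands = [FakeCand("A"), FakeCand("B")]
    graph = build_rbh_graph(cands, [FakePair("A", "Z")])
    assert graph.number_of_edges() == 0


def test_clique_density():
    cands = [FakeCand(x) for x in "ABCD"]
    pairs = [FakePair(a, b) for a in "ABCD" for b in "ABCD" if a < b]
    fams = single_linkage_families(build_rbh_graph(cands, pairs))
    (fam,) = fams
    assert len(fam) == 4 and fam.density == 1.0


def test_components_match_union_find_oracle():
    rng = np.random.default_rng(8)
    nodes = [f"n{i}" for i in range(50)]
    edges = set()
    while len(edges) < 40:
        a, b = rng.choice(50, size=2, replace=False)
        edges.add((f"n{min(a,b)}", f"n{max(a,b)}"))
    graph = build_rbh_graph(
        [FakeCand(n) for n in nodes], [FakePair(a, b) for a, b in edges]
    )
    fams = single_linkage_families(graph)
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    assert sorted(sorted(f.members) for f in fams) == [
        sorted(c) for c in uf.components()
    ]
    # structural inequality of any simple graph
    assert len(nodes) - len(fams) <= graph.number_of_edges()


def test_topology_stats_and_histogram():
    cands = [FakeCand(f"x{i}") for i in range(7)]
    pairs = [FakePair("x0", "x1")]
    fams = single_linkage_families(build_rbh_graph(cands, pairs))
    stats = cluster_topology_stats(fams)
    assert stats["size_histogram"] == {1: 5, 2: 1}
    assert sum(stats["size_histogram"].values()) == stats["n_families"]


def test_paralog_pairs_share_a_genome():
    graph = nx.Graph([("a", "b"), ("b", "c")])
    genomes = {"a": {"G1"}, "b": {"G1"}, "c": {"G2"}}
    assert paralog_pair_count(graph, genomes) == 1


def test_planted_topologies_recovered(small_run):
    """Clique plants give density 1.0; star plants give 2/n (n > 2)."""
    from trgkit.clustering import build_rbh_graph, single_linkage_families

    clade = small_run["clade"]
    idx = clade.truth.by_gene()
    kept = [
        c for c in small_run["candidates"]
        if c.status in ("trg_noncoding_trace", "trg_no_trace")
    ]
    graph = build_rbh_graph(kept, small_run["rbh_pairs"])
    fams = single_linkage_families(graph)
    by_protein = {c.protein_id: c for c in kept}
    seen = set()
    for fam in fams:
        if len(fam) < 3:
            continue
        truth_fams = {
            idx[g].family_id
            for m in fam.members
            for _, g in by_protein[m].protein.sources
            if g in idx
        }
        assert len(truth_fams) == 1
        (family_id,) = truth_fams
        seen.add(family_id)
        topology = family_id.split("_")[-1]
        if topology == "clique":
            assert fam.density == 1.0
        elif topology == "star":
            assert fam.density == 2 / len(fam)
    planted = {
        r.family_id for r in clade.truth.rows
        if r.family_id and r.true_class.startswith("family_")
    }
    assert seen == planted
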