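"""Mutual-exclusivity graph, Louvain clustering, and cutoff tuning."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mexnet.association import AssociationRecord, ContingencyTable
from mexnet.cluster import (
    ModulePartition,
    MutexGraph,
    build_graph,
    filter_modules,
    louvain_cluster,
    newman_modularity,
    tune_cutoff,
)

from .conftest import modularity_oracle, set_partitions


def _record(a, b, p, exclusive=True):
    return AssociationRecord(
        gene_a=min(a, b), gene_b=max(a, b),
        table=ContingencyTable(0, 5, 5, 10),
        fisher_p=p, odds_ratio=0.1 if exclusive else 2.0,
        glm_coef=-1.0 if exclusive else 1.0, glm_p=p,
        mutually_exclusive=exclusive,
    )


def _mutex_from_nx(g: nx.Graph) -> MutexGraph:
    gg = g.copy()
    for _, _, d in gg.edges(data=True):
        d.setdefault("weight", 1.0)
        d.setdefault("p_value", 0.1)
    return MutexGraph(graph=gg, edge_cutoff=1.0)


class TestBuildGraph:
    def test_cutoff_filters_edges(self):
        records = [_record("A", "B", 1e-9), _record("C", "D", 1e-7)]
        mutex = build_graph(records, 1e-8)
        assert mutex.n_edges == 1
        assert set(mutex.graph.nodes) == {"A", "B"}

    def test_cutoff_one_keeps_all_flagged(self):
        records = [
            _record("A", "B", 0.5), _record("B", "C", 1e-4),
            _record("C", "D", 1e-3, exclusive=False),
        ]
        mutex = build_graph(records, 1.0)
        assert mutex.n_edges == 2

    def test_weights_are_neg_log10_p(self):
        ps = [1e-9, 3.7e-5, 0.02]
        records = [_record("A", "B", ps[0]), _record("B", "C", ps[1]),
                   _record("C", "D", ps[2])]
        mutex = build_graph(records, 1.0)
        for rec, p in zip(records, ps):
            w = mutex.graph[rec.gene_a][rec.gene_b]["weight"]
            assert w == pytest.approx(-np.log10(p), abs=1e-12)

    def test_monotone_edge_sets(self):
        rng = np.random.default_rng(4)
        records = [
            _record(f"G{i}", f"G{j}", float(10 ** (-12 * rng.random())))
            for i, j in itertools.combinations(range(12), 2)
        ]
        previous = None
        for cutoff in (1e-2, 1e-4, 1e-6, 1e-8):
            edges = {
                frozenset(e) for e in build_graph(records, cutoff).graph.edges
            }
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestLouvain:
    def test_two_disjoint_cliques_exact(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        part = louvain_cluster(_mutex_from_nx(g), seed=0)
        assert sorted(part.sizes) == [4, 4]
        assert {frozenset(m) for m in part.modules} == {
            frozenset({"G0", "G1", "G2", "G3"}),
            frozenset({"G4", "G5", "G6", "G7"}),
        }

    def test_single_triangle_one_module(self):
        g = nx.relabel_nodes(nx.complete_graph(3), {0: "A", 1: "B", 2: "C"})
        part = louvain_cluster(_mutex_from_nx(g), seed=0)
        assert part.modules == [{"A", "B", "C"}]

    def test_clique_ring_four_modules(self):
        # ring of 4 triangles joined by single bridges
        g = nx.ring_of_cliques(4, 3)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        part = louvain_cluster(_mutex_from_nx(g), seed=0)
        assert len(part.modules) == 4
        assert part.modularity == pytest.approx(
            modularity_oracle(g, part.modules), abs=1e-12
        )

    def test_reported_modularity_recomputed_independently(self):
        rng = np.random.default_rng(8)
        g = nx.gnp_random_graph(15, 0.3, seed=8)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.uniform(0.5, 5.0))
            d["p_value"] = 0.01
        part = louvain_cluster(MutexGraph(g, 1.0), seed=0)
        assert part.modularity == pytest.approx(
            modularity_oracle(g, part.modules), abs=1e-12
        )

    def test_partition_is_exhaustive_and_disjoint(self):
        g = nx.relabel_nodes(
            nx.gnp_random_graph(20, 0.2, seed=3), {i: f"N{i:02d}" for i in range(20)}
        )
        g.remove_nodes_from(list(nx.isolates(g)))
        part = louvain_cluster(_mutex_from_nx(g), seed=0)
        union = set().union(*part.modules)
        assert union == set(g.nodes)
        assert sum(part.sizes) == len(union)

    def test_deterministic_across_reruns(self):
        g = nx.relabel_nodes(
            nx.gnp_random_graph(25, 0.25, seed=5), {i: f"N{i:02d}" for i in range(25)}
        )
        mutex = _mutex_from_nx(g)
        p1 = louvain_cluster(mutex, seed=7)
        p2 = louvain_cluster(mutex, seed=7)
        assert p1.modules == p2.modules
        assert p1.modularity == p2.modularity

    def test_empty_graph_empty_partition(self):
        part = louvain_cluster(MutexGraph(nx.Graph(), 1e-8), seed=0)
        assert part.modules == []

    @pytest.mark.parametrize(
        "maker",
        [
            lambda: nx.path_graph(6),
            lambda: nx.cycle_graph(7),
            lambda: nx.complete_graph(5),
            lambda: nx.star_graph(5),
            lambda: nx.barbell_graph(3, 1),
            lambda: nx.cubical_graph(),
        ],
        ids=["path6", "cycle7", "K5", "star6", "barbell", "cube8"],
    )
    def test_near_optimal_on_small_graphs(self, maker):
        """Louvain reaches >= 95% of the exact maximum modularity,
        found by enumerating every set partition of the nodes."""
        g = nx.relabel_nodes(maker(), {i: f"N{i}" for i in maker().nodes})
        part = louvain_cluster(_mutex_from_nx(g), seed=0)
        best = max(
            modularity_oracle(g, p) for p in set_partitions(list(g.nodes))
        )
        assert part.modularity >= 0.95 * best - 1e-12


class TestFilterModules:
    def _partition(self, sizes):
        mods, k = [], 0
        for s in sizes:
            mods.append({f"G{k + i:03d}" for i in range(s)})
            k += s
        return ModulePartition(mods, 0.5, 1e-8, 0)

    def test_small_modules_removed(self):
        out = filter_modules(self._partition([5, 3, 2, 1]))
        assert out.sizes == [5, 3]

    def test_renumbered_by_size(self):
        part = self._partition([3, 5, 4])
        out = filter_modules(part)
        assert out.sizes == [5, 4, 3]

    def test_all_singletons_empty(self):
        out = filter_modules(self._partition([1, 1, 1]))
        assert out.modules == []


class TestTuneCutoff:
    def test_fallback_when_out_of_range(self, caplog):
        records = [_record("A", "B", 1e-5), _record("B", "C", 1e-5),
                   _record("A", "C", 1e-5)]
        cutoff, part = tune_cutoff(records, target_range=(5, 10))
        assert cutoff == 1e-4  # least stringent among equally-distant grid points
        assert len(part.modules) <= 1
        assert any("no grid cutoff" in r.message for r in caplog.records)

    def test_single_cutoff_grid(self):
        records = [_record("A", "B", 1e-5), _record("B", "C", 1e-5),
                   _record("A", "C", 1e-5)]
        cutoff, _ = tune_cutoff(records, grid=(1e-4,))
        assert cutoff == 1e-4

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            tune_cutoff([])

    def test_synthetic_six_modules_in_target(self):
        from mexnet.association import pairwise_associations
        from mexnet.simulate import SimSpec, simulate

        matrix, _, _ = simulate(SimSpec(seed=1))
        records = pairwise_associations(matrix)
        cutoff, part = tune_cutoff(records, seed=1)
        assert 5 <= len(part.modules) <= 10
        assert all(s >= 3 for s in part.sizes)
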