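"""Correlation graphs, connected components and MCL clustering."""

import warnings

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from mitofunnel import (
    ClusterSet,
    CorrelationGraph,
    PipelineConfig,
    SimConfig,
    build_protein_graph,
    build_sample_graph,
    cluster_profiles,
    connected_components,
    generate_dataset,
    mcl_cluster,
    pearson,
)

from conftest import make_matrix
from mcl_reference import mcl_reference_partition


def graph_from_edges(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return CorrelationGraph(nodes=list(range(n)), graph=g, threshold=0.5)


def random_graph(rng, n, p=0.25):
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j, float(rng.uniform(0.5, 1.0))))
    return graph_from_edges(n, edges)


class TestPearson:
    def test_self_correlation_is_one(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert pearson(x, x) == 1.0

    def test_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, -x) == -1.0

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            assert pearson(x, y) == pytest.approx(
                sps.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestGraphBuilders:
    def test_duplicated_samples_give_complete_graph(self, config):
        rng = np.random.default_rng(0)
        col = rng.uniform(1, 10, size=5)
        vals = np.tile(col[:, None], (1, 18))
        matrix = make_matrix(vals)
        g = build_sample_graph(matrix, config)
        assert g.graph.number_of_edges() == 18 * 17 // 2
        assert all(w == pytest.approx(1.0) for _, _, w in g.edge_list())

    def test_uncorrelated_samples_give_edgeless_graph(self, config):
        rng = np.random.default_rng(1)
        matrix = make_matrix(rng.uniform(1, 100, size=(50, 18)))
        g = build_sample_graph(matrix, config)  # independent columns: r << 0.96
        assert g.graph.number_of_edges() == 0

    def test_identical_profiles_edge_weight_one(self, config):
        vals = np.vstack([np.linspace(1, 2, 9), 5 * np.linspace(1, 2, 9)])
        matrix = make_matrix(np.hstack([vals, vals]), replicates_per_group=3)
        syn = matrix.subset_compartment("synaptic")
        g = build_protein_graph(syn, config)
        assert g.graph.has_edge("P0", "P1")
        assert g.graph.edges["P0", "P1"]["weight"] == pytest.approx(1.0)

    def test_protein_edges_match_brute_force_threshold_scan(self, config):
        rng = np.random.default_rng(7)
        vals = np.exp(rng.normal(2, 1, size=(25, 9)))
        matrix = make_matrix(np.hstack([vals, vals]), replicates_per_group=3)
        syn = matrix.subset_compartment("synaptic")
        low = PipelineConfig(pearson_threshold=0.3)
        g = build_protein_graph(syn, low)
        expected = set()
        ids = syn.protein_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = pearson(vals[i], vals[j])
                if r >= 0.3:
                    expected.add(frozenset((ids[i], ids[j])))
        got = {frozenset((u, v)) for u, v, _ in g.edge_list()}
        assert got == expected

    def test_no_self_edges_and_weights_at_least_threshold(self, config):
        rng = np.random.default_rng(11)
        vals = np.exp(rng.normal(2, 1, size=(30, 9)))
        matrix = make_matrix(np.hstack([vals, vals]))
        g = build_protein_graph(
            matrix.subset_compartment("synaptic"), PipelineConfig(pearson_threshold=0.2)
        )
        assert not any(u == v for u, v, _ in g.edge_list())
        assert all(w >= 0.2 for _, _, w in g.edge_list())

    def test_zero_variance_protein_skipped_with_warning(self, config):
        vals = np.vstack([np.full(18, 4.0), np.tile(np.linspace(1, 2, 9), 2)])
        matrix = make_matrix(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            g = build_protein_graph(matrix.subset_compartment("synaptic"), config)
        assert g.graph.degree["P0"] == 0
        assert "P0" in g.nodes  # still a node -> singleton downstream


class TestComponents:
    def test_edgeless_graph(self):
        g = graph_from_edges(5, [])
        assert connected_components(g) == [[0], [1], [2], [3], [4]]

    def test_complete_graph(self):
        edges = [(i, j, 1.0) for i in range(6) for j in range(i + 1, 6)]
        assert connected_components(graph_from_edges(6, edges)) == [list(range(6))]

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            g = random_graph(rng, n, p=0.15)
            # independent BFS
            seen, parts = set(), []
            adj = {u: set() for u in range(n)}
            for u, v, _ in g.edge_list():
                adj[u].add(v)
                adj[v].add(u)
            for start in range(n):
                if start in seen:
                    continue
                queue, comp = [start], set()
                while queue:
                    u = queue.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    queue.extend(adj[u] - comp)
                seen |= comp
                parts.append(sorted(comp))
            assert [sorted(c) for c in connected_components(g)] == parts


class TestMCL:
    def test_two_disjoint_triangles(self, config):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
                 (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)]
        cs = mcl_cluster(graph_from_edges(6, edges), config)
        assert cs.clusters == [[0, 1, 2], [3, 4, 5]]

    def test_edgeless_graph_gives_singletons(self, config):
        cs = mcl_cluster(graph_from_edges(4, []), config)
        assert cs.clusters == [[0], [1], [2], [3]]

    def test_bridged_cliques_split_as_reference(self, config):
        edges = []
        for base in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append((base + i, base + j, 1.0))
        edges.append((0, 4, 1.0))
        g = graph_from_edges(8, edges)
        cs = mcl_cluster(g, config)
        assert {frozenset(c) for c in cs.clusters} == mcl_reference_partition(
            g.nodes, edges, inflation=config.mcl_inflation
        )
        assert cs.n_clusters == 2

    def test_matches_independent_reference_on_random_graphs(self, config):
        rng = np.random.default_rng(33)
        for _ in range(40):
            n = int(rng.integers(4, 22))
            g = random_graph(rng, n, p=0.3)
            ours = {frozenset(c) for c in mcl_cluster(g, config).clusters}
            ref = mcl_reference_partition(
                g.nodes, g.edge_list(), inflation=config.mcl_inflation
            )
            assert ours == ref

    def test_output_is_partition_fuzz(self, config):
        rng = np.random.default_rng(99)
        for _ in range(500):
            n = int(rng.integers(1, 41))
            g = random_graph(rng, n, p=float(rng.uniform(0.05, 0.5)))
            cs = mcl_cluster(g, config)
            flat = [x for c in cs.clusters for x in c]
            assert sorted(flat) == list(range(n))  # disjoint and covering
            assert all(len(c) > 0 for c in cs.clusters)

    def test_invariant_to_node_relabelling(self, config):
        rng = np.random.default_rng(17)
        g = random_graph(rng, 15, p=0.3)
        perm = rng.permutation(15)
        mapping = {i: int(perm[i]) for i in range(15)}
        edges2 = [(mapping[u], mapping[v], w) for u, v, w in g.edge_list()]
        g2 = graph_from_edges(15, edges2)
        ours = {frozenset(mapping[x] for x in c) for c in mcl_cluster(g, config).clusters}
        theirs = {frozenset(c) for c in mcl_cluster(g2, config).clusters}
        assert ours == theirs

    def test_inflation_granularity_trend(self):
        """Higher inflation should not coarsen clusterings on average;
        individual violations are a known MCL caveat and are logged."""
        rng = np.random.default_rng(55)
        counts = {1.5: [], 2.2: [], 4.0: []}
        for _ in range(20):
            g = random_graph(rng, 18, p=0.35)
            for infl in counts:
                cfg = PipelineConfig(mcl_inflation=infl)
                counts[infl].append(mcl_cluster(g, cfg).n_clusters)
        for a, b in [(1.5, 2.2), (2.2, 4.0)]:
            violations = sum(x > y for x, y in zip(counts[a], counts[b]))
            if violations:
                warnings.warn(f"inflation {a}->{b}: {violations} granularity reversals")
        assert np.mean(counts[1.5]) <= np.mean(counts[2.2]) + 1e-9
        assert np.mean(counts[2.2]) <= np.mean(counts[4.0]) + 1e-9

    def test_recovers_planted_classes_zero_noise(self, config):
        cfg = SimConfig(n_proteins=120, noise_sd=0.0, frac_single_peptide=0.0, seed=9)
        matrix, truth = generate_dataset(cfg)
        varying = truth.index[truth["class"] != "flat"]

        # non-synaptic: divergent proteins are flat there -> drop them too;
        # the four temporal classes are mutually separable at r = 0.96
        ns_ids = [p for p in varying if truth.loc[p, "class"] != "divergent_old"]
        ns = matrix.subset_compartment("non_synaptic").subset_proteins(ns_ids)
        cs = mcl_cluster(build_protein_graph(ns, config), config)
        labels_true = [truth.loc[p, "class"] for p in ns_ids]
        member = cs.membership()
        labels_pred = [member[p] for p in ns_ids]
        assert adjusted_rand_score(labels_true, labels_pred) == 1.0

        # synaptic: divergent-up is exactly affinely related to late_up
        # (and divergent-down to late_down), so Pearson similarity merges
        # them; assert recovery of that merged partition
        syn = matrix.subset_compartment("synaptic").subset_proteins(list(varying))
        cs_syn = mcl_cluster(build_protein_graph(syn, config), config)
        gm = matrix.subset_compartment("synaptic").subset_proteins(list(varying))
        merged = []
        div_rank = 0
        for p in varying:
            cls = truth.loc[p, "class"]
            if cls == "divergent_old":
                cls = "late_up" if div_rank % 2 == 0 else "late_down"
                div_rank += 1
            merged.append(cls)
        member_syn = cs_syn.membership()
        pred_syn = [member_syn[p] for p in varying]
        assert adjusted_rand_score(merged, pred_syn) == 1.0


class TestClusterProfiles:
    def test_singleton_cluster_keeps_own_profile(self, config):
        vals = np.hstack([np.tile([1, 2, 4], 3).reshape(1, -1)] * 2).reshape(1, 18)
        matrix = make_matrix(vals)
        cs = cluster_profiles(ClusterSet(clusters=[["P0"]]), matrix)
        prof = cs.profiles.loc[0]
        # replicate layout: ages alternate -> per-age means from group_means
        from mitofunnel import group_means
        gm = group_means(matrix)
        for age in ("young", "mid", "old"):
            expected = gm.loc["P0", :].xs(age, level="age").mean()
            assert prof[age] == pytest.approx(expected)

    def test_matches_nested_loop_oracle(self, config):
        rng = np.random.default_rng(4)
        matrix = make_matrix(rng.uniform(1, 10, size=(8, 18)))
        syn = matrix.subset_compartment("synaptic")
        clusters = ClusterSet(clusters=[["P0", "P3", "P5"], ["P1"], ["P2", "P7"]])
        cs = cluster_profiles(clusters, syn)
        from mitofunnel import group_means
        gm = group_means(syn)["synaptic"]
        for ci, members in enumerate(clusters.clusters):
            for age in ("young", "mid", "old"):
                expected = float(np.mean([gm.loc[p, age] for p in members]))
                assert cs.profiles.loc[ci, age] == pytest.approx(expected, abs=1e-12)

    def test_unknown_member_raises(self, config):
        matrix = make_matrix(np.full((2, 18), 1.5))
        with pytest.raises(KeyError):
            cluster_profiles(ClusterSet(clusters=[["P0", "MISSING"]]), matrix)
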