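"""Pearson correlation graphs and Markov (MCL) clustering.

Graphs are built by thresholding the sample Pearson correlation at
``pearson_threshold`` (default 0.96): sample-sample graphs correlate sample
abundance vectors over all proteins; protein-protein graphs correlate
protein expression vectors across one compartment's samples.  Negative
correlations never form edges (the threshold is on signed r).  Clustering
uses an in-house Markov Cluster (MCL) implementation: alternating matrix
expansion and elementwise inflation of a column-stochastic matrix with
pruning, run to a near-idempotent limit whose attractor structure defines
the clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import AGES, PipelineConfig
from .io import AbundanceMatrix, group_means


class MCLConvergenceError(RuntimeError):
    """MCL failed to converge; carries iteration diagnostics."""

    def __init__(self, iterations: int, last_change: float):
        self.iterations = iterations
        self.last_change = last_change
        super().__init__(
            f"MCL did not converge after {iterations} iterations "
            f"(last max change {last_change:.3e})"
        )


@dataclass
class CorrelationGraph:
    """Thresholded Pearson graph over samples or proteins.

    ``nodes`` preserves input order (including zero-variance nodes, which
    carry no edges); ``graph`` is an undirected networkx Graph whose edge
    ``weight`` attributes are the Pearson r values (all >= ``threshold``).
    """

    nodes: list[str]
    graph: nx.Graph
    threshold: float

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        ]


@dataclass
class ClusterSet:
    """Disjoint clusters of node ids with optional profiles and labels."""

    clusters: list[list[str]]
    profiles: pd.DataFrame | None = None  # clusters x ages mean profile
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("clusters must be non-empty")
            if seen & set(c):
                raise ValueError("clusters must be disjoint")
            seen |= set(c)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {node: i for i, c in enumerate(self.clusters) for node in c}


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-D vectors")
    if xa.size < 3:
        raise ValueError("pearson requires length >= 3")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sx = np.sqrt((xd * xd).sum())
    sy = np.sqrt((yd * yd).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("undefined correlation: zero-variance vector")
    return float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))


def _threshold_graph(
    data: np.ndarray, node_ids: list[str], threshold: float, what: str
) -> CorrelationGraph:
    """Graph over the rows of ``data`` with edges where r >= threshold."""
    sd = data.std(axis=1)
    # relative tolerance: constant rows built from large values carry
    # rounding noise of order 1e-16 * mean, far below any real signal
    scale = np.abs(data).mean(axis=1)
    ok = sd > 1e-9 * np.maximum(scale, np.finfo(float).tiny)
    if not ok.all():
        skipped = [node_ids[i] for i in np.flatnonzero(~ok)]
        warnings.warn(
            f"skipping {len(skipped)} zero-variance {what}(s) "
            f"(no edges): {skipped[:5]}",
            stacklevel=3,
        )
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    idx = np.flatnonzero(ok)
    if idx.size >= 2:
        corr = np.corrcoef(data[idx])
        corr = np.clip(corr, -1.0, 1.0)
        ii, jj = np.nonzero(np.triu(corr >= threshold, k=1))
        for a, b in zip(ii, jj):
            g.add_edge(
                node_ids[idx[a]], node_ids[idx[b]], weight=float(corr[a, b])
            )
    return CorrelationGraph(nodes=list(node_ids), graph=g, threshold=threshold)


def build_sample_graph(
    matrix: AbundanceMatrix, config: PipelineConfig
) -> CorrelationGraph:
    """Sample-sample correlation graph over all proteins."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    data = matrix.values.to_numpy(dtype=float).T  # samples x proteins
    g = _threshold_graph(
        data, list(matrix.values.columns), config.pearson_threshold, "sample"
    )
    for sid in g.nodes:
        g.graph.nodes[sid]["compartment"] = matrix.samples.loc[sid, "compartment"]
        g.graph.nodes[sid]["age"] = matrix.samples.loc[sid, "age"]
    return g


def build_protein_graph(
    matrix: AbundanceMatrix, config: PipelineConfig
) -> CorrelationGraph:
    """Protein-protein correlation graph across one compartment's samples."""
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate profiles")
    data = matrix.values.to_numpy(dtype=float)
    return _threshold_graph(
        data, list(matrix.values.index), config.pearson_threshold, "protein"
    )


def connected_components(graph: CorrelationGraph) -> list[list[str]]:
    """Maximal connected node sets, ordered by smallest member (input order)."""
    order = {n: i for i, n in enumerate(graph.nodes)}
    comps = [sorted(c, key=order.get) for c in nx.connected_components(graph.graph)]
    comps.sort(key=lambda c: order[c[0]])
    return comps


# -- MCL ---------------------------------------------------------------

def _normalise_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0.0] = 1.0
    return m / colsum


def _mcl_dense(
    adj: np.ndarray,
    inflation: float,
    expansion: int,
    prune: float,
    tol: float,
    max_iter: int = 200,
) -> np.ndarray:
    """Run MCL on a dense adjacency matrix; returns the limit matrix."""
    n = adj.shape[0]
    m = adj.astype(float).copy()
    np.fill_diagonal(m, 0.0)
    # self-loops at the max incident weight stabilise convergence
    loops = m.max(axis=0)
    loops[loops == 0.0] = 1.0
    m[np.diag_indices(n)] = loops
    m = _normalise_columns(m)

    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = _normalise_columns(np.power(m, inflation))
        m[m < prune] = 0.0
        m = _normalise_columns(m)
        change = float(np.abs(m - prev).max())
        if change < tol:
            return m
    raise MCLConvergenceError(max_iter, change)


def _clusters_from_limit(limit: np.ndarray) -> list[list[int]]:
    """Interpret the MCL limit matrix via its attractors.

    Attractors are nodes with positive mass on their own diagonal.
    Attractors sharing mass merge into one attractor system; every other
    node joins the system of the attractor holding the largest weight in
    its column (exact ties resolve to the system containing the smallest
    node index).  Nodes attracted by nothing become singletons.
    """
    n = limit.shape[0]
    attractors = np.flatnonzero(limit.diagonal() > 0.0)
    # union attractor systems through shared mass in rows/columns
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors.tolist())
    for a in attractors:
        linked = np.flatnonzero((limit[a, attractors] > 0) | (limit[attractors, a] > 0))
        for b in attractors[linked]:
            if a != b:
                sys_graph.add_edge(int(a), int(b))
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda c: c[0])
    system_of = {a: i for i, c in enumerate(systems) for a in c}

    clusters: list[list[int]] = [list(c) for c in systems]
    for j in range(n):
        if j in system_of:
            continue
        mass = limit[attractors, j] if attractors.size else np.array([])
        if mass.size and mass.max() > 0.0:
            best = mass.max()
            best_attr = attractors[np.flatnonzero(mass == best)]
            # ties: join the system containing the smallest node id
            target = min(
                (min(systems[system_of[int(a)]]), system_of[int(a)])
                for a in best_attr
            )[1]
            clusters[target].append(j)
        else:
            clusters.append([j])
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: c[0])
    return clusters


def mcl_cluster(graph: CorrelationGraph, config: PipelineConfig) -> ClusterSet:
    """Markov-cluster a correlation graph.

    The graph decomposes into connected components first (MCL can never
    merge disconnected components, and per-component runs keep the dense
    iteration small); isolated nodes become singleton clusters.  Edge
    weights (Pearson r) are the transition mass unless
    ``config.mcl_weighted`` is False, in which case edges count 1.
    """
    order = {n: i for i, n in enumerate(graph.nodes)}
    clusters: list[list[str]] = []
    for comp in nx.connected_components(graph.graph):
        members = sorted(comp, key=order.get)
        if len(members) == 1:
            clusters.append(members)
            continue
        sub = graph.graph.subgraph(members)
        n = len(members)
        adj = np.zeros((n, n))
        pos = {m: i for i, m in enumerate(members)}
        for u, v, d in sub.edges(data=True):
            w = float(d["weight"]) if config.mcl_weighted else 1.0
            adj[pos[u], pos[v]] = w
            adj[pos[v], pos[u]] = w
        limit = _mcl_dense(
            adj,
            config.mcl_inflation,
            int(config.mcl_expansion),
            config.mcl_prune,
            config.mcl_tol,
        )
        for idx_cluster in _clusters_from_limit(limit):
            clusters.append([members[i] for i in idx_cluster])
    clusters.sort(key=lambda c: order[c[0]])
    return ClusterSet(clusters=clusters)


def cluster_profiles(
    clusters: ClusterSet, matrix: AbundanceMatrix
) -> ClusterSet:
    """Attach mean temporal profiles (mean abundance per age) to clusters.

    The profile of a cluster is the mean over member proteins of the
    per-age group means, pooling the compartments present in ``matrix``
    (in the pipeline this is called with single-compartment matrices).
    """
    gm = group_means(matrix)
    # average over compartments present -> proteins x ages
    per_age = pd.concat(
        {age: gm.xs(age, axis=1, level="age").mean(axis=1) for age in AGES},
        axis=1,
    )[list(AGES)]
    known = set(matrix.protein_ids)
    rows = []
    for c in clusters.clusters:
        missing = [m for m in c if m not in known]
        if missing:
            raise KeyError(f"unknown cluster member(s): {missing[:5]}")
        rows.append(per_age.loc[c].mean(axis=0))
    profiles = pd.DataFrame(rows, index=range(len(clusters.clusters)))
    return ClusterSet(
        clusters=clusters.clusters, profiles=profiles, labels=clusters.labels
    )


def write_graphml(graph: CorrelationGraph, path) -> None:
    """Export a correlation graph (node attributes included) as GraphML."""
    nx.write_graphml(graph.graph, path)


def write_membership(clusters: ClusterSet, path) -> None:
    """Write cluster membership as TSV (node_id, cluster_id)."""
    rows = [
        {"node_id": node, "cluster_id": i}
        for i, c in enumerate(clusters.clusters)
        for node in c
    ]
    pd.DataFrame(rows, columns=["node_id", "cluster_id"]).to_csv(
        path, sep="\t", index=False
    )
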