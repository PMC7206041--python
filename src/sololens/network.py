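"""DEG-seeded weighted interaction network analysis.

The network is built from a STRING-style interaction table: edges with
combined confidence score strictly above a cutoff (default 700) are kept,
optionally requiring support from named evidence channels, and the node
set is the DEG seeds plus (under the default first-shell policy) their
direct interactors. Edge weights are the confidence scores.

Downstream: hubs are the top decile of the degree distribution; modules
are found by greedily growing overlapping node sets that maximize
cohesiveness f(V) = w_in / (w_in + w_bound + penalty*|V|), merging
near-duplicates by overlap score, and scoring each cluster with a
one-sided Mann-Whitney U test of per-vertex internal vs boundary weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu

from .io import ConfigError, DegTable, InteractionTable

log = logging.getLogger(__name__)


class SeedError(ValueError):
    """No seed node could be found in the interaction table."""


@dataclass
class WeightedNetwork:
    """Undirected score-weighted graph with seed flags on the nodes."""

    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def seeds(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_seed")}

    def edge_weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]


@dataclass
class HubSet:
    node_ids: list[str]
    degrees: dict[str, int]
    cutoff_degree: int
    fraction: float


@dataclass
class Cluster:
    nodes: frozenset[str]
    cohesiveness: float
    w_in: float
    w_bound: float
    p_value: float | None = None
    significant: bool | None = None

    @property
    def size(self) -> int:
        return len(self.nodes)


def build_network(
    seeds: DegTable | Iterable[str],
    interactions: InteractionTable,
    score_min: int = 700,
    expansion: str = "first_shell",
    evidence_channels: Sequence[str] | None = None,
    alias_map: dict[str, str] | None = None,
) -> WeightedNetwork:
    """Build the seed network from a thresholded interaction table.

    Edges with combined_score strictly greater than ``score_min`` are
    retained; if ``evidence_channels`` is given, an edge additionally needs
    a positive score in at least one listed channel. Under ``first_shell``
    the node set is the seeds plus their direct interactors and the edge
    set is every retained interaction among included nodes; ``seeds_only``
    restricts nodes to the seeds. Seeds without any retained edge are kept
    as isolated nodes and reported in the metadata.
    """
    if expansion not in ("first_shell", "seeds_only"):
        raise ConfigError(f"unknown expansion policy {expansion!r}")
    if not 0 <= score_min <= 999:
        raise ConfigError("score_min must lie in 0-999")
    seed_ids = seeds.gene_ids if isinstance(seeds, DegTable) else list(seeds)
    if alias_map:
        seed_ids = [alias_map.get(s, s) for s in seed_ids]
    seed_set = set(seed_ids)
    if not seed_set:
        raise SeedError("empty seed list")

    known = interactions.proteins()
    missing = sorted(seed_set - known)
    # an empty table carries no information: keep the seeds as isolated nodes
    if known and len(missing) == len(seed_set):
        raise SeedError(f"no seed found in the interaction table; misses: {missing}")

    df = interactions.frame
    keep = df["combined_score"] > score_min
    if evidence_channels:
        absent = [c for c in evidence_channels if c not in df.columns]
        if absent:
            raise ConfigError(f"evidence channel(s) not in table: {absent}")
        keep &= (df[list(evidence_channels)] > 0).any(axis=1)
    retained = df.loc[keep]

    incident = retained["protein_a"].isin(seed_set) | retained["protein_b"].isin(seed_set)
    if expansion == "first_shell":
        shell = retained.loc[incident]
        nodes = seed_set | set(shell["protein_a"]) | set(shell["protein_b"])
    else:
        nodes = seed_set
    edges = retained.loc[
        retained["protein_a"].isin(nodes) & retained["protein_b"].isin(nodes)
    ]

    graph = nx.Graph()
    for n in sorted(nodes):
        graph.add_node(n, is_seed=n in seed_set)
    for a, b, w in edges[["protein_a", "protein_b", "combined_score"]].itertuples(index=False):
        graph.add_edge(a, b, weight=int(w))
    isolated_seeds = sorted(n for n in seed_set if graph.degree(n) == 0)
    if isolated_seeds:
        log.info("%d isolated seed(s) kept: %s", len(isolated_seeds), isolated_seeds[:10])
    return WeightedNetwork(
        graph=graph,
        metadata={
            "score_min": score_min,
            "expansion": expansion,
            "evidence_channels": list(evidence_channels) if evidence_channels else None,
            "seeds_missing_from_table": missing,
            "isolated_seeds": isolated_seeds,
        },
    )


def network_from_interactions(
    interactions: InteractionTable, score_min: int = 0
) -> WeightedNetwork:
    """Whole-table network (every protein a node); handy for fixtures."""
    return build_network(
        sorted(interactions.proteins()), interactions, score_min=score_min,
        expansion="seeds_only",
    )


def find_hubs(net: WeightedNetwork, fraction: float = 0.10) -> HubSet:
    """Top-decile-degree nodes: k = ceil(fraction * n), ranked by
    (degree descending, node id ascending)."""
    n = net.n_nodes
    if n < 1:
        raise ConfigError("empty network")
    k = math.ceil(fraction * n)
    degrees = dict(net.graph.degree())
    ranked = sorted(degrees, key=lambda v: (-degrees[v], v))
    hubs = ranked[:k]
    return HubSet(
        node_ids=hubs,
        degrees={v: degrees[v] for v in hubs},
        cutoff_degree=degrees[hubs[-1]],
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Cohesiveness clustering


def _graph_of(net: WeightedNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, WeightedNetwork) else net


def cohesiveness(
    net: WeightedNetwork | nx.Graph, node_set: Iterable[str], penalty: float = 2.0
) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty*|V|), 0 when the denominator is 0."""
    g = _graph_of(net)
    members = set(node_set)
    if not members:
        raise ConfigError("empty node set")
    w_in, w_bound = _internal_boundary(g, members)
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _internal_boundary(g: nx.Graph, members: set[str]) -> tuple[float, float]:
    w_in = w_bound = 0.0
    for v in members:
        for u in g[v]:
            w = g[v][u].get("weight", 1.0)
            if u in members:
                if v < u:
                    w_in += w
            else:
                w_bound += w
    return w_in, w_bound


def _unweighted_density(g: nx.Graph, members: set[str]) -> float:
    n = len(members)
    if n < 2:
        return 0.0
    m = sum(1 for v in members for u in g[v] if u in members and v < u)
    return m / (n * (n - 1) / 2)


def grow_clusters(
    net: WeightedNetwork | nx.Graph,
    penalty: float = 2.0,
    min_size: int = 3,
    min_density: float = 0.5,
    seed_order: str = "degree_desc",
) -> list[Cluster]:
    """Greedy overlapping cluster growth by cohesiveness maximization.

    Seeds are taken in (degree descending, id ascending) order among nodes
    not yet inside any grown cluster. From the current set V the single
    best move — adding a boundary vertex or removing an internal non-seed
    vertex — is applied while it strictly increases cohesiveness; the
    local maximum is recorded. Clusters may overlap because growth can
    re-enter nodes used by earlier clusters. Clusters smaller than
    ``min_size`` or with unweighted edge density below ``min_density`` are
    discarded at the end.
    """
    if seed_order != "degree_desc":
        raise ConfigError(f"unknown seed order {seed_order!r}")
    g = _graph_of(net)
    degrees = dict(g.degree())
    order = sorted(g.nodes, key=lambda v: (-degrees[v], v))
    used: set[str] = set()
    raw: list[set[str]] = []
    for seed in order:
        if seed in used:
            continue
        members = {seed}
        w_in, w_bound = _internal_boundary(g, members)
        f = _score(w_in, w_bound, len(members), penalty)
        while True:
            best = None  # (new_f, action_rank, node, new_w_in, new_w_bound)
            boundary = {u for v in members for u in g[v] if u not in members}
            for u in sorted(boundary):
                d_in = sum(g[u][v].get("weight", 1.0) for v in g[u] if v in members)
                wdeg = sum(g[u][v].get("weight", 1.0) for v in g[u])
                n_in = w_in + d_in
                n_bound = w_bound - d_in + (wdeg - d_in)
                nf = _score(n_in, n_bound, len(members) + 1, penalty)
                if best is None or nf > best[0] + 1e-15:
                    best = (nf, 0, u, n_in, n_bound)
            for v in sorted(members - {seed}):
                d_in = sum(g[v][u].get("weight", 1.0) for u in g[v] if u in members)
                wdeg = sum(g[v][u].get("weight", 1.0) for u in g[v])
                n_in = w_in - d_in
                n_bound = w_bound + d_in - (wdeg - d_in)
                nf = _score(n_in, n_bound, len(members) - 1, penalty)
                if best is None or nf > best[0] + 1e-15:
                    best = (nf, 1, v, n_in, n_bound)
            if best is None or best[0] <= f + 1e-12:
                break
            f, action, node, w_in, w_bound = best[0], best[1], best[2], best[3], best[4]
            if action == 0:
                members.add(node)
            else:
                members.remove(node)
        used |= members
        raw.append(members)

    clusters: list[Cluster] = []
    for members in raw:
        if len(members) < min_size:
            continue
        if _unweighted_density(g, members) < min_density:
            continue
        w_in, w_bound = _internal_boundary(g, members)
        clusters.append(
            Cluster(
                nodes=frozenset(members),
                cohesiveness=_score(w_in, w_bound, len(members), penalty),
                w_in=w_in,
                w_bound=w_bound,
            )
        )
    return clusters


def _score(w_in: float, w_bound: float, size: int, penalty: float) -> float:
    denom = w_in + w_bound + penalty * size
    return w_in / denom if denom > 0 else 0.0


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """omega(A, B) = |A n B|^2 / (|A| * |B|)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        return 0.0
    inter = len(sa & sb)
    return inter * inter / (len(sa) * len(sb))


def merge_overlapping(
    clusters: list[Cluster],
    net: WeightedNetwork | nx.Graph,
    omega_threshold: float = 0.8,
    penalty: float = 2.0,
) -> list[Cluster]:
    """Transitively merge cluster pairs with overlap score > threshold.

    Merged clusters are the union of their node sets with cohesiveness
    recomputed from the graph.
    """
    g = _graph_of(net)
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if overlap_score(clusters[i].nodes, clusters[j].nodes) > omega_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, set[str]] = {}
    for i, cl in enumerate(clusters):
        groups.setdefault(find(i), set()).update(cl.nodes)
    merged: list[Cluster] = []
    for members in groups.values():
        w_in, w_bound = _internal_boundary(g, members)
        merged.append(
            Cluster(
                nodes=frozenset(members),
                cohesiveness=_score(w_in, w_bound, len(members), penalty),
                w_in=w_in,
                w_bound=w_bound,
            )
        )
    merged.sort(key=lambda c: (-c.cohesiveness, sorted(c.nodes)))
    return merged


def cluster_significance(
    net: WeightedNetwork | nx.Graph, cluster: Cluster | Iterable[str]
) -> float:
    """One-sided Mann-Whitney U p value for a cluster's internal cohesion.

    Compares, across the cluster's vertices, each vertex's summed edge
    weight to other members against its summed weight to non-members
    (alternative: internal > boundary). The exact U distribution is used
    for per-group sizes up to 20, the normal approximation with tie
    correction beyond.
    """
    g = _graph_of(net)
    members = set(cluster.nodes if isinstance(cluster, Cluster) else cluster)
    if len(members) < 2:
        log.warning("cluster of size %d: significance undefined, p = 1", len(members))
        return 1.0
    internal, boundary = [], []
    for v in members:
        w_int = sum(g[v][u].get("weight", 1.0) for u in g[v] if u in members)
        w_out = sum(g[v][u].get("weight", 1.0) for u in g[v] if u not in members)
        internal.append(w_int)
        boundary.append(w_out)
    method = "exact" if len(members) <= 20 else "asymptotic"
    res = mannwhitneyu(internal, boundary, alternative="greater", method=method)
    return float(res.pvalue)


def annotate_significance(
    net: WeightedNetwork | nx.Graph, clusters: list[Cluster], alpha: float = 0.05
) -> list[Cluster]:
    """Fill p_value / significant in place and return the list."""
    for cl in clusters:
        cl.p_value = cluster_significance(net, cl)
        cl.significant = cl.p_value < alpha
    return clusters


def write_graphml(net: WeightedNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_edge_list(net: WeightedNetwork, path) -> None:
    import pandas as pd

    rows = [
        {"protein_a": min(u, v), "protein_b": max(u, v), "weight": d["weight"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "weight"])
    df.sort_values(["protein_a", "protein_b"]).to_csv(path, sep="\t", index=False)
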