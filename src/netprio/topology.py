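"""Topology of a candidate gene set against the background network.

The candidate subnetwork is the subgraph induced by the gene set;
density is 2E/(V(V-1)) on that subgraph, while mean pairwise distance
is measured in the background network by default (the comparison of
interest is how tightly the candidates cluster inside the full
network).  Betweenness centrality is unnormalized shortest-path
betweenness on the induced subnetwork, identifying broker genes.  A
permutation null (uniform random node sets of equal size, optionally
degree-matched) yields an empirical p for the observed mean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .network import HeterogeneousNetwork, NetworkError, NodeId, assemble_network

logger = logging.getLogger(__name__)


def _resolve(network: HeterogeneousNetwork, gene_set: Iterable["NodeId | str"]
             ) -> tuple[list[NodeId], list["NodeId | str"]]:
    """Map gene-set members (NodeIds or bare identifiers) onto the network."""
    present: list[NodeId] = []
    missing: list["NodeId | str"] = []
    seen: set[NodeId] = set()
    for member in gene_set:
        if isinstance(member, NodeId):
            hits = [member] if member in network.node_index else []
        else:
            hits = network.find(member)
        if hits:
            for h in hits:
                if h not in seen:
                    seen.add(h)
                    present.append(h)
        else:
            missing.append(member)
    return present, missing


def induced_subnetwork(
    network: HeterogeneousNetwork, gene_set: Iterable["NodeId | str"]
) -> tuple[HeterogeneousNetwork, list["NodeId | str"]]:
    """Subgraph induced by the gene set, plus the unmapped members.

    Nodes are the gene-set members found in the network; edges are the
    network edges with both endpoints in that set (layer provenance
    kept).  Members absent from the network are returned as the second
    element.  Nodes left isolated inside the induced subgraph are kept.
    """
    members = list(gene_set)
    if not members:
        raise NetworkError("gene set is empty")
    present, missing = _resolve(network, members)
    if not present:
        raise NetworkError("no gene-set member maps into the network")
    if missing:
        logger.info("%d gene-set member(s) not in the network", len(missing))
    keep = set(present)
    nodes = sorted(keep)
    index = {node: i for i, node in enumerate(nodes)}
    edges = {}
    for (i, j), layers in network.edges.items():
        u, v = network.nodes[i], network.nodes[j]
        if u in keep and v in keep:
            a, b = index[u], index[v]
            edges[(a, b) if a < b else (b, a)] = layers
    sub = HeterogeneousNetwork(nodes=nodes, edges=edges, node_index=index)
    return sub, missing


def subgraph_density(
    network: HeterogeneousNetwork, gene_set: Iterable["NodeId | str"]
) -> float:
    """Density 2E/(V(V-1)) of the induced subgraph (V >= 2 required)."""
    sub, _ = induced_subnetwork(network, gene_set)
    v = sub.m
    if v < 2:
        raise NetworkError("density needs at least 2 mapped gene-set members")
    return 2.0 * sub.edge_count / (v * (v - 1))


def mean_pairwise_distance(
    network: HeterogeneousNetwork,
    gene_set: Iterable["NodeId | str"],
    within: str = "background",
) -> tuple[float, int]:
    """Mean shortest-path length over connected pairs of the gene set.

    Distances are measured in the background network by default
    (``within="induced"`` switches to the induced subgraph).  Returns
    (mean over connected unordered pairs, number of disconnected
    pairs); the mean is NaN when every pair is disconnected.
    """
    if within not in ("background", "induced"):
        raise ValueError(f"within must be 'background' or 'induced', got {within!r}")
    present, _ = _resolve(network, list(gene_set))
    if len(present) < 2:
        raise NetworkError("mean distance needs at least 2 mapped gene-set members")
    if within == "background":
        graph = network.to_networkx()
    else:
        graph = induced_subnetwork(network, present)[0].to_networkx()
    total = 0
    connected = 0
    disconnected = 0
    for a_idx in range(len(present)):
        lengths = nx.single_source_shortest_path_length(graph, present[a_idx])
        for b_idx in range(a_idx + 1, len(present)):
            d = lengths.get(present[b_idx])
            if d is None:
                disconnected += 1
            else:
                total += d
                connected += 1
    mean = total / connected if connected else float("nan")
    if not connected:
        logger.warning("all gene-set pairs are disconnected; mean distance undefined")
    return mean, disconnected


def betweenness(
    subnetwork: HeterogeneousNetwork, normalized: bool = False
) -> dict[NodeId, float]:
    """Shortest-path betweenness of each subnetwork node.

    Unnormalized by default: for node v the sum over unordered pairs
    {s,t} (s != t != v) of sigma_st(v)/sigma_st, the fraction of
    shortest s-t paths through v.
    """
    if subnetwork.m == 0:
        raise NetworkError("subnetwork is empty")
    graph = subnetwork.to_networkx()
    return {
        node: float(val)
        for node, val in nx.betweenness_centrality(graph, normalized=normalized).items()
    }


@dataclass
class TopologySummary:
    """Joint topology report for a gene set against the background."""

    gene_set_size: int
    mapped: int
    unmapped: int
    induced_nodes: int
    induced_edges: int
    density: float
    mean_distance: float
    disconnected_pairs: int
    betweenness: dict[NodeId, float]


def summarize_topology(
    network: HeterogeneousNetwork, gene_set: Iterable["NodeId | str"]
) -> TopologySummary:
    """Compute the full topology report in one call."""
    members = list(gene_set)
    sub, missing = induced_subnetwork(network, members)
    density = (
        2.0 * sub.edge_count / (sub.m * (sub.m - 1)) if sub.m >= 2 else float("nan")
    )
    if sub.m >= 2:
        mean_dist, disc = mean_pairwise_distance(network, sub.nodes)
    else:
        mean_dist, disc = float("nan"), 0
    return TopologySummary(
        gene_set_size=len(members),
        mapped=sub.m,
        unmapped=len(missing),
        induced_nodes=sub.m,
        induced_edges=sub.edge_count,
        density=density,
        mean_distance=mean_dist,
        disconnected_pairs=disc,
        betweenness=betweenness(sub),
    )


def null_distance_comparison(
    network: HeterogeneousNetwork,
    gene_set: Iterable["NodeId | str"],
    n_perm: int = 100,
    rng_seed: int = 0,
    degree_matched: bool = False,
) -> tuple[float, list[float], float]:
    """Empirical p for the gene set's mean distance under a random null.

    Draws ``n_perm`` random node sets of the same size (uniform over
    network nodes by default; ``degree_matched=True`` samples within
    log2-degree bins), computes each null set's background mean
    distance, and returns (observed mean, null means, empirical p) with
    p = (1 + #{null <= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = list(gene_set)
    if len(members) > network.m:
        raise NetworkError("gene set larger than the network")
    present, _ = _resolve(network, members)
    size = len(present)
    if size < 2:
        raise NetworkError("need at least 2 mapped gene-set members")
    observed, _ = mean_pairwise_distance(network, present)
    rng = np.random.default_rng(rng_seed)
    degrees = network.degrees()
    if degree_matched:
        bins = np.floor(np.log2(np.maximum(degrees, 1))).astype(int)
        bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
        target_bins = [bins[network.node_index[node]] for node in present]
    null_means: list[float] = []
    for _ in range(n_perm):
        if degree_matched:
            idx = [int(rng.choice(bin_members[b])) for b in target_bins]
        else:
            idx = rng.choice(network.m, size=size, replace=False).tolist()
        sample = [network.nodes[i] for i in idx]
        mean, _ = mean_pairwise_distance(network, sample)
        null_means.append(mean)
    finite = [x for x in null_means if not np.isnan(x)]
    p = (1 + sum(x <= observed for x in finite)) / (1 + n_perm)
    return observed, null_means, float(p)
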