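"""Bipartite sample–drug network, drug-similarity projection, and clustering.

The normalized inhibition matrix A defines a weighted bipartite graph
G = (V1, V2, E, ω): V1 the samples, V2 the drugs, with ω(s_i, d_j) = a_ij.
Projecting onto the drug side gives the drug-similarity network with

    w_ij = Σ_k a_ik · a_jk      (sum over shared samples)

i.e. the off-diagonal of AᵀA — two drugs are similar when they inhibit the
same samples strongly. Edges at or below the median similarity are discarded
as weak, and Louvain modularity maximization on the filtered network yields
drug communities (clusters of drugs with similar response behavior).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .response import ResponseMatrix

__all__ = [
    "build_bipartite",
    "project_onto_drugs",
    "filter_edges_median",
    "detect_communities",
    "DrugSimilarityNetwork",
    "ClusterAssignment",
]


@dataclass
class DrugSimilarityNetwork:
    """Drug nodes with symmetric similarity weights w_ij ≥ 0.

    ``filter_threshold`` is None before median filtering; afterwards it holds
    the median edge weight used for retention (edges kept iff w > threshold).
    """

    graph: nx.Graph
    filter_threshold: float | None = None

    @property
    def drug_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def weight(self, d1: str, d2: str) -> float:
        if self.graph.has_edge(d1, d2):
            return float(self.graph[d1][d2]["weight"])
        return 0.0

    def edge_weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.graph.edges(data="weight")], dtype=float)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(u, v, w) for u, v, w in self.graph.edges(data="weight")]
        return pd.DataFrame(rows, columns=["drug1", "drug2", "weight"])


@dataclass
class ClusterAssignment:
    """Partition of the drug nodes into communities, ids contiguous from 1."""

    labels: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cid: int) -> list[str]:
        return [d for d, c in self.labels.items() if c == cid]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["drug", "cluster"]
        )


def build_bipartite(m: ResponseMatrix, drop_zero: bool = True) -> nx.Graph:
    """Build the weighted bipartite network from a complete response matrix.

    Sample nodes carry ``bipartite=0``, drug nodes ``bipartite=1``; the edge
    weight between sample i and drug j is exactly a_ij. Zero-weight edges are
    dropped by default (they cannot contribute to any projection weight).
    """
    if m.a.size == 0:
        raise ValueError("empty response matrix")
    g = nx.Graph()
    g.add_nodes_from(m.sample_ids, bipartite=0)
    g.add_nodes_from(m.drug_ids, bipartite=1)
    for i, s in enumerate(m.sample_ids):
        for j, d in enumerate(m.drug_ids):
            w = float(m.a[i, j])
            if drop_zero and w == 0.0:
                continue
            g.add_edge(s, d, weight=w)
    return g


def project_onto_drugs(g: nx.Graph) -> DrugSimilarityNetwork:
    """One-mode projection of the bipartite network onto the drug node set.

    The projected weight between drugs i and j sums the products of their
    inhibition rates over every shared sample: w_ij = Σ_k a_ik·a_jk. Pairs
    with w_ij = 0 (no shared sample) get no edge.
    """
    drugs = [n for n, b in g.nodes(data="bipartite") if b == 1]
    samples = [n for n, b in g.nodes(data="bipartite") if b == 0]
    d_index = {d: j for j, d in enumerate(drugs)}
    n_d = len(drugs)
    w = np.zeros((n_d, n_d))
    # accumulate rank-1 contributions sample by sample (graph-driven, so
    # missing zero-weight edges are handled uniformly)
    for s in samples:
        vec = np.zeros(n_d)
        for d, attrs in g[s].items():
            vec[d_index[d]] = attrs["weight"]
        w += np.outer(vec, vec)
    proj = nx.Graph()
    proj.add_nodes_from(drugs)
    for i in range(n_d):
        for j in range(i + 1, n_d):
            if w[i, j] != 0.0:
                proj.add_edge(drugs[i], drugs[j], weight=float(w[i, j]))
    return DrugSimilarityNetwork(graph=proj)


def filter_edges_median(n: DrugSimilarityNetwork) -> DrugSimilarityNetwork:
    """Keep only edges strictly above the median of all edge weights.

    The median uses the midpoint convention for even edge counts. Drugs that
    lose all their edges stay in the network as isolated nodes; the threshold
    is recorded on the returned network.
    """
    weights = n.edge_weights()
    if weights.size == 0:
        raise ValueError("network has no edges to filter")
    med = float(np.median(weights))
    filt = nx.Graph()
    filt.add_nodes_from(n.graph.nodes)
    for u, v, w in n.graph.edges(data="weight"):
        if w > med:
            filt.add_edge(u, v, weight=w)
    return DrugSimilarityNetwork(graph=filt, filter_threshold=med)


def detect_communities(
    n: DrugSimilarityNetwork, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Weighted Louvain community detection on the (filtered) drug network.

    Louvain greedily maximizes weighted modularity; it is stochastic, so the
    partition is seeded for reproducibility. Isolated drugs come out as
    singleton communities. Community ids are renumbered 1..k, largest
    community first (ties by smallest member id).
    """
    g = n.graph
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 drugs to detect communities")
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(str(x) for x in c)))
    labels = {d: cid for cid, comm in enumerate(comms, start=1) for d in comm}
    if g.number_of_edges() > 0:
        mod = float(
            nx.community.modularity(g, comms, weight="weight", resolution=resolution)
        )
    else:
        mod = 0.0
    return ClusterAssignment(labels=labels, modularity=mod)
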