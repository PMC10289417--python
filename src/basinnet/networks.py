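"""Construction and modular decomposition of basin and species networks.

Two kinds of graphs are analyzed:

* the **basin network**: undirected, weighted; nodes are basins and the
  weight of an edge is the number of species the two basins share (no edge
  when they share none);
* **nearest-neighbour species networks**: directed, unweighted; every
  species points to its ``NN`` closest species under a chosen distance
  (cosine trait distance or cophenetic phylogenetic distance). In-degree is
  unconstrained, so the graph is genuinely asymmetric.

Modules are detected by modularity optimization: Louvain for the undirected
basin network, Leiden (which handles directed modularity) for the species
networks. Both are stochastic but reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidDataError

__all__ = [
    "ModulePartition",
    "build_basin_graph",
    "build_nn_graph",
    "modularity",
    "detect_modules",
]


@dataclass(frozen=True)
class ModulePartition:
    """A node -> module assignment with its modularity score."""

    membership: dict
    q: float
    algorithm: str
    seed: int
    sizes: dict = field(init=False)

    def __post_init__(self):
        counts: dict = {}
        for m in self.membership.values():
            counts[m] = counts.get(m, 0) + 1
        object.__setattr__(self, "sizes", counts)

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    def members(self, module: int) -> list:
        return [n for n, m in self.membership.items() if m == module]


def build_basin_graph(occ: pd.DataFrame) -> nx.Graph:
    """Weighted undirected basin graph from a binary species x basin table.

    ``weight(a, b)`` is the number of species present in both basins; basin
    pairs sharing no species get no edge. Basins sharing species with no one
    remain as isolated nodes.
    """
    arr = occ.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise InvalidDataError("occurrence matrix must be binary (0/1)")
    arr = arr.astype(np.int64)
    shared = arr.T @ arr
    basins = list(occ.columns)
    g = nx.Graph()
    g.add_nodes_from(basins)
    ii, jj = np.nonzero(np.triu(shared, k=1))
    g.add_weighted_edges_from(
        (basins[i], basins[j], int(shared[i, j])) for i, j in zip(ii, jj)
    )
    return g


def build_nn_graph(d: pd.DataFrame, nn: int) -> nx.DiGraph:
    """Directed unweighted graph linking each species to its ``nn`` nearest.

    Out-edges of node *i* target the ``nn`` species with smallest distance
    ``d[i, j]`` (j != i); ties are broken by ascending species identifier.
    Every node has out-degree exactly ``nn``.
    """
    arr = d.to_numpy(dtype=float)
    n = arr.shape[0]
    if np.isnan(arr).any():
        raise InvalidDataError("distance matrix contains NaN")
    if not 1 <= nn <= n - 1:
        raise InvalidArgumentError(f"NN must be in [1, {n - 1}], got {nn}")
    species = list(d.index)
    id_rank = np.argsort(np.argsort(np.asarray(species, dtype=object)))
    g = nx.DiGraph()
    g.add_nodes_from(species)
    for i in range(n):
        row = arr[i].copy()
        row[i] = np.inf
        order = np.lexsort((id_rank, row))  # distance first, then identifier
        for j in order[:nn]:
            g.add_edge(species[i], species[int(j)])
    return g


def modularity(g: nx.Graph | nx.DiGraph, partition: Mapping[Hashable, int]) -> float:
    """Newman modularity Q of a partition.

    Undirected weighted: Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j).
    Directed: Q = (1/m) sum_ij [A_ij - k_i^out k_j^in / m] delta(c_i, c_j).
    A graph without edges has Q = 0 by convention.
    """
    if g.number_of_nodes() == 0:
        raise InvalidArgumentError("modularity of an empty graph is undefined")
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise InvalidArgumentError(f"partition misses nodes {missing[:5]}")
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    labels = np.asarray([partition[n] for n in nodes])
    delta = labels[:, None] == labels[None, :]
    if g.is_directed():
        m = a.sum()
        if m == 0:
            return 0.0
        k_out = a.sum(axis=1)
        k_in = a.sum(axis=0)
        return float(((a - np.outer(k_out, k_in) / m) * delta).sum() / m)
    two_m = a.sum()  # symmetric adjacency sums each edge twice
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    return float(((a - np.outer(k, k) / two_m) * delta).sum() / two_m)


def _contiguous(membership: dict, nodes: list) -> dict:
    relabel: dict = {}
    out = {}
    for n in nodes:
        m = membership[n]
        if m not in relabel:
            relabel[m] = len(relabel)
        out[n] = relabel[m]
    return out


def detect_modules(g: nx.Graph | nx.DiGraph, seed: int = 0) -> ModulePartition:
    """Modularity-optimizing module detection.

    Louvain (networkx) for undirected graphs, Leiden (leidenalg, directed
    modularity) for directed graphs. Module indices are contiguous from 0 in
    order of first appearance over the graph's node order; Q is recomputed
    with :func:`modularity` on the returned partition.
    """
    if g.number_of_nodes() == 0:
        raise InvalidArgumentError("cannot detect modules in an empty graph")
    nodes = list(g.nodes)
    if g.is_directed():
        index = {n: i for i, n in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in g.edges]
        igg = ig.Graph(n=len(nodes), edges=edges, directed=True)
        part = leidenalg.find_partition(
            igg, leidenalg.ModularityVertexPartition, seed=int(seed)
        )
        membership = {n: part.membership[index[n]] for n in nodes}
        algorithm = "leiden"
    else:
        communities = nx.community.louvain_communities(g, weight="weight", seed=int(seed))
        membership = {}
        for m, comm in enumerate(communities):
            for n in comm:
                membership[n] = m
        algorithm = "louvain"
    membership = _contiguous(membership, nodes)
    return ModulePartition(
        membership=membership,
        q=modularity(g, membership),
        algorithm=algorithm,
        seed=int(seed),
    )
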