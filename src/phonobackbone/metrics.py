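"""Structural metrics for phonological networks.

Whole-network summaries (node/edge counts, giant component, islands and
hermits, degree, paths, clustering) and per-word variables (degree =
neighborhood density, clustering coefficient C, closeness centrality).

Conventions for disconnected graphs: closeness is component-normalized,
(n_c - 1) / sum of distances within the word's component (0 for hermits);
clustering is 0 for nodes of degree < 2; diameter and average shortest
path length are taken over all connected ordered pairs across every
component, which in practice is dominated by the giant component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csgraph

__all__ = [
    "ComponentDecomposition",
    "NodeMetrics",
    "NetworkSummary",
    "decompose",
    "node_metrics",
    "all_node_metrics",
    "summarize",
]


@dataclass
class ComponentDecomposition:
    """Connected components ordered by size descending, then smallest word id."""

    components: list[set[str]]
    giant: set[str]
    n_isolates: int
    island_size_min: int | None
    island_size_max: int | None

    @property
    def n_components_ge2(self) -> int:
        """Number of components of size >= 2 other than the giant ("islands")."""
        return sum(1 for c in self.components if len(c) >= 2) - (1 if len(self.giant) >= 2 else 0)


def decompose(network: nx.Graph) -> ComponentDecomposition:
    comps = sorted(nx.connected_components(network), key=lambda c: (-len(c), min(c)))
    giant = comps[0] if comps else set()
    isolates = sum(1 for c in comps if len(c) == 1)
    islands = [len(c) for c in comps[1:] if len(c) >= 2] if len(giant) >= 2 else []
    return ComponentDecomposition(
        components=comps,
        giant=giant,
        n_isolates=isolates,
        island_size_min=min(islands) if islands else None,
        island_size_max=max(islands) if islands else None,
    )


@dataclass(frozen=True)
class NodeMetrics:
    degree: int
    clustering: float
    closeness: float


def node_metrics(network: nx.Graph, word_id: str) -> NodeMetrics:
    """Degree, clustering coefficient and component-normalized closeness."""
    if word_id not in network:
        raise KeyError(f"word {word_id!r} not in network")
    deg = network.degree(word_id)
    clus = nx.clustering(network, word_id) if deg >= 2 else 0.0
    # wf_improved=False gives (reachable - 1) / sum(dist): the in-component
    # normalization, 0 for isolates
    close = nx.closeness_centrality(network, u=word_id, wf_improved=False)
    return NodeMetrics(degree=deg, clustering=float(clus), closeness=float(close))


def all_node_metrics(network: nx.Graph) -> pd.DataFrame:
    """Per-word metrics table: word_id, degree, clustering, closeness, component_id, in_giant."""
    decomp = decompose(network)
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(decomp.components):
        for n in comp:
            comp_of[n] = i
    clus = nx.clustering(network)
    rows = []
    for comp in decomp.components:
        if len(comp) == 1:
            (n,) = comp
            rows.append((n, 0, 0.0, 0.0))
            continue
        nodes = sorted(comp)
        D = _component_distances(network, nodes)
        nc = len(nodes)
        closeness = (nc - 1) / D.sum(axis=1)
        for n, c in zip(nodes, closeness):
            rows.append((n, network.degree(n), float(clus[n]), float(c)))
    df = pd.DataFrame(rows, columns=["word_id", "degree", "clustering", "closeness"])
    df["component_id"] = df["word_id"].map(comp_of)
    df["in_giant"] = df["component_id"] == 0
    return df.sort_values("word_id", ignore_index=True)


@dataclass
class NetworkSummary:
    """The whole-network characteristics table (original or backbone)."""

    n_nodes: int
    n_edges: int
    gc_nodes: int
    gc_edges: int
    avg_degree: float
    avg_degree_gc: float
    diameter: int
    avg_shortest_path: float
    n_components_ge2: int
    island_size_min: int | None
    island_size_max: int | None
    n_isolates: int
    avg_clustering: float
    degenerate: bool = False  # no connected pair: path stats reported as 0

    def to_dict(self) -> dict:
        return asdict(self)


def _component_distances(network: nx.Graph, nodes: list[str]) -> np.ndarray:
    """All-pairs BFS distance matrix within one connected component."""
    A = nx.to_scipy_sparse_array(network.subgraph(nodes), nodelist=nodes, format="csr")
    return csgraph.shortest_path(A, method="D", unweighted=True)


def _path_stats(network: nx.Graph, components: list[set[str]]) -> tuple[int, float, bool]:
    """Diameter and mean shortest-path length over all connected ordered pairs."""
    diameter = 0
    total = 0.0
    pairs = 0
    for comp in components:
        if len(comp) < 2:
            continue
        D = _component_distances(network, sorted(comp))
        diameter = max(diameter, int(D.max()))
        total += D.sum()
        pairs += len(comp) * (len(comp) - 1)
    if pairs == 0:
        return 0, 0.0, True
    return diameter, total / pairs, False


def summarize(network: nx.Graph, gc_only: bool = False) -> NetworkSummary:
    """Structural summary; with ``gc_only`` path statistics are restricted to the GC."""
    decomp = decompose(network)
    n = network.number_of_nodes()
    m = network.number_of_edges()
    gc = decomp.giant
    gc_sub = network.subgraph(gc)
    gc_n, gc_m = gc_sub.number_of_nodes(), gc_sub.number_of_edges()
    comps_for_paths = [gc] if gc_only else decomp.components
    diameter, avg_path, degenerate = _path_stats(network, comps_for_paths)
    if degenerate:
        warnings.warn("no connected node pair: diameter and average path reported as 0")
    avg_clus = sum(nx.clustering(network).values()) / n if n else 0.0
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        gc_nodes=gc_n,
        gc_edges=gc_m,
        avg_degree=2 * m / n if n else 0.0,
        avg_degree_gc=2 * gc_m / gc_n if gc_n else 0.0,
        diameter=diameter,
        avg_shortest_path=avg_path,
        n_components_ge2=decomp.n_components_ge2,
        island_size_min=decomp.island_size_min,
        island_size_max=decomp.island_size_max,
        n_isolates=decomp.n_isolates,
        avg_clustering=avg_clus,
        degenerate=degenerate,
    )
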