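"""L-spar backbone extraction for unweighted networks.

The local-sparsification (L-spar) backbone scores every edge by the Jaccard
similarity of its endpoints' neighborhoods, rank-normalizes the scores per
node (the strongest incident edge of each node gets score 1), and retains,
for each node of degree d, the edges ranked in the top ceil(d**s), where the
sparsification exponent s in [0, 1] controls density: s = 0 keeps only each
node's strongest edge(s), s = 1 keeps everything.  An edge survives if
EITHER endpoint nominates it.

Ranking is competition-style: tied Jaccard scores share the best (minimum)
rank, so all edges tied at the retention boundary are kept ("keep" tie
policy, the default).  A "strict" policy breaks ties lexicographically by
the edge's word-id pair, retaining exactly ceil(d**s) edges per node; it
exists for sensitivity analysis, since strict nomination at s = 0 can keep
at most one edge per node.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "EdgeScore",
    "BackboneResult",
    "jaccard_score",
    "rank_normalize",
    "degree_filter",
    "extract_backbone",
    "backbone_graph",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _canon(u, v) -> Edge:
    return (u, v) if u <= v else (v, u)


def jaccard_score(network: nx.Graph, edge: Edge, neighborhood_mode: str = "open") -> float:
    """Jaccard similarity of the endpoint neighborhoods of an edge.

    ``open`` (default) uses the bare adjacency sets, so an edge in a
    triangle-free region scores 0; ``closed`` includes each endpoint in its
    own neighborhood, so every existing edge scores > 0 (the endpoints
    always share {u, v}).  Ranges over [0, 1]: 1 means the neighborhoods
    coincide, 0 means they are disjoint.

    Open is the default because it is what graph libraries compute as
    vertex Jaccard similarity, and because under it tree-like regions
    (all-zero scores, hence all edges tied at the top rank) pass through
    the degree filter intact — which is how backbone extraction can remove
    most edges while barely changing which nodes stay connected.
    """
    u, v = edge
    if not network.has_edge(u, v):
        raise KeyError(f"edge ({u!r}, {v!r}) not in network")
    nu, nv = set(network[u]), set(network[v])
    if neighborhood_mode == "closed":
        nu.add(u)
        nv.add(v)
    elif neighborhood_mode != "open":
        raise ValueError(f"unknown neighborhood_mode {neighborhood_mode!r}")
    inter = len(nu & nv)
    union = len(nu | nv)
    return inter / union if union else 0.0


@dataclass(frozen=True)
class EdgeScore:
    """Jaccard score of one edge plus its per-endpoint normalized ranks.

    ``rank_u``/``rank_v`` are competition ranks (1 = strongest) of the edge
    within each endpoint's incident-edge list; ``rank_score_u``/``_v`` are
    the (d - r + 1)/d normalizations, so the strongest edge(s) score 1.
    """

    edge: Edge
    jaccard: float
    rank_u: int
    rank_v: int
    rank_score_u: float
    rank_score_v: float


def _per_node_ranks(
    network: nx.Graph,
    jaccard_scores: dict[Edge, float],
    tie_policy: str = "keep",
) -> dict[str, dict[Edge, int]]:
    """Competition rank of each incident edge, per node.

    With ``keep``, ties share the best rank (1, 2, 2, 4, ...).  With
    ``strict``, ties are broken by the canonical word-id pair, yielding
    distinct ranks 1..d.
    """
    if tie_policy not in ("keep", "strict"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    ranks: dict[str, dict[Edge, int]] = {}
    for node in network.nodes:
        incident = [_canon(node, nbr) for nbr in network[node]]
        if not incident:
            ranks[node] = {}
            continue
        incident.sort(key=lambda e: (-jaccard_scores[e], e))
        node_ranks: dict[Edge, int] = {}
        for pos, e in enumerate(incident):
            if tie_policy == "strict":
                node_ranks[e] = pos + 1
            else:
                prev = incident[pos - 1] if pos else None
                if prev is not None and jaccard_scores[prev] == jaccard_scores[e]:
                    node_ranks[e] = node_ranks[prev]
                else:
                    node_ranks[e] = pos + 1
        ranks[node] = node_ranks
    return ranks


def rank_normalize(
    network: nx.Graph,
    jaccard_scores: dict[Edge, float],
    tie_policy: str = "keep",
) -> dict[Edge, EdgeScore]:
    """Attach per-endpoint ranks and normalized rank scores to every edge."""
    missing = [e for e in (_canon(*e) for e in network.edges) if e not in jaccard_scores]
    if missing:
        raise KeyError(f"{len(missing)} edges lack a Jaccard score, e.g. {missing[0]}")
    ranks = _per_node_ranks(network, jaccard_scores, tie_policy)
    out: dict[Edge, EdgeScore] = {}
    for u, v in network.edges:
        e = _canon(u, v)
        a, b = e
        ra, rb = ranks[a][e], ranks[b][e]
        da, db = network.degree(a), network.degree(b)
        out[e] = EdgeScore(
            edge=e,
            jaccard=jaccard_scores[e],
            rank_u=ra,
            rank_v=rb,
            rank_score_u=(da - ra + 1) / da,
            rank_score_v=(db - rb + 1) / db,
        )
    return out


def degree_filter(network: nx.Graph, scores: dict[Edge, EdgeScore], s: float) -> set[Edge]:
    """Retain each node's top ceil(d**s) incident edges (either-endpoint rule).

    An edge is kept iff, for at least one endpoint of degree d, its rank
    there is <= ceil(d**s).  Under the keep-ties ranking, edges tied at the
    boundary rank are all retained.
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"sparsification exponent s={s} outside [0, 1]")
    retained: set[Edge] = set()
    for e, sc in scores.items():
        a, b = e
        ka = math.ceil(network.degree(a) ** s)
        kb = math.ceil(network.degree(b) ** s)
        if sc.rank_u <= ka or sc.rank_v <= kb:
            retained.add(e)
    return retained


@dataclass
class BackboneResult:
    """Retained edge subset plus the parameters that produced it."""

    retained_edges: set[Edge]
    s: float
    escore: str = "jaccard"
    normalize: str = "rank"
    filter: str = "degree"
    umst: bool = False
    neighborhood_mode: str = "closed"
    tie_policy: str = "keep"
    n_original_edges: int = 0
    n_nodes: int = 0
    scores: dict[Edge, EdgeScore] = field(default_factory=dict, repr=False)

    @property
    def removed_fraction(self) -> float:
        """Fraction of original edges removed; 0 for an edgeless input."""
        if self.n_original_edges == 0:
            return 0.0
        return 1.0 - len(self.retained_edges) / self.n_original_edges

    def params_dict(self) -> dict:
        return {
            "escore": self.escore,
            "normalize": self.normalize,
            "filter": self.filter,
            "s": self.s,
            "umst": self.umst,
            "neighborhood_mode": self.neighborhood_mode,
            "tie_policy": self.tie_policy,
            "n_nodes": self.n_nodes,
            "n_original_edges": self.n_original_edges,
            "n_retained_edges": len(self.retained_edges),
            "removed_fraction": self.removed_fraction,
        }


def extract_backbone(
    network: nx.Graph,
    s: float = 0.0,
    neighborhood_mode: str = "open",
    tie_policy: str = "keep",
    umst: bool = False,
) -> BackboneResult:
    """Run the full L-spar pipeline: Jaccard score, rank-normalize, degree-filter.

    With ``umst=True`` the edges of a maximum spanning forest (Jaccard
    weights) are united into the retained set, guaranteeing the backbone
    connects whatever the original connected.  Default False.
    """
    jac = {
        _canon(u, v): jaccard_score(network, (u, v), neighborhood_mode)
        for u, v in network.edges
    }
    if network.number_of_edges() == 0:
        warnings.warn("backbone of an edgeless network is empty; removed_fraction reported as 0")
        return BackboneResult(
            retained_edges=set(),
            s=s,
            umst=umst,
            neighborhood_mode=neighborhood_mode,
            tie_policy=tie_policy,
            n_original_edges=0,
            n_nodes=network.number_of_nodes(),
        )
    scores = rank_normalize(network, jac, tie_policy)
    retained = degree_filter(network, scores, s)
    if umst:
        W = nx.Graph()
        W.add_nodes_from(network)
        W.add_weighted_edges_from((u, v, jac[_canon(u, v)]) for u, v in network.edges)
        msf = nx.maximum_spanning_edges(W, data=False)
        retained |= {_canon(u, v) for u, v in msf}
    result = BackboneResult(
        retained_edges=retained,
        s=s,
        umst=umst,
        neighborhood_mode=neighborhood_mode,
        tie_policy=tie_policy,
        n_original_edges=network.number_of_edges(),
        n_nodes=network.number_of_nodes(),
        scores=scores,
    )
    logger.info(
        "backbone s=%g: retained %d / %d edges (%.1f%% removed)",
        s,
        len(retained),
        result.n_original_edges,
        100 * result.removed_fraction,
    )
    return result


def backbone_graph(network: nx.Graph, result: BackboneResult) -> nx.Graph:
    """The backbone as a graph over ALL original nodes (isolates included)."""
    B = nx.Graph()
    B.add_nodes_from(network.nodes)
    B.add_edges_from(result.retained_edges)
    return B
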