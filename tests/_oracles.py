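"""Independent reference implementations used only as test oracles.

Everything here is written from first principles (brute force, textbook
formulas, full dynamic programming) and deliberately shares no code with
the package, so agreement between the two is evidence, not tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np


def levenshtein(a, b) -> int:
    """Full DP edit distance over phoneme tokens."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[lb]


def lspar_bruteforce(G: nx.Graph, s: float, mode: str = "open", ties: str = "keep") -> set:
    """Direct transcription of the local-sparsification rule.

    For every node: score each incident edge by neighborhood Jaccard, sort
    descending, keep the top ceil(d**s) ranks (ties either share a rank or
    are broken by the sorted edge pair).  An edge survives if any endpoint
    keeps it.
    """
    def jac(u, v):
        nu, nv = set(G[u]), set(G[v])
        if mode == "closed":
            nu = nu | {u}
            nv = nv | {v}
        union = nu | nv
        return len(nu & nv) / len(union) if union else 0.0

    retained = set()
    for node in G.nodes:
        inc = sorted(
            (tuple(sorted((node, nbr))) for nbr in G[node]),
            key=lambda e: (-jac(*e), e),
        )
        if not inc:
            continue
        k = math.ceil(G.degree(node) ** s)
        if ties == "strict":
            keep = inc[:k]
        else:
            # competition ranks: position of the first edge with this score
            scores = [jac(*e) for e in inc]
            ranks = []
            for i, sc in enumerate(scores):
                ranks.append(ranks[i - 1] if i and scores[i - 1] == sc else i + 1)
            keep = [e for e, r in zip(inc, ranks) if r <= k]
        retained.update(keep)
    return retained


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_unionfind(G: nx.Graph) -> set[frozenset]:
    uf = UnionFind(G.nodes)
    for u, v in G.edges:
        uf.union(u, v)
    groups: dict = {}
    for n in G.nodes:
        groups.setdefault(uf.find(n), set()).add(n)
    return {frozenset(c) for c in groups.values()}


def welch_anova_textbook(groups) -> tuple[float, float, float]:
    """Welch's heteroscedastic one-way ANOVA, written out longhand.

    Returns (F, df2, p).  Kept scalar and loop-based on purpose, as an
    independent route from any vectorized implementation.
    """
    from scipy.stats import f as fdist

    k = len(groups)
    n = [len(g) for g in groups]
    mean = [sum(g) / len(g) for g in groups]
    var = [sum((x - m) ** 2 for x in g) / (len(g) - 1) for g, m in zip(groups, mean)]
    w = [n_j / v_j for n_j, v_j in zip(n, var)]
    sum_w = sum(w)
    grand = sum(w_j * m_j for w_j, m_j in zip(w, mean)) / sum_w
    between = sum(w_j * (m_j - grand) ** 2 for w_j, m_j in zip(w, mean)) / (k - 1)
    lam = sum((1 - w_j / sum_w) ** 2 / (n_j - 1) for w_j, n_j in zip(w, n))
    F = between / (1 + 2 * (k - 2) * lam / (k**2 - 1))
    df2 = (k**2 - 1) / (3 * lam)
    return F, df2, float(fdist.sf(F, k - 1, df2))


def modularity_bruteforce(G: nx.Graph, labels: dict) -> float:
    """Q from the ordered-pair definition:
    (1/2m) * sum over ordered (i, j), same community, of A_ij - k_i k_j / 2m.
    """
    m = G.number_of_edges()
    nodes = list(G.nodes)
    q = 0.0
    for u in nodes:
        for v in nodes:
            if labels[u] != labels[v]:
                continue
            a = 1.0 if G.has_edge(u, v) else 0.0
            q += a - G.degree(u) * G.degree(v) / (2.0 * m)
    return q / (2.0 * m)


def set_partitions(items):
    """All partitions of a small collection (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_bruteforce(G: nx.Graph):
    """Maximum-modularity partition by exhaustive enumeration (tiny graphs)."""
    best_q, best = -math.inf, None
    for part in set_partitions(G.nodes):
        labels = {n: i for i, block in enumerate(part) for n in block}
        q = modularity_bruteforce(G, labels)
        if q > best_q:
            best_q, best = q, part
    return best_q, best
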