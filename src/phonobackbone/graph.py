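"""Phonological similarity network construction.

Nodes are word ids; an undirected edge joins two words whose phoneme
sequences differ by exactly one phoneme addition, deletion, or
substitution.  A word's degree is its phonological neighborhood density.

Construction uses a deletion-variant index: every word is keyed by its own
phoneme sequence and by each sequence obtainable by deleting one phoneme.
Any pair at edit distance 1 shares a key (substitution pairs share a
deletion variant; insertion/deletion pairs share the shorter word's full
sequence), so candidate pairs come from shared buckets and are then
verified with :func:`edit1_related`.  The index is a speed device only —
the result is extensionally identical to all-pairs comparison.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .lexicon import Lexicon, LexiconError

__all__ = ["edit1_related", "build_network", "neighbors", "find_homophones"]

logger = logging.getLogger(__name__)


def edit1_related(a: Sequence[str], b: Sequence[str]) -> bool:
    """True iff two phoneme sequences are at phonological edit distance 1.

    Distance 1 means exactly one substitution (equal lengths) or one
    insertion/deletion (lengths differing by 1).  Transpositions do not
    count; identical sequences are distance 0, hence not related.
    """
    if len(a) == 0 or len(b) == 0:
        raise LexiconError("phoneme sequences must be non-empty")
    la, lb = len(a), len(b)
    if la == lb:
        # exactly one position differs
        diff = 0
        for x, y in zip(a, b):
            if x != y:
                diff += 1
                if diff > 1:
                    return False
        return diff == 1
    if abs(la - lb) != 1:
        return False
    longer, shorter = (a, b) if la > lb else (b, a)
    # the shorter must equal the longer minus one phoneme: scan to first
    # mismatch, skip one token of the longer, require the rest to match
    i = 0
    while i < len(shorter) and longer[i] == shorter[i]:
        i += 1
    return tuple(longer[i + 1 :]) == tuple(shorter[i:])


def _deletion_keys(phonemes: tuple[str, ...]) -> Iterable[tuple[str, ...]]:
    # the empty variant of a length-1 word is a real key: it buckets all
    # single-phoneme words together (they are mutual substitution neighbors)
    yield phonemes
    for i in range(len(phonemes)):
        yield phonemes[:i] + phonemes[i + 1 :]


def find_homophones(lexicon: Lexicon) -> list[list[str]]:
    """Groups of distinct words sharing an identical transcription."""
    by_trans: dict[tuple[str, ...], list[str]] = defaultdict(list)
    for e in lexicon:
        by_trans[e.phonemes].append(e.word_id)
    return [ids for ids in by_trans.values() if len(ids) > 1]


def build_network(lexicon: Lexicon, merge_homophones: bool = False) -> nx.Graph:
    """Build the edit-distance-1 network over a lexicon.

    Homophones (distinct words with identical transcriptions) stay distinct
    nodes with identical neighborhoods — and are not adjacent to each other,
    since their mutual distance is 0.  With ``merge_homophones`` each
    homophone group collapses onto its lexicographically first word id.

    Deterministic: the edge set depends only on the lexicon content.
    """
    if len(lexicon) == 0:
        raise LexiconError("cannot build a network from an empty lexicon")
    entries = list(lexicon)
    homophones = find_homophones(lexicon)
    if homophones:
        logger.info(
            "lexicon contains %d homophone groups (kept as distinct nodes: %s)",
            len(homophones),
            not merge_homophones,
        )
        if merge_homophones:
            drop: set[str] = set()
            for group in homophones:
                drop.update(sorted(group)[1:])
            entries = [e for e in entries if e.word_id not in drop]

    G = nx.Graph()
    phon = {e.word_id: e.phonemes for e in entries}
    G.add_nodes_from(phon)

    buckets: dict[tuple[str, ...], list[str]] = defaultdict(list)
    for e in entries:
        for key in _deletion_keys(e.phonemes):
            buckets[key].append(e.word_id)

    seen: set[tuple[str, str]] = set()
    for ids in buckets.values():
        if len(ids) < 2:
            continue
        for u, v in combinations(ids, 2):
            pair = (u, v) if u < v else (v, u)
            if pair in seen:
                continue
            seen.add(pair)
            if edit1_related(phon[u], phon[v]):
                G.add_edge(*pair)
    return G


def build_network_bruteforce(lexicon: Lexicon) -> nx.Graph:
    """Reference all-pairs O(n^2) construction (definitionally correct)."""
    if len(lexicon) == 0:
        raise LexiconError("cannot build a network from an empty lexicon")
    G = nx.Graph()
    entries = list(lexicon)
    G.add_nodes_from(e.word_id for e in entries)
    for a, b in combinations(entries, 2):
        if edit1_related(a.phonemes, b.phonemes):
            G.add_edge(a.word_id, b.word_id)
    return G


def neighbors(network: nx.Graph, word_id: str) -> set[str]:
    """The phonological neighborhood of a word (its adjacency set)."""
    if word_id not in network:
        raise KeyError(f"word {word_id!r} not in network")
    return set(network[word_id])
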