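"""Synthetic lexicons and norms for end-to-end pipeline testing.

Real phonological lexicons produce a characteristic morphology when
connected by one-phoneme edits: a giant component holding a large minority
of the words, many small "islands", and many unconnected "hermits".
Uniform-random phoneme strings over a modest inventory with an
English-like length distribution (most words 3-5 phonemes) reproduce that
morphology, which is all the pipeline's structural analysis needs; no
phonotactics are modeled.  The default inventory of 15 symbols was
calibrated (pilot runs over inventory sizes) so that the giant component
has a dense short-word core with a sparse long-word periphery — the regime
in which local sparsification strips periphery rather than shattering the
core, as observed in real lexicons.

Norms are explicit generative stand-ins.  Log frequency is Gaussian,
optionally coupled to a word's network degree (``degree_coupled``), which
induces the frequency-density correlation that makes backbone survival
frequency-sensitive.  Familiarity is a bounded logistic transform of
standardized log frequency into the 1-7 rating scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .lexicon import Lexicon, LexiconEntry

__all__ = ["SyntheticLexiconConfig", "generate_lexicon", "generate_norms", "fixture_community"]


def _default_length_probs() -> dict[int, float]:
    # discretized Normal(4.06, 0.93) over lengths 2..8 (English-like: mode 4)
    lengths = np.arange(2, 9)
    dens = np.exp(-0.5 * ((lengths - 4.06) / 0.93) ** 2)
    dens /= dens.sum()
    return {int(l): float(p) for l, p in zip(lengths, dens)}


@dataclass
class SyntheticLexiconConfig:
    """Parameters of the synthetic lexicon and its norms.

    ``freq_beta`` is the coupling slope of mean log frequency on
    standardized degree (0 = independent); ``freq_sigma`` the residual SD.
    ``freq_mu`` centres log10 frequency-per-million near real lexicon norms.
    """

    n_words: int = 5000
    inventory_size: int = 15
    length_probs: dict[int, float] = field(default_factory=_default_length_probs)
    seed: int = 0
    freq_model: str = "degree_coupled"  # or "independent"
    freq_mu: float = 0.8
    freq_beta: float = 0.5
    freq_sigma: float = 0.3
    familiarity_slope: float = 1.5
    familiarity_noise: float = 0.5

    def __post_init__(self) -> None:
        if self.inventory_size < 2:
            raise ValueError("inventory_size must be >= 2")
        total = sum(self.length_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length probabilities sum to {total}, not 1")
        if self.freq_model not in ("independent", "degree_coupled"):
            raise ValueError(f"unknown freq_model {self.freq_model!r}")
        max_len = max(self.length_probs)
        if self.n_words > self.inventory_size**max_len:
            raise ValueError(
                f"cannot draw {self.n_words} unique words of length <= {max_len} "
                f"from a {self.inventory_size}-symbol inventory"
            )


def _inventory(size: int) -> list[str]:
    base = "abcdefghijklmnopqrstuvwxyz"
    if size <= len(base):
        return list(base[:size])
    return list(base) + [f"x{i}" for i in range(size - len(base))]


def generate_lexicon(config: SyntheticLexiconConfig) -> Lexicon:
    """Draw unique random phoneme strings: a length, then uniform symbols.

    Deterministic for a fixed config and seed.  Duplicate draws are
    rejected and redrawn; generation fails if uniqueness proves infeasible.
    """
    rng = np.random.default_rng(config.seed)
    symbols = _inventory(config.inventory_size)
    lengths = sorted(config.length_probs)
    probs = np.array([config.length_probs[l] for l in lengths])
    seen: set[tuple[str, ...]] = set()
    entries: list[LexiconEntry] = []
    attempts = 0
    max_attempts = 50 * config.n_words
    while len(entries) < config.n_words:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not draw {config.n_words} unique words after {max_attempts} attempts; "
                "enlarge the inventory or the length support"
            )
        L = int(rng.choice(lengths, p=probs))
        word = tuple(symbols[i] for i in rng.integers(0, len(symbols), size=L))
        if word in seen:
            continue
        seen.add(word)
        entries.append(LexiconEntry(word_id=f"w{len(entries):05d}", phonemes=word))
    return Lexicon(entries=entries, dialect="tokens")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_norms(
    lexicon: Lexicon, network: nx.Graph, config: SyntheticLexiconConfig
) -> Lexicon:
    """Fill familiarity and frequency norms, optionally coupled to degree.

    log_frequency ~ Normal(mu + beta * z(degree), sigma), truncated at 0;
    familiarity = 1 + 6 * logistic(slope * z(log_frequency) + noise),
    which lies in (1, 7) by construction.  Raw frequency per million is
    back-transformed as 10**logf - 1 (consistent with the add-one log
    policy of the lexicon reader).
    """
    if set(network.nodes) != {e.word_id for e in lexicon}:
        raise ValueError("network nodes do not match the lexicon")
    rng = np.random.default_rng(config.seed + 1)
    degrees = np.array([network.degree(e.word_id) for e in lexicon], dtype=float)
    beta = config.freq_beta if config.freq_model == "degree_coupled" else 0.0
    logf = config.freq_mu + beta * _zscore(degrees) + rng.normal(0, config.freq_sigma, len(lexicon))
    logf = np.clip(logf, 0.0, None)
    fam_lin = config.familiarity_slope * _zscore(logf) + rng.normal(
        0, config.familiarity_noise, len(lexicon)
    )
    familiarity = 1.0 + 6.0 / (1.0 + np.exp(-fam_lin))
    familiarity = np.clip(familiarity, 1.0, 7.0)
    entries = [
        replace(
            e,
            familiarity=float(f),
            frequency_per_million=float(10**lf - 1.0),
            log_frequency=float(lf),
        )
        for e, lf, f in zip(lexicon, logf, familiarity)
    ]
    return lexicon.with_entries(entries)


def fixture_community() -> Lexicon:
    """The five-word /-Et/ toy community plus three hermits.

    bet, debt, pet, wet, set differ pairwise by one initial-consonant
    substitution, so they form a complete K5; the three long hermit words
    are pairwise far from everything and stay isolated.
    """
    rows = [
        ("bet", ("b", "E", "t")),
        ("debt", ("d", "E", "t")),
        ("pet", ("p", "E", "t")),
        ("wet", ("w", "E", "t")),
        ("set", ("s", "E", "t")),
        ("obtuse", ("a", "b", "t", "u", "s")),
        ("spinach", ("s", "p", "I", "n", "I", "C")),
        ("rhythm", ("r", "I", "D", "m", "z", "q")),
    ]
    return Lexicon(
        entries=[LexiconEntry(word_id=w, phonemes=p, orthography=w) for w, p in rows],
        dialect="tokens",
    )
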