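"""Lexicon tables and graph-format I/O.

A lexicon is a table of word forms: a unique identifier, a phonemic
transcription, and optional psycholinguistic norms (familiarity on a 1-7
scale, raw frequency per million tokens).  Transcriptions come in two
dialects: ``symbols`` (one character per phoneme, Klattese-style) and
``tokens`` (whitespace-separated multi-character phoneme symbols).  The
dialect is explicit configuration and never guessed from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "read_lexicon",
    "write_lexicon",
    "read_network",
    "write_network",
    "NETWORK_FORMATS",
]

DIALECTS = ("symbols", "tokens")
NETWORK_FORMATS = ("edgelist", "graphml", "gexf")

#: default column names; overridable via ``column_map``
DEFAULT_COLUMNS = {
    "word_id": "word_id",
    "transcription": "transcription",
    "orthography": "orthography",
    "familiarity": "familiarity",
    "frequency": "frequency_per_million",
}


class LexiconError(ValueError):
    """Raised for malformed lexicon files or invalid entries."""


@dataclass(frozen=True)
class LexiconEntry:
    """One word form.

    ``phonemes`` is the parsed transcription, one token per phoneme;
    multi-character symbols are atomic.  ``log_frequency`` is log10 of
    frequency per the configured zero-frequency policy, or ``None`` when
    frequency is missing (or zero under the ``exclude`` policy).
    """

    word_id: str
    phonemes: tuple[str, ...]
    orthography: str | None = None
    familiarity: float | None = None
    frequency_per_million: float | None = None
    log_frequency: float | None = None

    def __post_init__(self) -> None:
        if len(self.phonemes) < 1:
            raise LexiconError(f"empty transcription for word {self.word_id!r}")
        if self.familiarity is not None and not (1.0 <= self.familiarity <= 7.0):
            raise LexiconError(
                f"familiarity {self.familiarity} outside [1, 7] for word {self.word_id!r}"
            )
        if self.frequency_per_million is not None and self.frequency_per_million < 0:
            raise LexiconError(
                f"negative frequency for word {self.word_id!r}"
            )

    @property
    def length(self) -> int:
        """Number of phonemes."""
        return len(self.phonemes)


@dataclass
class Lexicon:
    """An ordered collection of :class:`LexiconEntry` with unique ids."""

    entries: list[LexiconEntry] = field(default_factory=list)
    dialect: str = "tokens"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise LexiconError(f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}")
        self._by_id: dict[str, LexiconEntry] = {}
        for e in self.entries:
            if e.word_id in self._by_id:
                raise LexiconError(f"duplicate word_id {e.word_id!r}")
            self._by_id[e.word_id] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def __contains__(self, word_id: str) -> bool:
        return word_id in self._by_id

    def __getitem__(self, word_id: str) -> LexiconEntry:
        return self._by_id[word_id]

    @property
    def word_ids(self) -> list[str]:
        return [e.word_id for e in self.entries]

    def with_entries(self, entries: Iterable[LexiconEntry]) -> "Lexicon":
        return Lexicon(entries=list(entries), dialect=self.dialect)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per entry), transcription in the lexicon's dialect."""
        sep = "" if self.dialect == "symbols" else " "
        return pd.DataFrame(
            {
                "word_id": [e.word_id for e in self.entries],
                "orthography": [e.orthography for e in self.entries],
                "transcription": [sep.join(e.phonemes) for e in self.entries],
                "length": [e.length for e in self.entries],
                "familiarity": [e.familiarity for e in self.entries],
                "frequency_per_million": [e.frequency_per_million for e in self.entries],
                "log_frequency": [e.log_frequency for e in self.entries],
            }
        )


def parse_transcription(text: str, dialect: str) -> tuple[str, ...]:
    """Split a transcription string into phoneme tokens per the dialect."""
    text = text.strip()
    if not text:
        raise LexiconError("empty transcription")
    if dialect == "symbols":
        return tuple(text)
    if dialect == "tokens":
        return tuple(text.split())
    raise LexiconError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def apply_log_frequency(freq: float | None, policy: str = "add_one") -> float | None:
    """log10 transform of raw frequency under a zero-frequency policy.

    ``add_one``: log10(freq + 1) (default; zero maps to 0).
    ``exclude``: zero or missing frequency yields missing log-frequency.
    """
    if freq is None:
        return None
    if policy == "add_one":
        return math.log10(freq + 1.0)
    if policy == "exclude":
        return math.log10(freq) if freq > 0 else None
    raise LexiconError(f"unknown zero-frequency policy {policy!r}")


def _coerce_optional_float(value, what: str, word_id: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise LexiconError(f"unparseable {what} {value!r} for word {word_id!r}") from None


def read_lexicon(
    path: str | Path,
    dialect: str = "tokens",
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    zero_frequency_policy: str = "add_one",
) -> Lexicon:
    """Read a delimited lexicon table.

    Parameters
    ----------
    path
        UTF-8 delimited text with a header row.  TSV by default; pass
        ``sep=","`` for CSV (``.csv`` extension also selects comma).
    dialect
        ``"symbols"`` or ``"tokens"`` — how to split transcriptions.
    column_map
        Overrides for the logical column names ``word_id``,
        ``transcription``, ``orthography``, ``familiarity``, ``frequency``.
    zero_frequency_policy
        How zero counts enter the log10 transform (``add_one`` or
        ``exclude``).
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={cols["word_id"]: str}, keep_default_na=True)
    for logical in ("word_id", "transcription"):
        if cols[logical] not in df.columns:
            raise LexiconError(
                f"required column {cols[logical]!r} (for {logical}) missing from {path.name}; "
                f"found {list(df.columns)}"
            )
    entries: list[LexiconEntry] = []
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        word_id = str(rec[cols["word_id"]])
        raw_trans = rec[cols["transcription"]]
        if raw_trans is None or (isinstance(raw_trans, float) and math.isnan(raw_trans)) or not str(raw_trans).strip():
            raise LexiconError(f"empty transcription for word {word_id!r}")
        phonemes = parse_transcription(str(raw_trans), dialect)
        orth = rec.get(cols["orthography"])
        if orth is not None and isinstance(orth, float) and math.isnan(orth):
            orth = None
        fam = _coerce_optional_float(rec.get(cols["familiarity"]), "familiarity", word_id)
        freq = _coerce_optional_float(rec.get(cols["frequency"]), "frequency", word_id)
        entries.append(
            LexiconEntry(
                word_id=word_id,
                phonemes=phonemes,
                orthography=None if orth is None else str(orth),
                familiarity=fam,
                frequency_per_million=freq,
                log_frequency=apply_log_frequency(freq, zero_frequency_policy),
            )
        )
    return Lexicon(entries=entries, dialect=dialect)


def write_lexicon(lexicon: Lexicon, path: str | Path, sep: str | None = None) -> None:
    """Write a lexicon table (TSV default, CSV for ``.csv`` paths)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = lexicon.to_frame().drop(columns=["length", "log_frequency"])
    df.to_csv(path, sep=sep, index=False)


def write_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Export a network; node and edge sets are preserved exactly.

    ``edgelist`` writes one line per edge (two tab-separated word ids) and
    one line per isolate (a single id), so isolated nodes survive the round
    trip.  ``graphml`` and ``gexf`` delegate to networkx writers.
    """
    path = Path(path)
    if format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in network.edges()):
                fh.write(f"{u}\t{v}\n")
            for n in sorted(nx.isolates(network)):
                fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml(network, path)
    elif format == "gexf":
        nx.write_gexf(network, path)
    else:
        raise LexiconError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "edgelist":
        G = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 2:
                    G.add_edge(parts[0], parts[1])
                elif len(parts) == 1 and parts[0]:
                    G.add_node(parts[0])
        return G
    if format == "graphml":
        return nx.Graph(nx.read_graphml(path))
    if format == "gexf":
        return nx.Graph(nx.read_gexf(path))
    raise LexiconError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
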