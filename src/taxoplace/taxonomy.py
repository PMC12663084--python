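"""Rank-structured taxonomies with explicit multi-label ambiguity.

Lineages are indexed over seven fixed ranks (coarse to fine):
Domain/Kingdom, Phylum, Class, Order, Family, Genus, Species. Each rank
carries a *set* of taxon names; an empty set means "unclassified at this
rank". Multi-label sets arise when a sequence region cannot distinguish
taxa, and are rendered canonically as sorted names joined by ";"
(e.g. ``Denitratisoma;Sulfuritalea``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

RANKS: tuple[str, ...] = (
    "Domain", "Phylum", "Class", "Order", "Family", "Genus", "Species",
)
N_RANKS = len(RANKS)
SPECIES = N_RANKS - 1

#: Tokens treated as "missing/unclassified" designations (case-insensitive).
#: Matched against the whole token and against its first word, so that
#: e.g. "uncultured bacterium" is also recognised. Overridable per call.
DEFAULT_MISSING_VOCAB: frozenset[str] = frozenset(
    {"unclassified", "uncultured", "metagenome", "unidentified", ""}
)

#: Sentinel used when rendering an empty label set.
UNASSIGNED = "unassigned"

_GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

EMPTY = frozenset()


class TaxonomyParseError(ValueError):
    """Raised for malformed lineage strings."""


def rank_index(rank: int | str) -> int:
    """Resolve a rank given by name or index to its integer index."""
    if isinstance(rank, int):
        if not 0 <= rank < N_RANKS:
            raise ValueError(f"rank index out of range: {rank}")
        return rank
    try:
        return RANKS.index(rank.capitalize() if rank.islower() else rank)
    except ValueError:
        raise ValueError(f"unknown rank name: {rank!r}") from None


@dataclass(frozen=True)
class Lineage:
    """Per-rank label sets for one sequence (or one tree node).

    ``labels[i]`` is the (possibly empty, possibly multi-member) set of
    taxon names at rank ``RANKS[i]``. Holes are allowed: a rank may be
    empty while finer ranks are not, mirroring databases with missing
    mid-rank annotations.
    """

    labels: tuple[frozenset[str], ...]

    def __post_init__(self):
        if len(self.labels) != N_RANKS:
            raise ValueError(f"lineage must have {N_RANKS} ranks")

    @classmethod
    def from_names(cls, names: Iterable[str | None]) -> "Lineage":
        """Build a single-label lineage from one name (or None) per rank."""
        names = list(names)
        names += [None] * (N_RANKS - len(names))
        return cls(tuple(
            frozenset() if n is None or n == "" else frozenset([n])
            for n in names[:N_RANKS]
        ))

    def at(self, rank: int | str) -> frozenset[str]:
        return self.labels[rank_index(rank)]

    @property
    def finest_rank(self) -> int | None:
        """Index of the finest non-empty rank, or None if fully empty."""
        for r in range(N_RANKS - 1, -1, -1):
            if self.labels[r]:
                return r
        return None


def collapse_species(token: str) -> str:
    """Collapse strain/subspecies suffixes: keep the first two
    whitespace-separated words (the binomial); shorter tokens verbatim.

    "Bacillus cereus ATCC 14579" -> "Bacillus cereus". Note this rule
    will also truncate unusual multi-word names such as "Candidatus X y";
    see the package methods note.
    """
    words = token.split()
    return " ".join(words[:2]) if len(words) > 2 else token


def _is_missing(token: str, vocab: frozenset[str]) -> bool:
    low = token.strip().lower()
    if low in vocab:
        return True
    first = low.split()[0] if low.split() else ""
    return first in vocab


def parse_taxonomy_string(
    raw: str,
    dialect: str = "silva",
    missing_vocab: frozenset[str] = DEFAULT_MISSING_VOCAB,
) -> Lineage:
    """Parse a semicolon-delimited lineage into a :class:`Lineage`.

    ``dialect="silva"`` takes tokens verbatim; ``dialect="gtdb"``
    requires and strips ``d__ p__ c__ o__ f__ g__ s__`` rank prefixes.
    Subspecies/strain information is grouped to the species level and
    tokens matching the missing vocabulary become empty sets. Tokens
    beyond the seven canonical ranks (sub-ranks) are dropped.
    """
    if not raw or not raw.strip():
        raise TaxonomyParseError("empty lineage string")
    if dialect not in ("silva", "gtdb"):
        raise TaxonomyParseError(f"unknown taxonomy dialect: {dialect!r}")
    tokens = [t.strip() for t in raw.strip().split(";")]
    # mothur-style lineages end with ';' producing a trailing empty token
    if tokens and tokens[-1] == "":
        tokens.pop()
    if dialect == "gtdb":
        cleaned = []
        for i, tok in enumerate(tokens):
            if tok == "":
                cleaned.append(tok)
                continue
            if len(tok) < 3 or tok[1:3] != "__" or tok[0] not in "dpcofgs":
                raise TaxonomyParseError(
                    f"malformed GTDB rank prefix in token {tok!r}"
                )
            cleaned.append(tok[3:])
        tokens = cleaned
    tokens = tokens[:N_RANKS]

    sets: list[frozenset[str]] = []
    for i, tok in enumerate(tokens):
        if _is_missing(tok, missing_vocab):
            sets.append(EMPTY)
            continue
        if i == SPECIES:
            tok = collapse_species(tok)
        sets.append(frozenset([tok]))
    sets += [EMPTY] * (N_RANKS - len(sets))
    return Lineage(tuple(sets))


def render_labels(
    lineage: Lineage | frozenset[str],
    rank: int | str | None = None,
    sentinel: str = UNASSIGNED,
) -> str:
    """Render a label set as a canonical sorted ';'-joined string.

    Accepts either a :class:`Lineage` plus a rank, or a bare label set.
    An empty set renders as *sentinel*.
    """
    if isinstance(lineage, Lineage):
        if rank is None:
            raise ValueError("rank required when rendering a Lineage")
        labels = lineage.at(rank)
    else:
        labels = lineage
    return ";".join(sorted(labels)) if labels else sentinel


@dataclass
class TaxonomyTable:
    """Map of sequence ID -> :class:`Lineage`."""

    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __getitem__(self, seq_id: str) -> Lineage:
        return self.lineages[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def __iter__(self):
        return iter(self.lineages)

    def items(self):
        return self.lineages.items()

    def subset(self, ids: Iterable[str]) -> "TaxonomyTable":
        return TaxonomyTable({i: self.lineages[i] for i in ids})

    def labels_at(self, rank: int | str) -> set[str]:
        """Union of all labels present at a rank."""
        r = rank_index(rank)
        out: set[str] = set()
        for lin in self.lineages.values():
            out |= lin.labels[r]
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Lineage]) -> "TaxonomyTable":
        return cls(dict(mapping))


def read_taxonomy_tsv(
    path,
    dialect: str = "silva",
    missing_vocab: frozenset[str] = DEFAULT_MISSING_VOCAB,
) -> TaxonomyTable:
    """Read a mothur-compatible two-column TSV (ID, lineage)."""
    table: dict[str, Lineage] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise TaxonomyParseError(f"expected 2 columns, got {row!r}")
            seq_id, raw = row[0].strip(), row[1]
            if seq_id in table:
                raise TaxonomyParseError(f"duplicate sequence ID {seq_id!r}")
            table[seq_id] = parse_taxonomy_string(raw, dialect, missing_vocab)
    return TaxonomyTable(table)


def write_taxonomy_tsv(table: TaxonomyTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for seq_id, lin in table.items():
            w.writerow([
                seq_id,
                ";".join(
                    render_labels(lin.labels[r], sentinel="") for r in range(N_RANKS)
                ) + ";",
            ])
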