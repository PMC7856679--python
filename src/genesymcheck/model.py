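"""Core domain types for gene-symbol validation and correction.

Gene symbols drift: genes get renamed (``GCN5L2`` became ``KAT2A``), informal
aliases circulate, symbols are withdrawn, and spreadsheet software silently
rewrites some of them as dates (``DEC1`` -> ``1-DEC``) or scientific notation
(``2310009E13`` -> ``2.31001E+19``).  This module defines the in-memory
vocabulary the rest of the package shares: a :class:`GeneSymbolMap` is a
multimap from every recognisable lookup form of a symbol (the approved symbol
itself, aliases, previously approved symbols, spreadsheet renderings, MGI
withdrawn-symbol redirects) to the currently approved symbol(s), and a
:class:`CheckResult` is the verdict on one queried symbol.

Types here carry no I/O and no algorithmics; constructing any of them with an
invariant-violating value raises :class:`ValueError`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterator, Optional, Set, Tuple

__all__ = [
    "Species",
    "SourceKind",
    "MapEntry",
    "GeneSymbolMap",
    "CheckResult",
    "MogrificationRecord",
    "SUGGESTION_DELIMITER",
    "MapFormatError",
    "FetchError",
]

#: Delimiter joining multiple suggested approved symbols in one output cell.
#: Approved gene symbols never contain "/", so the token is unambiguous.
SUGGESTION_DELIMITER = " /// "


class MapFormatError(ValueError):
    """A nomenclature source file or map snapshot is malformed."""


class FetchError(RuntimeError):
    """A network fetch of a nomenclature file failed (retriable)."""


class Species(str, Enum):
    """The two supported nomenclature authorities: HGNC (human), MGI (mouse)."""

    HUMAN = "human"
    MOUSE = "mouse"

    @classmethod
    def coerce(cls, value: "Species | str") -> "Species":
        """Accept a Species or its string name; reject anything else."""
        if isinstance(value, Species):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"species must be 'human' or 'mouse', got {value!r}"
            ) from None


class SourceKind(str, Enum):
    """Provenance of a lookup key -> approved symbol pair.

    Precedence (used when one key reaches the same approved symbol through
    several routes, and when the checker decides validity) is, from strongest
    to weakest: approved identity, previously approved symbol, withdrawn-symbol
    redirect (an MGI-curated rename), informal alias, spreadsheet-mangled
    rendering.
    """

    APPROVED_IDENTITY = "approved_identity"
    PREVIOUS_SYMBOL = "previous_symbol"
    WITHDRAWN_REDIRECT = "withdrawn_redirect"
    ALIAS = "alias"
    MOGRIFIED = "mogrified"

    @property
    def precedence(self) -> int:
        """Smaller is stronger."""
        return _PRECEDENCE[self]


_PRECEDENCE = {
    SourceKind.APPROVED_IDENTITY: 0,
    SourceKind.PREVIOUS_SYMBOL: 1,
    SourceKind.WITHDRAWN_REDIRECT: 2,
    SourceKind.ALIAS: 3,
    SourceKind.MOGRIFIED: 4,
}


@dataclass(frozen=True)
class MapEntry:
    """One lookup key resolving to one approved symbol.

    Parameters
    ----------
    key:
        The lookup form (case-normalized per species convention for symbol
        keys; verbatim for spreadsheet renderings, which are case-sensitive
        artifacts).  Non-empty; must not contain tabs or newlines, so
        snapshots serialize losslessly as TSV.
    approved:
        The currently approved symbol the key resolves to, case preserved as
        in the source file.
    source_kind:
        Provenance of the pair.
    chromosome:
        Chromosome designator of the approved gene ("1".."22", "X", "Y",
        "MT") when known; ``None`` otherwise.  Used for disambiguating keys
        that resolve to genes on different chromosomes.
    """

    key: str
    approved: str
    source_kind: SourceKind
    chromosome: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.key:
            raise ValueError("MapEntry.key must be non-empty")
        if any(c in self.key for c in "\t\n\r"):
            raise ValueError(f"MapEntry.key contains tab/newline: {self.key!r}")
        if not self.approved:
            raise ValueError(f"MapEntry.approved must be non-empty (key={self.key!r})")
        if any(c in self.approved for c in "\t\n\r"):
            raise ValueError(
                f"MapEntry.approved contains tab/newline: {self.approved!r}"
            )
        if not isinstance(self.source_kind, SourceKind):
            raise ValueError(f"invalid source_kind: {self.source_kind!r}")
        if self.chromosome is not None and (
            self.chromosome == "" or "\t" in self.chromosome
        ):
            raise ValueError(f"invalid chromosome: {self.chromosome!r}")


@dataclass(frozen=True)
class CheckResult:
    """Verdict on one queried symbol.

    ``input`` is the query verbatim.  ``approved_flag`` is True iff the query
    (after species case normalization) is a currently approved symbol.  When
    the query is invalid but correctable, ``suggested`` holds the approved
    symbol(s), several candidates joined by :data:`SUGGESTION_DELIMITER`;
    ``None`` means unmappable (rendered as ``NA`` in text output).
    """

    input: str
    approved_flag: bool
    suggested: Optional[str] = None

    def __post_init__(self) -> None:
        if self.approved_flag and self.suggested is None:
            raise ValueError("a valid symbol must carry its normalized form")
        if self.suggested is not None and self.suggested == "":
            raise ValueError("suggested must be non-empty or None")

    @property
    def suggestions(self) -> Tuple[str, ...]:
        """The suggested approved symbols as a tuple (empty if unmappable)."""
        if self.suggested is None:
            return ()
        return tuple(self.suggested.split(SUGGESTION_DELIMITER))


@dataclass(frozen=True)
class MogrificationRecord:
    """A symbol plus every string the emulated spreadsheet renders it as.

    ``renderings`` is empty iff the symbol is not coercible; the original is
    never its own rendering.
    """

    original: str
    renderings: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "renderings", frozenset(self.renderings))
        if self.original in self.renderings:
            raise ValueError(
                f"original {self.original!r} must not be among its renderings"
            )

    @property
    def coercible(self) -> bool:
        return bool(self.renderings)


class GeneSymbolMap:
    """Multimap from lookup keys to approved symbols, with provenance.

    Invariants maintained on insertion:

    * no key maps twice to the same approved symbol — duplicates collapse,
      keeping the strongest :class:`SourceKind`;
    * lookups return entries in a stable, lexicographic order of approved
      symbol;
    * a case-folded secondary index supports case-insensitive retrieval
      (needed for mouse symbols, whose keys are stored verbatim).
    """

    def __init__(
        self,
        species: Species | str,
        build_date: Optional[datetime.date] = None,
        source_label: str = "unspecified",
    ) -> None:
        self.species = Species.coerce(species)
        self.build_date = build_date or datetime.date.today()
        self.source_label = source_label
        # key -> approved -> entry
        self._entries: Dict[str, Dict[str, MapEntry]] = {}
        # casefolded key -> set of exact keys
        self._casefold: Dict[str, Set[str]] = {}

    # -- construction -----------------------------------------------------

    def add(self, entry: MapEntry) -> None:
        """Insert an entry, collapsing duplicates by source-kind precedence."""
        bucket = self._entries.setdefault(entry.key, {})
        existing = bucket.get(entry.approved)
        if existing is None or entry.source_kind.precedence < existing.source_kind.precedence:
            bucket[entry.approved] = entry
        self._casefold.setdefault(entry.key.casefold(), set()).add(entry.key)

    def copy(self) -> "GeneSymbolMap":
        dup = GeneSymbolMap(self.species, self.build_date, self.source_label)
        dup._entries = {k: dict(v) for k, v in self._entries.items()}
        dup._casefold = {k: set(v) for k, v in self._casefold.items()}
        return dup

    # -- lookup -----------------------------------------------------------

    def lookup(self, key: str) -> Tuple[MapEntry, ...]:
        """Entries for an exact key, sorted by approved symbol."""
        bucket = self._entries.get(key)
        if not bucket:
            return ()
        return tuple(bucket[a] for a in sorted(bucket))

    def lookup_casefold(self, key: str) -> Tuple[MapEntry, ...]:
        """Entries for any key equal to ``key`` up to case, deduplicated."""
        merged: Dict[str, MapEntry] = {}
        for exact in sorted(self._casefold.get(key.casefold(), ())):
            for entry in self.lookup(exact):
                prev = merged.get(entry.approved)
                if prev is None or entry.source_kind.precedence < prev.source_kind.precedence:
                    merged[entry.approved] = entry
        return tuple(merged[a] for a in sorted(merged))

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def keys(self) -> Iterator[str]:
        return iter(self._entries)

    def iter_entries(self) -> Iterator[MapEntry]:
        """All entries, sorted by (key, approved) for determinism."""
        for key in sorted(self._entries):
            bucket = self._entries[key]
            for approved in sorted(bucket):
                yield bucket[approved]

    def approved_symbols(self) -> Tuple[str, ...]:
        """All symbols present as approved-identity targets, sorted."""
        out = {
            e.approved
            for bucket in self._entries.values()
            for e in bucket.values()
            if e.source_kind is SourceKind.APPROVED_IDENTITY
        }
        return tuple(sorted(out))

    def counts_by_kind(self) -> Dict[SourceKind, int]:
        counts: Dict[SourceKind, int] = {k: 0 for k in SourceKind}
        for bucket in self._entries.values():
            for e in bucket.values():
                counts[e.source_kind] += 1
        return counts

    # -- misc -------------------------------------------------------------

    def __len__(self) -> int:
        return sum(len(b) for b in self._entries.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSymbolMap):
            return NotImplemented
        return (
            self.species == other.species
            and self.build_date == other.build_date
            and self.source_label == other.source_label
            and self._entries == other._entries
        )

    def __repr__(self) -> str:
        return (
            f"GeneSymbolMap(species={self.species.value!r}, "
            f"entries={len(self)}, build_date={self.build_date.isoformat()}, "
            f"source_label={self.source_label!r})"
        )
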