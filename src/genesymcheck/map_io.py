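"""Reading and writing gene-symbol maps.

Two source dialects are supported:

* the HGNC complete-set file (``hgnc_complete_set.txt``): tab-separated with a
  header row; multi-value fields (``alias_symbol``, ``prev_symbol``) are
  pipe-delimited and may be double-quoted.  Columns are located **by name**,
  because the live file gains columns over time.
* the MGI EntrezGene report (``MGI_EntrezGene.rpt``): tab-separated with no
  header; column positions are fixed by :class:`MgiDialect` (the report's
  published layout), configurable because the file documents no schema.

Both parsers produce a :class:`~genesymcheck.model.GeneSymbolMap`.  Withdrawn
HGNC entries contribute nothing — a withdrawn symbol is invalid with no
suggestion.  MGI withdrawn rows whose name reads ``withdrawn, = NewSymbol``
contribute a redirect to the new symbol.

Maps serialize to a dated TSV snapshot (commented metadata preamble + one row
per entry) that round-trips exactly, so a map built once can be shipped or
cached without re-downloading the sources.
"""

from __future__ import annotations

import csv
import datetime
import io
import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, TextIO

from .checker import normalize_case_human
from .model import (
    FetchError,
    GeneSymbolMap,
    MapEntry,
    MapFormatError,
    SourceKind,
    Species,
)

__all__ = [
    "HGNC_REQUIRED_COLUMNS",
    "MgiDialect",
    "DEFAULT_MGI_DIALECT",
    "SOURCE_URLS",
    "parse_hgnc",
    "parse_mgi",
    "parse_chromosome",
    "fetch_map",
    "save_map",
    "load_map",
]

logger = logging.getLogger(__name__)

HGNC_REQUIRED_COLUMNS = ("symbol", "status", "alias_symbol", "prev_symbol", "location")

#: Canonical download locations.  Configuration values, not logic: the
#: authorities move/update these, and every fetch accepts an override.
SOURCE_URLS: Dict[Species, str] = {
    Species.HUMAN: (
        "https://ftp.ebi.ac.uk/pub/databases/genenames/new/tsv/hgnc_complete_set.txt"
    ),
    Species.MOUSE: "http://www.informatics.jax.org/downloads/reports/MGI_EntrezGene.rpt",
}


@dataclass(frozen=True)
class MgiDialect:
    """0-based column positions in the headerless MGI EntrezGene report."""

    mgi_id: int = 0
    symbol: int = 1
    status: int = 2
    name: int = 3
    chromosome: int = 5
    synonyms: int = 9
    official_code: str = "O"
    withdrawn_code: str = "W"

    @property
    def min_columns(self) -> int:
        """Columns every row must have (through the name field)."""
        return max(self.mgi_id, self.symbol, self.status, self.name) + 1


DEFAULT_MGI_DIALECT = MgiDialect()

_CHROM_RE = re.compile(r"(2[0-2]|1[0-9]|[1-9]|X|Y)")


def parse_chromosome(location: str) -> Optional[str]:
    """Chromosome designator from a cytogenetic band string.

    ``"1q32.1"`` -> ``"1"``; ``"Xp22.2"`` -> ``"X"``; mitochondrial locations
    map to ``"MT"``; anything unparseable -> ``None``.  Total function.
    """
    text = (location or "").strip()
    if not text:
        return None
    if text.lower().startswith("mitochondri") or text.upper() == "MT":
        return "MT"
    match = _CHROM_RE.match(text)
    if match is None:
        return None
    return match.group(1)


def _split_multi(field: str) -> List[str]:
    """Split a pipe-delimited multi-value field, trimming whitespace."""
    if not field or not field.strip():
        return []
    return [part.strip() for part in field.split("|") if part.strip()]


def parse_hgnc(stream: TextIO) -> GeneSymbolMap:
    """Parse the HGNC complete-set file into a human gene-symbol map.

    Approved rows contribute an approved-identity entry keyed by their own
    symbol plus one alias entry per ``alias_symbol`` token and one
    previous-symbol entry per ``prev_symbol`` token, all carrying the
    chromosome extracted from ``location``.  Withdrawn rows contribute
    nothing.  Alias/previous keys are stored case-normalized (uppercase with
    the orf exception), so lookup is a single hash probe.
    """
    reader = csv.reader(stream, delimiter="\t", quotechar='"')
    try:
        header = next(reader)
    except StopIteration:
        raise MapFormatError("HGNC file is empty") from None
    positions: Dict[str, int] = {name.strip(): i for i, name in enumerate(header)}
    for column in HGNC_REQUIRED_COLUMNS:
        if column not in positions:
            raise MapFormatError(f"HGNC file is missing required column {column!r}")

    gene_map = GeneSymbolMap(Species.HUMAN, source_label="HGNC snapshot")
    n_rows = 0
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        n_rows += 1

        def get(column: str) -> str:
            index = positions[column]
            return row[index].strip() if index < len(row) else ""

        symbol = get("symbol")
        status = get("status")
        if not symbol:
            raise MapFormatError(f"HGNC line {lineno}: empty symbol field")
        if status.lower() != "approved":
            continue  # withdrawn / merged symbols are unmappable by design
        chromosome = parse_chromosome(get("location"))
        gene_map.add(
            MapEntry(
                key=normalize_case_human(symbol),
                approved=symbol,
                source_kind=SourceKind.APPROVED_IDENTITY,
                chromosome=chromosome,
            )
        )
        for alias in _split_multi(get("alias_symbol")):
            gene_map.add(
                MapEntry(
                    key=normalize_case_human(alias),
                    approved=symbol,
                    source_kind=SourceKind.ALIAS,
                    chromosome=chromosome,
                )
            )
        for prev in _split_multi(get("prev_symbol")):
            gene_map.add(
                MapEntry(
                    key=normalize_case_human(prev),
                    approved=symbol,
                    source_kind=SourceKind.PREVIOUS_SYMBOL,
                    chromosome=chromosome,
                )
            )
    if n_rows == 0:
        raise MapFormatError("HGNC file has a header but no data rows")
    if len(gene_map) == 0:
        raise MapFormatError("HGNC file contains no approved symbols")
    return gene_map


_MGI_WITHDRAWN_RE = re.compile(r"^withdrawn,\s*=\s*(\S+)")


def parse_mgi(
    stream: TextIO, dialect: MgiDialect = DEFAULT_MGI_DIALECT
) -> GeneSymbolMap:
    """Parse the MGI EntrezGene report into a mouse gene-symbol map.

    Official rows (status ``O``) contribute an approved-identity entry and one
    alias entry per pipe-delimited synonym.  Withdrawn rows (status ``W``)
    whose name matches ``withdrawn, = NewSymbol`` contribute a redirect
    old -> new; withdrawn rows without a redirect contribute nothing.  Mouse
    keys are stored verbatim (the map keeps a case-folded secondary index).
    """
    gene_map = GeneSymbolMap(Species.MOUSE, source_label="MGI snapshot")
    n_rows = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < dialect.min_columns:
            raise MapFormatError(
                f"MGI line {lineno}: expected at least {dialect.min_columns} "
                f"columns, found {len(fields)}"
            )
        n_rows += 1
        symbol = fields[dialect.symbol].strip()
        status = fields[dialect.status].strip()
        name = fields[dialect.name].strip()
        chromosome: Optional[str] = None
        if dialect.chromosome < len(fields):
            chrom_field = fields[dialect.chromosome].strip()
            if chrom_field and chrom_field.upper() != "UN":
                chromosome = chrom_field
        if not symbol:
            raise MapFormatError(f"MGI line {lineno}: empty symbol field")

        if status == dialect.withdrawn_code:
            redirect = _MGI_WITHDRAWN_RE.match(name)
            if redirect is not None:
                gene_map.add(
                    MapEntry(
                        key=symbol,
                        approved=redirect.group(1),
                        source_kind=SourceKind.WITHDRAWN_REDIRECT,
                        chromosome=chromosome,
                    )
                )
            continue
        if status != dialect.official_code:
            continue

        gene_map.add(
            MapEntry(
                key=symbol,
                approved=symbol,
                source_kind=SourceKind.APPROVED_IDENTITY,
                chromosome=chromosome,
            )
        )
        synonyms_field = (
            fields[dialect.synonyms] if dialect.synonyms < len(fields) else ""
        )
        for synonym in _split_multi(synonyms_field):
            gene_map.add(
                MapEntry(
                    key=synonym,
                    approved=symbol,
                    source_kind=SourceKind.ALIAS,
                    chromosome=chromosome,
                )
            )
    if n_rows == 0:
        raise MapFormatError("MGI report is empty")
    if len(gene_map) == 0:
        raise MapFormatError("MGI report contains no official symbols")
    return gene_map


# ---------------------------------------------------------------------------
# snapshot serialization

_SNAPSHOT_HEADER = "key\tapproved\tsource_kind\tchromosome"
_PREAMBLE_FIELDS = ("species", "build_date", "source_label")


def save_map(gene_map: GeneSymbolMap, stream: TextIO) -> None:
    """Write a map snapshot: commented metadata preamble + sorted TSV body."""
    stream.write(f"#species\t{gene_map.species.value}\n")
    stream.write(f"#build_date\t{gene_map.build_date.isoformat()}\n")
    stream.write(f"#source_label\t{gene_map.source_label}\n")
    stream.write(_SNAPSHOT_HEADER + "\n")
    for entry in gene_map.iter_entries():
        chromosome = entry.chromosome or ""
        stream.write(
            f"{entry.key}\t{entry.approved}\t{entry.source_kind.value}\t{chromosome}\n"
        )


def load_map(stream: TextIO) -> GeneSymbolMap:
    """Load a snapshot written by :func:`save_map` (exact round trip)."""
    metadata: Dict[str, str] = {}
    lines = iter(enumerate(stream, start=1))
    header_seen = False
    entries: List[MapEntry] = []
    for lineno, raw in lines:
        line = raw.rstrip("\n").rstrip("\r")
        if not header_seen:
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                metadata[key.strip()] = value.strip()
                continue
            for field_name in _PREAMBLE_FIELDS:
                if field_name not in metadata:
                    raise MapFormatError(
                        f"snapshot is missing metadata field {field_name!r}"
                    )
            if line != _SNAPSHOT_HEADER:
                raise MapFormatError(
                    f"snapshot line {lineno}: expected header "
                    f"{_SNAPSHOT_HEADER!r}, found {line!r}"
                )
            header_seen = True
            continue
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise MapFormatError(
                f"snapshot line {lineno}: expected 4 columns, found {len(fields)}"
            )
        key, approved, kind_token, chromosome = fields
        try:
            kind = SourceKind(kind_token)
        except ValueError:
            raise MapFormatError(
                f"snapshot line {lineno}: unknown source_kind {kind_token!r}"
            ) from None
        entries.append(
            MapEntry(
                key=key,
                approved=approved,
                source_kind=kind,
                chromosome=chromosome or None,
            )
        )
    if not header_seen:
        # empty stream or preamble without header
        for field_name in _PREAMBLE_FIELDS:
            if field_name not in metadata:
                raise MapFormatError(f"snapshot is missing metadata field {field_name!r}")
        raise MapFormatError("snapshot has no column header")
    try:
        build_date = datetime.date.fromisoformat(metadata["build_date"])
    except ValueError:
        raise MapFormatError(
            f"snapshot has invalid build_date {metadata['build_date']!r}"
        ) from None
    gene_map = GeneSymbolMap(
        Species.coerce(metadata["species"]),
        build_date=build_date,
        source_label=metadata["source_label"],
    )
    for entry in entries:
        gene_map.add(entry)
    return gene_map


# ---------------------------------------------------------------------------
# fetching

def fetch_map(
    species: Species | str,
    url_override: Optional[str] = None,
    timeout: float = 120.0,
) -> GeneSymbolMap:
    """Download and parse the current nomenclature file for a species.

    The parsed map is extended with spreadsheet-mogrification reversal
    entries.  A network failure raises :class:`FetchError` and never returns
    a partial map; a malformed download raises :class:`MapFormatError`.
    """
    from .excel import extend_map_with_mogrifications

    species = Species.coerce(species)
    url = url_override or SOURCE_URLS[species]
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            text = response.read().decode("utf-8", errors="replace")
    except (urllib.error.URLError, OSError, ValueError) as exc:
        raise FetchError(f"could not fetch {url}: {exc}") from exc
    if species is Species.HUMAN:
        gene_map = parse_hgnc(io.StringIO(text))
    else:
        gene_map = parse_mgi(io.StringIO(text))
    gene_map = extend_map_with_mogrifications(gene_map)
    gene_map.build_date = datetime.date.today()
    gene_map.source_label = f"{'HGNC' if species is Species.HUMAN else 'MGI'} download"
    logger.info("fetched %s map: %d entries", species.value, len(gene_map))
    return gene_map
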