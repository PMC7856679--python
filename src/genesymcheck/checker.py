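"""Symbol validation and correction.

The correction procedure for a queried symbol runs in three conceptual steps:

1. **Capitalization** — human symbols are uppercased except the open reading
   frame (orf) infix, which is lowercase by convention (``c9orf72`` ->
   ``C9orf72``); mouse symbols take an initial capital followed by lowercase
   (``BRCA1`` -> ``Brca1``).
2. **Mogrification reversal** — spreadsheet renderings (``1-DEC``,
   ``2.31001E+19``) are looked up in the reversal index built by
   :mod:`genesymcheck.excel`.  Renderings are matched verbatim before case
   normalization can destroy them; both title- and upper-case renderings are
   indexed, so either route succeeds.
3. **Alias resolution** — aliases, previously approved symbols, and
   withdrawn-symbol redirects map to the currently approved symbol(s).

A query that reaches an approved symbol identically (after case fixing) is
reported valid.  A query reaching one or more approved symbols indirectly is
reported invalid with the sorted candidates joined by ``" /// "``.  An
optional per-query chromosome disambiguates keys shared by genes on different
chromosomes — e.g. ``FHL1`` is both an approved symbol (on X) and an alias of
``CFH`` (on 1): unqueried it is simply valid, but with chromosome ``"1"`` it
corrects to ``CFH``.  Queries reaching nothing are unmappable: withdrawn
symbols, lncRNA names, LOC identifiers, probe IDs, blanks.  No fuzzy matching
of typos is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from .model import (
    SUGGESTION_DELIMITER,
    CheckResult,
    GeneSymbolMap,
    MapEntry,
    SourceKind,
    Species,
)

__all__ = [
    "CheckOptions",
    "normalize_case_human",
    "normalize_case_mouse",
    "normalize_symbol",
    "check_one",
    "check_symbols",
    "check_gene_symbols",
]

logger = logging.getLogger(__name__)

# orf nomenclature: C<chromosome>orf<number>, the one lowercase exception in
# human symbols.  Chromosome token is 1-22, X or Y; two-digit alternatives
# first so the match is maximal.
_ORF_RE = re.compile(r"C(2[0-2]|1[0-9]|[1-9]|X|Y)ORF(?=[0-9])")


@dataclass
class CheckOptions:
    """Options governing a batch check.

    ``unmapped_as_na`` (default True) reports unmappable symbols with an
    absent suggestion (rendered ``NA``); when False the original input is kept
    in the suggestion column.  ``chromosomes``, when given, must align
    one-to-one with the query list.
    """

    species: Species
    unmapped_as_na: bool = True
    chromosomes: Optional[Sequence[Optional[str]]] = None

    def __post_init__(self) -> None:
        self.species = Species.coerce(self.species)


def normalize_case_human(symbol: str) -> str:
    """Uppercase a human symbol, keeping the orf infix lowercase.

    >>> normalize_case_human("c9orf72")
    'C9orf72'
    """
    upper = symbol.strip().upper()
    return _ORF_RE.sub(lambda m: f"C{m.group(1)}orf", upper)


def normalize_case_mouse(symbol: str) -> str:
    """Initial capital, all later letters lowercase; digits/punctuation kept.

    >>> normalize_case_mouse("BRCA1")
    'Brca1'
    """
    out: List[str] = []
    seen_alpha = False
    for ch in symbol.strip():
        if ch.isalpha():
            out.append(ch.lower() if seen_alpha else ch.upper())
            seen_alpha = True
        else:
            out.append(ch)
    return "".join(out)


def normalize_symbol(symbol: str, species: Species | str) -> str:
    """Apply the species' capitalization convention."""
    if Species.coerce(species) is Species.HUMAN:
        return normalize_case_human(symbol)
    return normalize_case_mouse(symbol)


def _lookup(query: str, gene_map: GeneSymbolMap) -> Sequence[MapEntry]:
    """First-hit lookup: exact key (catches verbatim symbols and the
    case-sensitive spreadsheet renderings), then the case-normalized key,
    then a case-folded probe (covers mouse synonyms stored verbatim)."""
    hits = gene_map.lookup(query)
    if hits:
        return hits
    hits = gene_map.lookup(normalize_symbol(query, gene_map.species))
    if hits:
        return hits
    return gene_map.lookup_casefold(query)


def check_one(
    symbol: str,
    gene_map: GeneSymbolMap,
    options: CheckOptions,
    chromosome: Optional[str] = None,
) -> CheckResult:
    """Validate and, where possible, correct a single symbol.

    The chromosome filter is advisory: candidates on a conflicting chromosome
    are dropped, but if that would leave nothing the unfiltered candidates are
    returned, so a wrong or missing chromosome degrades gracefully.
    """
    if gene_map.species is not Species.coerce(options.species):
        raise ValueError(
            f"map species {gene_map.species.value!r} does not match "
            f"options species {Species.coerce(options.species).value!r}"
        )
    raw = symbol if isinstance(symbol, str) else ""
    query = raw.strip()
    if not query:
        return CheckResult(input=raw, approved_flag=False, suggested=None)

    hits = _lookup(query, gene_map)

    def excluded(entry: MapEntry) -> bool:
        return (
            chromosome is not None
            and entry.chromosome is not None
            and entry.chromosome != chromosome
        )

    approved_hits = [
        e for e in hits
        if e.source_kind is SourceKind.APPROVED_IDENTITY and not excluded(e)
    ]
    if approved_hits:
        normalized = normalize_symbol(query, gene_map.species)
        if not any(e.approved == normalized for e in approved_hits):
            # approved symbol whose own casing defies the species convention
            normalized = approved_hits[0].approved
        return CheckResult(input=raw, approved_flag=True, suggested=normalized)

    if hits:
        targets = sorted({e.approved for e in hits if not excluded(e)})
        if not targets:  # filter emptied the set: degrade to unfiltered
            targets = sorted({e.approved for e in hits})
        return CheckResult(
            input=raw,
            approved_flag=False,
            suggested=SUGGESTION_DELIMITER.join(targets),
        )

    return CheckResult(
        input=raw,
        approved_flag=False,
        suggested=None if options.unmapped_as_na else raw,
    )


def check_symbols(
    symbols: Sequence[str],
    gene_map: GeneSymbolMap,
    options: Optional[CheckOptions] = None,
) -> List[CheckResult]:
    """Check a list of symbols; output aligns one-to-one with the input.

    Logs one informational line with the map's build date and the counts of
    valid, corrected and unmappable queries.
    """
    if options is None:
        options = CheckOptions(species=gene_map.species)
    chromosomes = options.chromosomes
    if chromosomes is not None and len(chromosomes) != len(symbols):
        raise ValueError(
            f"chromosomes length {len(chromosomes)} does not match "
            f"query length {len(symbols)}"
        )
    results = [
        check_one(
            s,
            gene_map,
            options,
            chromosome=chromosomes[i] if chromosomes is not None else None,
        )
        for i, s in enumerate(symbols)
    ]
    n_valid = sum(r.approved_flag for r in results)
    n_corrected = sum((not r.approved_flag) and r.suggested is not None for r in results)
    n_unmappable = len(results) - n_valid - n_corrected
    logger.info(
        "map last updated %s (%s): checked %d symbols — %d valid, "
        "%d corrected, %d unmappable",
        gene_map.build_date.isoformat(),
        gene_map.source_label,
        len(results),
        n_valid,
        n_corrected,
        n_unmappable,
    )
    return results


def check_gene_symbols(
    symbols: Sequence[str],
    species: Species | str = Species.HUMAN,
    gene_map: Optional[GeneSymbolMap] = None,
    chromosomes: Optional[Sequence[Optional[str]]] = None,
    unmapped_as_na: bool = True,
):
    """High-level interface returning a pandas DataFrame.

    Columns are ``x`` (the input, verbatim), ``Approved`` (bool) and
    ``Suggested.Symbol`` (approved symbol(s), several joined by ``" /// "``;
    missing when unmappable).  When ``gene_map`` is omitted the packaged
    synthetic demonstration snapshot is used; for real analyses build or
    fetch a current map first.
    """
    import pandas as pd

    species = Species.coerce(species)
    if gene_map is None:
        from .data import load_default_map

        gene_map = load_default_map(species)
    options = CheckOptions(
        species=species, unmapped_as_na=unmapped_as_na, chromosomes=chromosomes
    )
    results = check_symbols(list(symbols), gene_map, options)
    return pd.DataFrame(
        {
            "x": [r.input for r in results],
            "Approved": [r.approved_flag for r in results],
            "Suggested.Symbol": [r.suggested for r in results],
        }
    )
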