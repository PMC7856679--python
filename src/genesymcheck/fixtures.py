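"""Synthetic miniature nomenclature files with known ground truth.

Real HGNC/MGI dumps are large, frequently updated, and not redistributable
here; this module generates fully synthetic stand-ins in the exact file
dialects the parsers read, together with a *truth table* — the exact list of
map entries the file must parse into — so every layer of the package is
testable offline and end to end.

The generated content deliberately includes the classic trouble cases:

* an alias rename (``GCN5L2`` -> ``KAT2A``);
* an approved-symbol/alias collision (``FHL1`` approved on X, and an alias of
  ``CFH`` on 1) for chromosome disambiguation;
* date-coercible symbols (``DEC1``, ``SEPT1``, ``MARCH1``, ``MARC1`` — the
  last two share the rendering ``1-Mar``);
* a scientific-notation-coercible symbol (``2310009E13``);
* an orf-cased symbol (``C9orf72``);
* a withdrawn symbol (``OCLM``; mouse: a ``withdrawn, = NewSymbol`` redirect);

plus any number of deterministic pseudo-random filler genes.  Generation is a
pure function of ``(spec, seed)``: the same spec always yields byte-identical
files.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .checker import CheckOptions, normalize_case_human, normalize_symbol
from .excel import CoercionRuleSet, DEFAULT_RULES, mogrify
from .map_io import parse_chromosome
from .model import (
    SUGGESTION_DELIMITER,
    CheckResult,
    GeneSymbolMap,
    MapEntry,
    SourceKind,
    Species,
)

__all__ = [
    "FixtureSpec",
    "generate_hgnc_fixture",
    "generate_mgi_fixture",
    "generate_query_set",
    "write_fixture_dir",
    "UNMAPPABLE_QUERIES",
]

#: Queries with no possible mapping, mixed into generated query sets: a
#: withdrawn symbol, an uncharacterized LOC identifier, a lncRNA name, a probe
#: id, plain garbage, and blank/whitespace inputs.
UNMAPPABLE_QUERIES = ("OCLM", "LOC644669", "lnc-ARMCX4-1", "200041_s_at", "XYZ999", "", "   ")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling synthetic nomenclature-file generation."""

    n_approved: int = 20
    n_alias_per: int = 2
    n_prev_per: int = 1
    include_collision: bool = True
    include_date_coercible: bool = True
    include_sci_coercible: bool = True
    include_withdrawn: bool = True
    include_orf: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_approved", "n_alias_per", "n_prev_per"):
            if getattr(self, name) < 0:
                raise ValueError(f"FixtureSpec.{name} must be >= 0")


_HGNC_HEADER = (
    "hgnc_id\tsymbol\tname\tlocus_group\tstatus\tlocation\talias_symbol\tprev_symbol"
)

# fixed cast of named trouble-case genes (synthetic annotations)
_HGNC_NAMED = {
    "base": [
        # symbol, name, location, aliases, prevs
        ("KAT2A", "lysine acetyltransferase 2A", "17q21.2", ["GCN5L2"], []),
        ("TP53", "tumor protein p53", "17p13.1", [], []),
    ],
    "collision": [
        ("CFH", "complement factor H", "1q31.3", ["FHL1"], ["HF1"]),
        ("FHL1", "four and a half LIM domains 1", "Xq26.3", [], []),
    ],
    "date": [
        ("DEC1", "deleted in esophageal cancer 1", "9q33.1", [], []),
        ("SEPT1", "septin 1", "16p11.2", ["DIFF6"], []),
        ("MARCH1", "membrane associated ring-CH-type finger 1", "4q24", [], []),
        ("MARC1", "mitochondrial amidoxime reducing component 1", "1q41", [], []),
    ],
    "sci": [
        ("2310009E13", "uncharacterized reading-frame symbol", "7q11.1", [], []),
    ],
    "orf": [
        ("C9orf72", "chromosome 9 open reading frame 72", "9p21.2", [], []),
    ],
}

_MGI_NAMED = {
    "base": [
        # symbol, name, chromosome, synonyms
        ("Brca1", "breast cancer 1, early onset", "11", ["Brca-1"]),
        ("Trp53", "transformation related protein 53", "11", []),
    ],
    "withdrawn_target": [
        ("Bhlhe40", "basic helix-loop-helix family, member e40", "6", ["Dec-1 related"]),
    ],
    "sci": [
        ("2310009E13", "RIKEN-style clone symbol", "7", []),
    ],
}


def _quote_if_multi(value: str) -> str:
    """The HGNC dialect double-quotes multi-value fields."""
    return f'"{value}"' if "|" in value else value


def _random_symbol(rng: random.Random, used: Set[str], prefix: str = "") -> str:
    """An uppercase letters+digits token not seen before."""
    while True:
        letters = "".join(rng.choices(string.ascii_uppercase, k=rng.randint(3, 5)))
        digits = "".join(rng.choices(string.digits, k=rng.randint(1, 2)))
        candidate = f"{prefix}{letters}{digits}"
        if candidate not in used:
            used.add(candidate)
            return candidate


def generate_hgnc_fixture(spec: FixtureSpec) -> Tuple[str, List[MapEntry]]:
    """Synthetic HGNC complete-set file text plus its parse truth table."""
    rng = random.Random(spec.seed)
    rows: List[Tuple[str, str, str, str, List[str], List[str]]] = []
    # (symbol, name, status, location, aliases, prevs)
    named: List[Tuple[str, str, str, List[str], List[str]]] = list(_HGNC_NAMED["base"])
    if spec.include_collision:
        named += _HGNC_NAMED["collision"]
    if spec.include_date_coercible:
        named += _HGNC_NAMED["date"]
    if spec.include_sci_coercible:
        named += _HGNC_NAMED["sci"]
    if spec.include_orf:
        named += _HGNC_NAMED["orf"]
    if spec.n_approved == 0 and not any(
        (
            spec.include_collision,
            spec.include_date_coercible,
            spec.include_sci_coercible,
            spec.include_withdrawn,
            spec.include_orf,
        )
    ):
        named = []  # fully degenerate: header-only file

    used: Set[str] = set()
    for symbol, name, location, aliases, prevs in named:
        used.add(symbol)
        used.update(aliases)
        used.update(prevs)
    if named:
        for symbol, name, location, aliases, prevs in named:
            rows.append((symbol, name, "Approved", location, aliases, prevs))

    locations = ["1p36.1", "2q31.1", "5q14.3", "7p21.3", "11q13.2", "19p13.3", "Xq28", "Yq11.2", ""]
    for _ in range(spec.n_approved):
        symbol = _random_symbol(rng, used)
        aliases = [_random_symbol(rng, used) for _ in range(spec.n_alias_per)]
        prevs = [_random_symbol(rng, used) for _ in range(spec.n_prev_per)]
        rows.append(
            (symbol, f"synthetic gene {symbol}", "Approved", rng.choice(locations), aliases, prevs)
        )
    if spec.include_withdrawn:
        rows.append(("OCLM", "oculomedin", "Entry Withdrawn", "1q25.2", [], []))

    lines = [_HGNC_HEADER]
    truth: List[MapEntry] = []
    for i, (symbol, name, status, location, aliases, prevs) in enumerate(rows, start=1):
        lines.append(
            "\t".join(
                [
                    f"HGNC:{i}",
                    symbol,
                    name,
                    "protein-coding gene",
                    status,
                    location,
                    _quote_if_multi("|".join(aliases)),
                    _quote_if_multi("|".join(prevs)),
                ]
            )
        )
        if status != "Approved":
            continue
        chromosome = parse_chromosome(location)
        truth.append(
            MapEntry(
                key=normalize_case_human(symbol),
                approved=symbol,
                source_kind=SourceKind.APPROVED_IDENTITY,
                chromosome=chromosome,
            )
        )
        for alias in aliases:
            truth.append(
                MapEntry(
                    key=normalize_case_human(alias),
                    approved=symbol,
                    source_kind=SourceKind.ALIAS,
                    chromosome=chromosome,
                )
            )
        for prev in prevs:
            truth.append(
                MapEntry(
                    key=normalize_case_human(prev),
                    approved=symbol,
                    source_kind=SourceKind.PREVIOUS_SYMBOL,
                    chromosome=chromosome,
                )
            )
    return "\n".join(lines) + "\n", truth


def generate_mgi_fixture(spec: FixtureSpec) -> Tuple[str, List[MapEntry]]:
    """Synthetic MGI EntrezGene report text plus its parse truth table.

    Emits the default 10-column dialect (id, symbol, status, name, cM,
    chromosome, type, secondary ids, entrez id, synonyms).
    """
    rng = random.Random(spec.seed + 1)
    # (symbol, status, name, chromosome, synonyms)
    rows: List[Tuple[str, str, str, str, List[str]]] = []
    named: List[Tuple[str, str, str, List[str]]] = list(_MGI_NAMED["base"])
    if spec.include_withdrawn:
        named += _MGI_NAMED["withdrawn_target"]
    if spec.include_sci_coercible:
        named += _MGI_NAMED["sci"]
    for symbol, name, chromosome, synonyms in named:
        rows.append((symbol, "O", name, chromosome, synonyms))
    if spec.include_withdrawn:
        rows.append(("Dec1", "W", "withdrawn, = Bhlhe40", "6", []))
        rows.append(("Gsymw1", "W", "withdrawn", "", []))

    used: Set[str] = set()
    for symbol, _, _, _, synonyms in rows:
        used.add(symbol)
        used.update(synonyms)
    chromosomes = ["1", "2", "4", "7", "11", "17", "19", "X", "Y", ""]
    for _ in range(spec.n_approved):
        while True:
            symbol = _random_symbol(rng, used).capitalize()
            if symbol not in used:
                break
        used.add(symbol)
        synonyms = [_random_symbol(rng, used) for _ in range(spec.n_alias_per)]
        rows.append((symbol, "O", f"synthetic gene {symbol}", rng.choice(chromosomes), synonyms))

    lines: List[str] = []
    truth: List[MapEntry] = []
    for i, (symbol, status, name, chromosome, synonyms) in enumerate(rows, start=1):
        lines.append(
            "\t".join(
                [
                    f"MGI:{100000 + i}",
                    symbol,
                    status,
                    name,
                    "syntenic",
                    chromosome,
                    "Gene",
                    "",
                    str(200000 + i),
                    "|".join(synonyms),
                ]
            )
        )
        chrom: Optional[str] = chromosome or None
        if status == "O":
            truth.append(
                MapEntry(
                    key=symbol,
                    approved=symbol,
                    source_kind=SourceKind.APPROVED_IDENTITY,
                    chromosome=chrom,
                )
            )
            for synonym in synonyms:
                truth.append(
                    MapEntry(
                        key=synonym,
                        approved=symbol,
                        source_kind=SourceKind.ALIAS,
                        chromosome=chrom,
                    )
                )
        elif status == "W" and name.startswith("withdrawn, ="):
            target = name.split("=", 1)[1].strip()
            truth.append(
                MapEntry(
                    key=symbol,
                    approved=target,
                    source_kind=SourceKind.WITHDRAWN_REDIRECT,
                    chromosome=chrom,
                )
            )
    return "\n".join(lines) + "\n" if lines else "", truth


def generate_query_set(
    gene_map: GeneSymbolMap,
    rules: CoercionRuleSet = DEFAULT_RULES,
    seed: int = 0,
    unmappable: Sequence[str] = UNMAPPABLE_QUERIES,
) -> Tuple[List[str], List[CheckResult]]:
    """A shuffled query list with its expected check results.

    Coverage is exhaustive over the map rather than sampled: every approved
    symbol appears verbatim and (where unambiguous) case-mangled; every
    alias / previous-symbol / redirect key appears; every spreadsheet
    rendering of every key appears; plus the fixed unmappable inputs
    (withdrawn, LOC/lncRNA/probe identifiers, garbage, blanks).  Expected
    results are derived directly from the map's entries by the documented
    resolution rules — approved identity wins, otherwise the sorted approved
    targets are joined by ``" /// "`` — independently of the checker's
    lookup machinery.  An empty map yields an empty query set.
    """
    if len(gene_map) == 0:
        return [], []
    rng = random.Random(seed)
    pairs: List[Tuple[str, CheckResult]] = []
    seen: Set[str] = set()

    def emit(query: str, result: CheckResult) -> None:
        if query not in seen:
            seen.add(query)
            pairs.append((query, result))

    def expected_for_key(query: str, entries: Sequence[MapEntry]) -> CheckResult:
        if any(e.source_kind is SourceKind.APPROVED_IDENTITY for e in entries):
            return CheckResult(query, True, normalize_symbol(query, gene_map.species))
        targets = sorted({e.approved for e in entries})
        return CheckResult(query, False, SUGGESTION_DELIMITER.join(targets))

    mangle = str.lower if gene_map.species is Species.HUMAN else str.upper
    for key in sorted(gene_map.keys()):
        entries = gene_map.lookup(key)
        emit(key, expected_for_key(key, entries))
        if all(e.source_kind is SourceKind.MOGRIFIED for e in entries):
            continue  # renderings are case-sensitive artifacts: verbatim only
        mangled = mangle(key)
        if (
            mangled != key
            and mangled not in gene_map
            and normalize_symbol(mangled, gene_map.species)
            == normalize_symbol(key, gene_map.species)
        ):
            base = expected_for_key(key, entries)
            emit(mangled, CheckResult(mangled, base.approved_flag, base.suggested))

    for query in unmappable:
        if query.strip() and query in gene_map:
            continue
        emit(query, CheckResult(query, False, None))

    rng.shuffle(pairs)
    queries = [q for q, _ in pairs]
    expected = [r for _, r in pairs]
    return queries, expected


def write_fixture_dir(
    directory: "Path | str",
    spec: FixtureSpec = FixtureSpec(),
    rules: CoercionRuleSet = DEFAULT_RULES,
) -> Dict[str, Path]:
    """Write the four fixture artifacts to a directory.

    ``fixture_hgnc.tsv`` and ``fixture_mgi.rpt`` are the synthetic source
    files; ``queries.txt`` is a human query list (one symbol per line);
    ``expected.tsv`` is the check output the CLI must reproduce byte-for-byte
    (columns ``x``, ``Approved``, ``Suggested.Symbol``; TRUE/FALSE/NA).
    Returns the paths keyed by artifact name.
    """
    from .excel import extend_map_with_mogrifications
    from .map_io import parse_hgnc

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hgnc_text, _ = generate_hgnc_fixture(spec)
    mgi_text, _ = generate_mgi_fixture(spec)
    paths = {
        "hgnc": directory / "fixture_hgnc.tsv",
        "mgi": directory / "fixture_mgi.rpt",
        "queries": directory / "queries.txt",
        "expected": directory / "expected.tsv",
    }
    paths["hgnc"].write_text(hgnc_text, newline="\n")
    paths["mgi"].write_text(mgi_text, newline="\n")

    import io as _io

    gene_map = extend_map_with_mogrifications(parse_hgnc(_io.StringIO(hgnc_text)), rules)
    queries, expected = generate_query_set(gene_map, rules, seed=spec.seed)
    paths["queries"].write_text("".join(q + "\n" for q in queries), newline="\n")
    body = ["x\tApproved\tSuggested.Symbol"]
    for result in expected:
        flag = "TRUE" if result.approved_flag else "FALSE"
        suggestion = result.suggested if result.suggested is not None else "NA"
        body.append(f"{result.input}\t{flag}\t{suggestion}")
    paths["expected"].write_text("".join(line + "\n" for line in body), newline="\n")
    return paths
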