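"""Deterministic emulation of spreadsheet auto-coercion of gene symbols.

Spreadsheet software interprets symbols such as ``DEC1``, ``SEPT1``, ``MARCH1``
or ``MARC1`` as calendar dates and symbols such as ``2310009E13`` as numbers in
scientific notation, silently rewriting them on export.  Rather than importing
a symbol list into an actual spreadsheet and exporting it in every date format,
this module forward-simulates the coercion with an explicit, auditable rule set
and uses the simulated renderings to build a reversal index: each rendering
becomes a ``mogrified`` map entry pointing back at the approved symbol(s) it
could have come from.

The emulated dialect is fixed and locale-independent: English month names only,
four date output formats (``D-MMM``, ``DD-MMM``, ``MMM-DD``, ``D-MMMM``) in
title and upper case, and 6-significant-digit scientific notation.  A month is
recognised from any prefix of its English name of length >= 3 (``MAR``,
``MARC``, ``MARCH`` ...), which is the behaviour that corrupts both the septin
(``SEPT?``) and ``MARC?`` gene families.  Date *serial numbers* (``43709``) are
deliberately not emulated: their reversal is year-dependent and collision-prone.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping, Optional, TextIO, Tuple

from .model import GeneSymbolMap, MapEntry, MogrificationRecord, SourceKind

__all__ = [
    "MONTH_NAMES",
    "CoercionRuleSet",
    "DEFAULT_RULES",
    "coerce_as_date",
    "render_date",
    "coerce_as_number",
    "mogrify",
    "extend_map_with_mogrifications",
]

logger = logging.getLogger(__name__)

#: Fixed English month table — never taken from the system locale.
MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)

#: Longest day a spreadsheet accepts per month.  February is capped at 29:
#: acceptance of Feb-29 depends on the current year in a real spreadsheet, and
#: always accepting it makes the reversal index a safe superset.
DEFAULT_MAX_DAY = {
    1: 31, 2: 29, 3: 31, 4: 30, 5: 31, 6: 30,
    7: 31, 8: 31, 9: 30, 10: 31, 11: 30, 12: 31,
}

_DATE_FORMATS = ("D-MMM", "DD-MMM", "MMM-DD", "D-MMMM")
_CASE_VARIANTS = ("title", "upper")
_SEPARATORS = ("-", " ", "/", ".")


def _default_month_tokens() -> Dict[str, int]:
    """Every uppercase prefix (length >= 3) of every English month name."""
    tokens: Dict[str, int] = {}
    for num, name in enumerate(MONTH_NAMES, start=1):
        upper = name.upper()
        for cut in range(3, len(upper) + 1):
            tokens[upper[:cut]] = num
    return tokens


@dataclass(frozen=True)
class CoercionRuleSet:
    """The emulated spreadsheet dialect.

    Parameters
    ----------
    month_tokens:
        Case-insensitive token -> month number.  Defaults to all >=3-letter
        prefixes of the English month names (50 tokens), which covers the
        three-letter abbreviations, the full names, and the prefixes
        (``SEPT``, ``MARC``) responsible for the well-known septin/MARC
        symbol corruptions.
    max_day:
        Largest accepted day per month (Feb capped at 29, see module note).
    date_output_formats:
        Ordered subset of ``D-MMM``, ``DD-MMM``, ``MMM-DD``, ``D-MMMM``.
    case_variants:
        Subset of ``title`` / ``upper`` applied to the month part.
    sci_digits:
        Significant digits of the scientific-notation rendering (spreadsheet
        "General" display uses 6).
    """

    month_tokens: Mapping[str, int] = field(default_factory=_default_month_tokens)
    max_day: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MAX_DAY))
    date_output_formats: Tuple[str, ...] = _DATE_FORMATS
    case_variants: Tuple[str, ...] = _CASE_VARIANTS
    sci_digits: int = 6

    def __post_init__(self) -> None:
        upper_tokens: Dict[str, int] = {}
        for token, month in self.month_tokens.items():
            key = token.upper()
            if key in upper_tokens and upper_tokens[key] != month:
                raise ValueError(f"month token {token!r} defined twice (case-insensitively)")
            if not 1 <= int(month) <= 12:
                raise ValueError(f"month number out of range for token {token!r}: {month}")
            upper_tokens[key] = int(month)
        object.__setattr__(self, "month_tokens", upper_tokens)
        for fmt in self.date_output_formats:
            if fmt not in _DATE_FORMATS:
                raise ValueError(f"unknown date output format: {fmt!r}")
        for case in self.case_variants:
            if case not in _CASE_VARIANTS:
                raise ValueError(f"unknown case variant: {case!r}")
        if self.sci_digits < 1:
            raise ValueError("sci_digits must be >= 1")
        object.__setattr__(self, "max_day", dict(self.max_day))
        object.__setattr__(self, "_date_re", self._compile_date_re())

    def _compile_date_re(self) -> "re.Pattern[str]":
        # Longest tokens first so SEPT wins over SEP when both could anchor.
        alternation = "|".join(
            re.escape(t) for t in sorted(self.month_tokens, key=len, reverse=True)
        )
        sep = r"[-/. ]?"
        return re.compile(
            rf"(?:(?P<tok1>{alternation}){sep}(?P<day1>[0-9]{{1,2}})"
            rf"|(?P<day2>[0-9]{{1,2}}){sep}(?P<tok2>{alternation}))$",
            re.IGNORECASE,
        )

    # -- config round trip -------------------------------------------------

    def to_config(self, stream: TextIO) -> None:
        """Serialize as a plain key=value file, so the dialect is auditable."""
        stream.write(f"sci_digits={self.sci_digits}\n")
        stream.write("date_output_formats=" + ",".join(self.date_output_formats) + "\n")
        stream.write("case_variants=" + ",".join(self.case_variants) + "\n")
        stream.write(
            "max_day=" + ",".join(f"{m}:{d}" for m, d in sorted(self.max_day.items())) + "\n"
        )
        for token in sorted(self.month_tokens):
            stream.write(f"month_token={token}:{self.month_tokens[token]}\n")

    @classmethod
    def from_config(cls, stream: TextIO) -> "CoercionRuleSet":
        kwargs: Dict[str, object] = {}
        tokens: Dict[str, int] = {}
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            if key == "sci_digits":
                kwargs["sci_digits"] = int(value)
            elif key == "date_output_formats":
                kwargs["date_output_formats"] = tuple(value.split(","))
            elif key == "case_variants":
                kwargs["case_variants"] = tuple(value.split(","))
            elif key == "max_day":
                kwargs["max_day"] = {
                    int(m): int(d) for m, d in (p.split(":") for p in value.split(","))
                }
            elif key == "month_token":
                tok, _, num = value.partition(":")
                tokens[tok] = int(num)
            else:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
        if tokens:
            kwargs["month_tokens"] = tokens
        return cls(**kwargs)  # type: ignore[arg-type]


DEFAULT_RULES = CoercionRuleSet()


def coerce_as_date(
    symbol: str, rules: CoercionRuleSet = DEFAULT_RULES
) -> Optional[Tuple[int, int]]:
    """Return ``(month, day)`` if a spreadsheet would read the symbol as a date.

    The symbol must consist, case-insensitively, of a month token and a 1-2
    digit day (either order) with at most one separator from ``- space / .``,
    and the day must exist in that month (Feb capped at 29).  Total function:
    anything else returns ``None``.
    """
    match = rules._date_re.fullmatch(symbol.strip())  # type: ignore[attr-defined]
    if match is None:
        return None
    token = match.group("tok1") or match.group("tok2")
    day_text = match.group("day1") or match.group("day2")
    month = rules.month_tokens[token.upper()]
    day = int(day_text)
    if not 1 <= day <= rules.max_day.get(month, 0):
        return None
    return (month, day)


def render_date(
    month: int,
    day: int,
    format_id: str,
    case_variant: str = "title",
    rules: CoercionRuleSet = DEFAULT_RULES,
) -> str:
    """Render a (month, day) the way the emulated spreadsheet prints it.

    ``D-MMM`` -> ``1-Sep``; ``DD-MMM`` -> ``01-Sep``; ``MMM-DD`` -> ``Sep-01``;
    ``D-MMMM`` -> ``1-September``; the ``upper`` case variant uppercases the
    month part (``1-SEP``).
    """
    if format_id not in _DATE_FORMATS:
        raise ValueError(f"unknown date output format: {format_id!r}")
    if case_variant not in _CASE_VARIANTS:
        raise ValueError(f"unknown case variant: {case_variant!r}")
    if not 1 <= month <= 12 or not 1 <= day <= rules.max_day.get(month, 0):
        raise ValueError(f"invalid calendar day: month={month}, day={day}")
    name = MONTH_NAMES[month - 1]
    abbrev = name[:3]
    if case_variant == "upper":
        name, abbrev = name.upper(), abbrev.upper()
    if format_id == "D-MMM":
        return f"{day}-{abbrev}"
    if format_id == "DD-MMM":
        return f"{day:02d}-{abbrev}"
    if format_id == "MMM-DD":
        return f"{abbrev}-{day:02d}"
    return f"{day}-{name}"  # D-MMMM


_SCI_RE = re.compile(r"[0-9]+(?:\.[0-9]+)?[Ee][0-9]+")


def coerce_as_number(symbol: str, sci_digits: int = 6) -> Optional[str]:
    """Scientific-notation rendering of an E-style symbol, or ``None``.

    Symbols matching ``digits[.digits]E digits`` (e.g. RIKEN clone names like
    ``2310009E13``) are read as mantissa x 10^exponent in exact decimal
    arithmetic and printed with ``sci_digits`` significant digits and a signed
    two-digit exponent, as spreadsheet "General" display does:
    ``2310009E13`` -> ``2.31001E+19``.
    """
    if _SCI_RE.fullmatch(symbol.strip()) is None:
        return None
    mantissa_text, _, exponent_text = re.split(r"([Ee])", symbol.strip(), maxsplit=1)
    value = Decimal(mantissa_text).scaleb(int(exponent_text))
    if value == 0:
        return f"{Decimal(0):.{sci_digits - 1}f}E+00"
    exp = value.adjusted()
    quantum = Decimal(1).scaleb(-(sci_digits - 1))
    mantissa = value.scaleb(-exp).quantize(quantum, rounding=ROUND_HALF_UP)
    if mantissa >= 10:  # rounding bumped 9.99995... to 10
        mantissa = (mantissa / 10).quantize(quantum, rounding=ROUND_HALF_UP)
        exp += 1
    sign = "+" if exp >= 0 else "-"
    return f"{mantissa:.{sci_digits - 1}f}E{sign}{abs(exp):02d}"


def mogrify(symbol: str, rules: CoercionRuleSet = DEFAULT_RULES) -> MogrificationRecord:
    """All spreadsheet renderings of a symbol under the emulated dialect.

    Renderings cover the full date format x case grid when the symbol is
    date-coercible, plus the scientific rendering when it is number-coercible;
    the original is never included.  Non-coercible symbols yield an empty set.
    """
    renderings: set[str] = set()
    as_date = coerce_as_date(symbol, rules)
    if as_date is not None:
        month, day = as_date
        for fmt in rules.date_output_formats:
            for case in rules.case_variants:
                renderings.add(render_date(month, day, fmt, case, rules))
    as_number = coerce_as_number(symbol, rules.sci_digits)
    if as_number is not None:
        renderings.add(as_number)
    renderings.discard(symbol)
    return MogrificationRecord(original=symbol, renderings=frozenset(renderings))


def extend_map_with_mogrifications(
    gene_map: GeneSymbolMap, rules: CoercionRuleSet = DEFAULT_RULES
) -> GeneSymbolMap:
    """Add reversal entries for every coercible key of a map.

    Every approved / alias / previous / redirect key is forward-mogrified and
    each rendering becomes a ``mogrified`` entry pointing at that key's
    approved target(s).  Renderings shared by several originals (``MARC1`` and
    ``MARCH1`` both print as ``1-Mar``) become multimap entries.  Existing
    stronger entries are never overwritten, by source-kind precedence; a
    rendering colliding with a real approved symbol is logged.  The input map
    is not modified.
    """
    extended = gene_map.copy()
    for entry in gene_map.iter_entries():
        if entry.source_kind is SourceKind.MOGRIFIED:
            continue
        record = mogrify(entry.key, rules)
        for rendering in record.renderings:
            existing = extended.lookup(rendering)
            if any(e.source_kind is SourceKind.APPROVED_IDENTITY for e in existing):
                logger.warning(
                    "rendering %r of %r collides with an approved symbol; "
                    "approved identity takes precedence",
                    rendering,
                    entry.key,
                )
            extended.add(
                MapEntry(
                    key=rendering,
                    approved=entry.approved,
                    source_kind=SourceKind.MOGRIFIED,
                    chromosome=entry.chromosome,
                )
            )
    return extended
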