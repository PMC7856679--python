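# Methods

## The correction model

`genesymcheck` treats gene-symbol correction as dictionary reversal, not
inference. A **correction map** for a species is a multimap
`key → {approved symbol, …}` in which every currently approved symbol is a
key for itself, and every other recognisable form of a symbol — alias,
previously approved symbol, MGI withdrawn-symbol redirect, or spreadsheet
rendering — is a key pointing at the approved symbol(s) it can stand for.
Each `key → approved` pair carries a provenance tag (`source_kind`) and,
where the source file allows it, the chromosome of the approved gene.

Two structural rules keep lookups deterministic:

* **Deduplication by precedence.** A key never maps twice to the same
  approved symbol; when several routes exist, the strongest provenance is
  kept: approved identity > previous symbol > withdrawn redirect > alias >
  mogrified. The position of `withdrawn_redirect` is this package's choice:
  a redirect is an authority-curated rename and therefore outranks an
  informal alias, but the original behaviour of comparable tools is unstated.
* **Stable ordering.** Looking up a key yields entries sorted
  lexicographically by approved symbol, so multi-gene suggestions are always
  rendered in the same order, joined by the literal delimiter `" /// "`
  (approved symbols never contain `/`). The delimiter is a documented
  convention; an "unmappable" verdict is an explicit absent state, rendered
  `NA` only at the text boundary, so a hypothetical gene literally named
  `NA` could never be confused with it.

## Checking a query

For one query the lookup sequence is: (1) the exact string; (2) the
case-normalized string; (3) a case-folded probe. Step 1 runs first because
spreadsheet renderings are case-sensitive artifacts — uppercasing `1-Sep`
first would lose information (though `1-SEP` is also indexed, the order is
fixed for determinism). Step 3 exists mainly for mouse maps, whose keys are
stored verbatim; human keys are already stored case-normalized.

Case normalization: human symbols are uppercased, then any
`C<1–22|X|Y>ORF<digits>` run is rewritten with lowercase `orf` (the one
lowercase exception in human nomenclature); mouse symbols get an initial
capital followed by lowercase letters, with digits and punctuation untouched.
Both transforms are idempotent (property-tested).

Resolution: if any reachable entry is an approved identity not excluded by
the chromosome constraint, the query is **valid** and the suggestion is its
normalized form — a pure capitalization fix (`BRCA1` → `Brca1`) therefore
counts as valid. Otherwise the suggestion is the sorted set of approved
targets, filtered by chromosome *when both sides state one*. The filter is
advisory: if it would empty the candidate set, the unfiltered set is
returned, so a wrong or missing chromosome degrades gracefully rather than
destroying a correction. Queries reaching nothing are invalid; by default
the suggestion is absent (`unmapped_as_na=True`), optionally the original
input is kept. Blank or whitespace-only inputs are always invalid with an
absent suggestion — real annotation files contain blanks, and they should
never raise.

The collision policy follows from precedence: a symbol that is both approved
and an alias of another gene (*FHL1*, also an alias of *CFH*) is reported
valid when unconstrained; supplying the other gene's chromosome flips the
verdict to a correction. Should a spreadsheet rendering ever collide with a
real approved symbol, approved identity wins and the collision is logged as
a warning at map-build time.

## The emulated spreadsheet dialect

The mogrification index is built by *forward-simulating* coercion for every
non-mogrified key of a map, rather than by round-tripping a symbol list
through actual spreadsheet software. The emulated dialect is explicit,
serializable (`CoercionRuleSet.to_config`/`from_config`) and
locale-independent (month names are a fixed English table):

* **Month tokens**: every prefix of length ≥ 3 of the twelve English month
  names — 50 tokens. The prefix rule, rather than a fixed abbreviation list,
  is what makes both `SEPT1…SEPT14` (septins) and `MARC1`/`MARC2` coercible,
  exactly the families that forced nomenclature renames; a plain
  {3-letter + full name} table would miss `MARC1`.
* **Date recognition**: `<token><sep?><day>` or `<day><sep?><token>`,
  case-insensitive, one optional separator from `- space / .`, day of 1–2
  digits valid for the month. February is capped at 29: real spreadsheet
  acceptance of `FEB29` depends on the current year, and always accepting it
  makes the reversal index a superset — a key that never occurs in data from
  non-leap years is harmless.
* **Date output**: formats `D-MMM` (`1-Sep`), `DD-MMM` (`01-Sep`), `MMM-DD`
  (`Sep-01`), `D-MMMM` (`1-September`), each in title and upper case — eight
  renderings per date-coercible symbol. `MMM-DD` strings are indexed under
  the month-*day* interpretation only; the month-*year* reading of `Sep-02`
  is out of scope.
* **Numbers**: symbols matching `digits[.digits]E digits` are rendered in
  scientific notation with 6 significant digits (half-up rounding, exact
  decimal arithmetic) and a signed ≥2-digit exponent, matching common
  "General" display: `2310009E13` → `2.31001E+19`.
* **Not emulated**: date serial numbers (`43709`) — their reversal is
  year-dependent and collision-prone — and locale-specific month names. The
  rendering set is a deliberate, documented superset of what any one
  spreadsheet build produces; supersets are safe for a reversal index keyed
  by renderings.

Invariants verified by tests: forward/backward closure (every rendering of
every map symbol resolves back to it), no self-mapping, agreement with a
brute-force calendar validator over the exhaustive token × day 1–31 ×
separator × order grid (15 500 strings), and agreement of the scientific
rendering with C `%.5E` formatting away from exact rounding ties.

## Source-file parsing

* **HGNC complete set**: tab-separated with a header; required columns
  (`symbol`, `status`, `alias_symbol`, `prev_symbol`, `location`) are located
  by name, since the live file gains columns over time. Multi-value fields
  are pipe-delimited and possibly double-quoted (handled by the `csv`
  module). Only `Approved` rows contribute entries; withdrawn rows
  contribute nothing, making their symbols invalid-without-suggestion. The
  chromosome is the leading designator of the cytogenetic band (`1q32.1` →
  `1`, `mitochondria` → `MT`).
* **MGI EntrezGene report**: tab-separated, headerless; column positions
  (0-based: id 0, symbol 1, status 2, name 3, chromosome 5, synonyms 9) are
  fixed by an `MgiDialect` constant and configurable, since the report
  documents no schema. Status `O` rows are official; `W` rows whose name
  matches `withdrawn, = NewSymbol` become redirects.
* **Snapshots**: a map serializes to a TSV with a commented metadata preamble
  (`#species`, `#build_date`, `#source_label`) and sorted
  `key/approved/source_kind/chromosome` rows. Round-tripping is exact and
  byte-stable; unknown tokens, missing metadata and malformed rows fail with
  the offending line number. Canonical download URLs are configuration
  values; `fetch-map` accepts any override (including `file://`), and a
  failed fetch never yields a partial map.

## Synthetic fixtures

The fixture generator emulates both source dialects at miniature scale and
returns, with each file, the exact entry list it must parse into. Generation
is a pure function of `(FixtureSpec, seed)`; the same spec yields
byte-identical files. Fixtures always contain the canonical trouble cases —
the *GCN5L2*→*KAT2A* alias, the *FHL1*/*CFH* collision with distinct
chromosomes, *DEC1*/*SEPT1*/*MARCH1*/*MARC1* (the last two share the
rendering `1-Mar`), *2310009E13*, *C9orf72*, withdrawn *OCLM* and a mouse
`withdrawn, =` redirect — plus any number of pseudo-random filler genes with
configurable alias/previous-symbol counts. Generated query sets are
exhaustive over the map (every key, case-mangled variants where unambiguous,
every rendering) plus fixed unmappable inputs (withdrawn, LOC/lncRNA/probe
identifiers, blanks), with expected verdicts derived from the entry lists by
the documented resolution rules.

What the fixtures do **not** emulate: genome-scale symbol distributions, the
long tail of historical HGNC renames, real MGI accession structure, or data
from mixed species. Passing tests therefore demonstrate the correctness of
the parsing/reversal/resolution machinery on files of the real dialects, not
recall statistics on any particular public database snapshot — those depend
on the map version, which is why maps are dated and rebuildable.

## Problem sizes and defaults

The default `FixtureSpec` (20 filler genes, 2 aliases and 1 previous symbol
each, all trouble-case flags on) keeps unit fixtures readable; the exhaustive
identity/idempotence and closure checks use a 5000-gene fixture map (~20 000
keys), comfortably larger than the count of coercible symbols in real
nomenclature while still checking every key, not a sample. The packaged
demonstration snapshots are built from a 25-gene spec with a pinned seed and
date so the committed files change only when the generator or rule set does.

## Known limitations

* Correction is lookup, not inference: misspellings, lncRNA names
  (`lnc-SOX11-1`), `LOC…` identifiers, probe IDs and non-human/non-mouse
  symbols are reported invalid with no suggestion. No fuzzy matching is
  attempted, by design.
* A symbol that is both approved and an alias is reported valid unless a
  chromosome disambiguates; without extra evidence that is the best
  available answer, but it can mask a genuine alias usage.
* The emulated coercion dialect is a superset-by-design; it may index rare
  renderings no specific spreadsheet build produces, and it omits serial
  numbers (above). Users can audit or restrict the dialect via the rule-set
  config file.
* Mouse symbols that legitimately violate the capitalization convention
  (rare lowercase-only historical symbols) are handled by falling back to
  the matched approved form rather than the normalized query.
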