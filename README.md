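# genesymcheck

Validation and correction of human and mouse gene symbols.

Gene symbols are memorable but unstable identifiers. Genes get renamed
(*GCN5L2* became *KAT2A* when its histone-acetyltransferase activity was
discovered), informal aliases circulate alongside approved symbols, some
symbols are withdrawn outright, and spreadsheet software silently rewrites
others on import/export: *DEC1* becomes the date `1-DEC`, *SEPT1* becomes
`1-Sep`, and RIKEN-style symbols such as *2310009E13* collapse to scientific
notation `2.31001E+19`. Any analysis keyed on symbols — platform annotation
tables, gene-set collections, published signatures — accumulates these
corruptions over time.

`genesymcheck` checks a list of symbols against a correction map built from
the authoritative nomenclature sources — HGNC (human) and MGI (mouse) — and
suggests the currently approved replacement where one exists. It is intended
for bioinformaticians cleaning symbol-annotated data before downstream
analysis.

## The method

A correction map is a multimap from every recognisable *lookup form* of a
symbol to the currently approved symbol(s), with provenance:

| key kind           | example key → approved        | built from                      |
|--------------------|-------------------------------|---------------------------------|
| approved identity  | `KAT2A` → KAT2A               | every approved symbol           |
| previous symbol    | `HF1` → CFH                   | HGNC `prev_symbol`              |
| withdrawn redirect | `Dec1` → Bhlhe40 (mouse)      | MGI "withdrawn, = …" rows       |
| alias              | `GCN5L2` → KAT2A              | HGNC `alias_symbol` / MGI synonyms |
| mogrified          | `1-DEC` → DEC1                | emulated spreadsheet coercion   |

Withdrawn symbols without a replacement (e.g. *OCLM*) contribute nothing and
are reported invalid with no suggestion.

Checking one query runs three steps: **capitalization** is normalized (human:
uppercase except the lowercase `orf` infix, so `c9orf72` → `C9orf72`; mouse:
initial capital then lowercase, so `BRCA1` → `Brca1`); **spreadsheet
renderings** are reversed through a deterministic coercion emulator (any
≥3-letter prefix of an English month name plus a valid day is a date, four
output formats × two case variants are indexed; `digits[.digits]Edigits`
symbols are indexed by their 6-significant-digit scientific rendering); and
**aliases/previous symbols** are mapped to their approved targets, sorted and
joined by `" /// "` when several genes share a key. A query that is itself an
approved symbol wins over any alias reading — *FHL1* is both approved and an
alias of *CFH*, and is reported valid — unless a per-query chromosome says
otherwise (with chromosome `1`, *FHL1* corrects to *CFH* on 1q31.3).

## Worked example

```python
>>> from genesymcheck import check_gene_symbols
>>> check_gene_symbols(["TP53", "GCN5L2", "1-DEC", "FHL1", "c9orf72", "OCLM"])
         x  Approved Suggested.Symbol
      TP53      True             TP53
    GCN5L2     False            KAT2A
     1-DEC     False             DEC1
      FHL1      True             FHL1
   c9orf72      True          C9orf72
      OCLM     False             None
```

`TP53` is already valid. `GCN5L2` is an alias: invalid, corrected to its
current name `KAT2A`. `1-DEC` is a spreadsheet-mangled `DEC1`. `FHL1` is
valid as-is (its alias reading is suppressed without chromosome evidence).
`c9orf72` only needed its capitalization fixed, and is therefore counted
valid. `OCLM` is withdrawn: invalid with no replacement (`None`, printed as
`NA` in text output).

The same check from the shell:

```sh
$ printf 'GCN5L2\n1-DEC\nOCLM\n' | genesymcheck check -
x	Approved	Suggested.Symbol
GCN5L2	FALSE	KAT2A
1-DEC	FALSE	DEC1
OCLM	FALSE	NA
```

The exit status is script-friendly: 0 when all inputs are valid, 1 when some
were corrected, 2 when some are unmappable.

**Maps.** The snapshot bundled with the package is a small *synthetic*
demonstration map. For real data, build a current one:

```sh
genesymcheck fetch-map --species human --out human_map.tsv     # needs network
# or, from a downloaded hgnc_complete_set.txt / MGI_EntrezGene.rpt:
genesymcheck build-map hgnc_complete_set.txt --species human --out human_map.tsv
genesymcheck check my_symbols.txt --map human_map.tsv --out checked.tsv
```

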