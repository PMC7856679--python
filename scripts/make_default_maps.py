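"""Regenerate the packaged synthetic demonstration snapshots.

Run from the repository root:

    python scripts/make_default_maps.py

The snapshots are fixture-scale synthetic maps (no real HGNC/MGI content);
regeneration is deterministic, so the committed files only change when the
fixture generator or the coercion rule set changes.
"""

import datetime
import io
import pathlib

from genesymcheck.excel import extend_map_with_mogrifications
from genesymcheck.fixtures import FixtureSpec, generate_hgnc_fixture, generate_mgi_fixture
from genesymcheck.map_io import parse_hgnc, parse_mgi, save_map

DATA_DIR = pathlib.Path(__file__).resolve().parent.parent / "src" / "genesymcheck" / "data"
SPEC = FixtureSpec(n_approved=25, seed=20240101)
# fixed date: the snapshot only changes when the generator does
BUILD_DATE = datetime.date(2024, 1, 1)


def main() -> None:
    hgnc_text, _ = generate_hgnc_fixture(SPEC)
    mgi_text, _ = generate_mgi_fixture(SPEC)
    for species, gene_map in (
        ("human", parse_hgnc(io.StringIO(hgnc_text))),
        ("mouse", parse_mgi(io.StringIO(mgi_text))),
    ):
        gene_map = extend_map_with_mogrifications(gene_map)
        gene_map.build_date = BUILD_DATE
        gene_map.source_label = "synthetic demonstration fixture"
        out = DATA_DIR / f"synthetic_snapshot_{species}.tsv"
        with open(out, "w", encoding="utf-8", newline="\n") as handle:
            save_map(gene_map, handle)
        print(f"wrote {out} ({len(gene_map)} entries)")


if __name__ == "__main__":
    main()
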