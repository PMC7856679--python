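"""HGNC / MGI parsers, chromosome extraction, snapshot round trip, fetching."""

import io
import pathlib

import pytest

from genesymcheck.map_io import (
    fetch_map,
    load_map,
    parse_chromosome,
    parse_hgnc,
    parse_mgi,
    save_map,
)
from genesymcheck.model import (
    FetchError,
    MapFormatError,
    SourceKind,
    Species,
)

MINI_HGNC = """\
hgnc_id\tsymbol\tname\tstatus\tlocation\talias_symbol\tprev_symbol
HGNC:1\tKAT2A\tlysine acetyltransferase 2A\tApproved\t17q21.2\tGCN5L2\t
HGNC:2\tCFH\tcomplement factor H\tApproved\t1q31.3\tFHL1\t"HF1|HUS"
HGNC:3\tFHL1\tfour and a half LIM domains 1\tApproved\tXq26.3\t\t
HGNC:4\tOCLM\toculomedin\tEntry Withdrawn\t1q25.2\t\t
"""

MINI_MGI = (
    "MGI:1\tBrca1\tO\tbreast cancer 1\t20.0\t11\tGene\t\t100\tBrca-1\n"
    "MGI:2\tDec1\tW\twithdrawn, = Bhlhe40\t\t6\tGene\t\t101\t\n"
    "MGI:3\tBhlhe40\tO\tbasic helix-loop-helix e40\t\t6\tGene\t\t102\t\n"
    "MGI:4\tOclm\tW\twithdrawn\t\t\tGene\t\t103\t\n"
)


class TestParseHgnc:
    def test_aliases_previous_and_collisions(self):
        gene_map = parse_hgnc(io.StringIO(MINI_HGNC))
        assert gene_map.species is Species.HUMAN
        assert [e.approved for e in gene_map.lookup("GCN5L2")] == ["KAT2A"]
        # FHL1 is simultaneously an approved symbol and an alias of CFH
        fhl1 = {e.approved: e.source_kind for e in gene_map.lookup("FHL1")}
        assert fhl1 == {
            "FHL1": SourceKind.APPROVED_IDENTITY,
            "CFH": SourceKind.ALIAS,
        }
        # quoted pipe-delimited multi-value field
        assert [e.approved for e in gene_map.lookup("HUS")] == ["CFH"]
        assert gene_map.lookup("HF1")[0].source_kind is SourceKind.PREVIOUS_SYMBOL

    def test_withdrawn_entries_contribute_nothing(self):
        gene_map = parse_hgnc(io.StringIO(MINI_HGNC))
        assert "OCLM" not in gene_map
        assert "OCLM" not in gene_map.approved_symbols()

    def test_chromosome_carried_on_every_entry(self):
        gene_map = parse_hgnc(io.StringIO(MINI_HGNC))
        assert gene_map.lookup("FHL1")[1].chromosome == "X"  # FHL1 itself
        assert gene_map.lookup("FHL1")[0].chromosome == "1"  # alias of CFH

    def test_header_only_is_a_format_error(self):
        header = MINI_HGNC.splitlines()[0] + "\n"
        with pytest.raises(MapFormatError):
            parse_hgnc(io.StringIO(header))

    def test_empty_file_is_a_format_error(self):
        with pytest.raises(MapFormatError, match="empty"):
            parse_hgnc(io.StringIO(""))

    def test_missing_required_column_named_in_error(self):
        bad = MINI_HGNC.replace("alias_symbol", "some_other_column")
        with pytest.raises(MapFormatError, match="alias_symbol"):
            parse_hgnc(io.StringIO(bad))

    def test_parsing_is_idempotent(self, hgnc_fixture):
        text = hgnc_fixture[0]
        first = parse_hgnc(io.StringIO(text))
        second = parse_hgnc(io.StringIO(text))
        assert set(first.iter_entries()) == set(second.iter_entries())

    def test_alias_targets_are_approved_keys(self, human_map):
        approved = set(human_map.approved_symbols())
        for entry in human_map.iter_entries():
            if entry.source_kind is SourceKind.ALIAS:
                assert entry.approved in approved


class TestParseMgi:
    def test_official_synonym_and_redirect_rows(self):
        gene_map = parse_mgi(io.StringIO(MINI_MGI))
        assert gene_map.species is Species.MOUSE
        assert [e.approved for e in gene_map.lookup("Brca-1")] == ["Brca1"]
        assert [e.approved for e in gene_map.lookup("Brca1")] == ["Brca1"]
        (redirect,) = gene_map.lookup("Dec1")
        assert redirect.approved == "Bhlhe40"
        assert redirect.source_kind is SourceKind.WITHDRAWN_REDIRECT
        # withdrawn without a redirect target contributes nothing
        assert "Oclm" not in gene_map

    def test_official_row_with_empty_synonyms(self):
        gene_map = parse_mgi(io.StringIO(MINI_MGI))
        assert [e.source_kind for e in gene_map.lookup("Bhlhe40")] == [
            SourceKind.APPROVED_IDENTITY
        ]

    def test_short_row_rejected_with_line_number(self):
        bad = MINI_MGI + "MGI:5\tShort1\n"
        with pytest.raises(MapFormatError, match="line 5"):
            parse_mgi(io.StringIO(bad))

    def test_empty_stream_is_a_format_error(self):
        with pytest.raises(MapFormatError, match="empty"):
            parse_mgi(io.StringIO(""))

    def test_hgnc_file_is_rejected_as_mouse_source(self):
        with pytest.raises(MapFormatError):
            parse_mgi(io.StringIO(MINI_HGNC))


class TestParseChromosome:
    @pytest.mark.parametrize("location,expected", [
        ("1q32.1", "1"),
        ("Xp22.2", "X"),
        ("Yq11.2", "Y"),
        ("19p13.3", "19"),
        ("22q11", "22"),
        ("2cen-q13", "2"),
        ("mitochondria", "MT"),
        ("MT", "MT"),
        ("", None),
        ("unplaced", None),
        ("not on reference assembly", None),
    ])
    def test_leading_designator(self, location, expected):
        assert parse_chromosome(location) == expected


class TestSnapshotRoundTrip:
    @pytest.mark.parametrize("map_fixture", ["human_map_ext", "mouse_map_ext"])
    def test_round_trip_identity(self, map_fixture, request):
        gene_map = request.getfixturevalue(map_fixture)
        buffer = io.StringIO()
        save_map(gene_map, buffer)
        buffer.seek(0)
        assert load_map(buffer) == gene_map

    def test_round_trip_is_byte_stable(self, human_map_ext):
        first, second = io.StringIO(), io.StringIO()
        save_map(human_map_ext, first)
        first.seek(0)
        save_map(load_map(first), second)
        first.seek(0)
        assert second.getvalue() == first.getvalue()

    def test_unknown_source_kind_rejected(self, human_map):
        buffer = io.StringIO()
        save_map(human_map, buffer)
        text = buffer.getvalue().replace("alias", "nickname", 1)
        with pytest.raises(MapFormatError, match="nickname"):
            load_map(io.StringIO(text))

    def test_missing_metadata_field_named(self, human_map):
        buffer = io.StringIO()
        save_map(human_map, buffer)
        lines = [l for l in buffer.getvalue().splitlines() if not l.startswith("#build_date")]
        with pytest.raises(MapFormatError, match="build_date"):
            load_map(io.StringIO("\n".join(lines) + "\n"))

    def test_wrong_column_count_reports_line(self, human_map):
        buffer = io.StringIO()
        save_map(human_map, buffer)
        lines = buffer.getvalue().splitlines()
        lines[4] = lines[4].replace("\t", " ")  # first data row after preamble+header
        with pytest.raises(MapFormatError, match="line 5"):
            load_map(io.StringIO("\n".join(lines) + "\n"))


class TestFetchMap:
    def test_unreachable_url_raises_fetch_error(self):
        with pytest.raises(FetchError):
            fetch_map("human", url_override="http://127.0.0.1:1/none.txt", timeout=2)

    def test_file_override_equals_offline_parse_plus_mogrifications(
        self, tmp_path, hgnc_fixture, human_map_ext
    ):
        source = tmp_path / "hgnc.tsv"
        source.write_text(hgnc_fixture[0])
        fetched = fetch_map("human", url_override=source.as_uri())
        assert fetched.species is Species.HUMAN
        assert set(fetched.iter_entries()) == set(human_map_ext.iter_entries())

    def test_mouse_override_propagates_species(self, tmp_path, mgi_fixture):
        source = tmp_path / "mgi.rpt"
        source.write_text(mgi_fixture[0])
        fetched = fetch_map("mouse", url_override=source.as_uri())
        assert fetched.species is Species.MOUSE
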