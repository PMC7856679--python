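"""Case normalization and the validation/correction algorithm."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genesymcheck.checker import (
    CheckOptions,
    check_gene_symbols,
    check_one,
    check_symbols,
    normalize_case_human,
    normalize_case_mouse,
)
from genesymcheck.model import SourceKind


class TestNormalizeCaseHuman:
    @pytest.mark.parametrize("symbol,expected", [
        ("c9orf72", "C9orf72"),
        ("C9ORF72", "C9orf72"),
        ("C10ORF54", "C10orf54"),
        ("C22orf39", "C22orf39"),
        ("CXORF21", "CXorf21"),
        ("tp53", "TP53"),
        ("  TP53 ", "TP53"),
        ("hla-drb1", "HLA-DRB1"),
        ("ORF1", "ORF1"),       # no chromosome token: not orf nomenclature
        ("CORF1", "CORF1"),     # ditto
    ])
    def test_uppercase_with_orf_exception(self, symbol, expected):
        assert normalize_case_human(symbol) == expected

    @given(st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-", max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, symbol):
        once = normalize_case_human(symbol)
        assert normalize_case_human(once) == once


class TestNormalizeCaseMouse:
    @pytest.mark.parametrize("symbol,expected", [
        ("BRCA1", "Brca1"),
        ("brca1", "Brca1"),
        ("Kat2a", "Kat2a"),
        ("2310009E13", "2310009E13"),
        ("  Trp53 ", "Trp53"),
        ("BRCA-1", "Brca-1"),
    ])
    def test_initial_capital_then_lowercase(self, symbol, expected):
        assert normalize_case_mouse(symbol) == expected

    @given(st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-", max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, symbol):
        once = normalize_case_mouse(symbol)
        assert normalize_case_mouse(once) == once


class TestCheckOne:
    def test_alias_corrected_to_approved(self, human_map_ext, human_opts):
        result = check_one("GCN5L2", human_map_ext, human_opts)
        assert (result.approved_flag, result.suggested) == (False, "KAT2A")

    def test_date_rendering_reversed(self, human_map_ext, human_opts):
        result = check_one("1-DEC", human_map_ext, human_opts)
        assert (result.approved_flag, result.suggested) == (False, "DEC1")

    def test_collision_valid_without_chromosome(self, human_map_ext, human_opts):
        result = check_one("FHL1", human_map_ext, human_opts)
        assert (result.approved_flag, result.suggested) == (True, "FHL1")

    def test_collision_resolved_by_chromosome(self, human_map_ext, human_opts):
        result = check_one("FHL1", human_map_ext, human_opts, chromosome="1")
        assert (result.approved_flag, result.suggested) == (False, "CFH")

    def test_withdrawn_symbol_unmappable(self, human_map_ext, human_opts):
        result = check_one("OCLM", human_map_ext, human_opts)
        assert (result.approved_flag, result.suggested) == (False, None)

    def test_unmapped_kept_when_requested(self, human_map_ext):
        options = CheckOptions(species="human", unmapped_as_na=False)
        assert check_one("XYZ999", human_map_ext, options).suggested == "XYZ999"

    @pytest.mark.parametrize("blank", ["", "   ", "\t "])
    def test_blank_input_invalid_without_suggestion(self, blank, human_map_ext):
        options = CheckOptions(species="human", unmapped_as_na=False)
        result = check_one(blank, human_map_ext, options)
        assert (result.approved_flag, result.suggested) == (False, None)

    def test_wrong_chromosome_degrades_to_unfiltered(self, human_map_ext, human_opts):
        # GCN5L2's only target sits on 17; an impossible constraint is advisory
        result = check_one("GCN5L2", human_map_ext, human_opts, chromosome="5")
        assert result.suggested == "KAT2A"

    def test_species_mismatch_rejected(self, human_map_ext, mouse_opts):
        with pytest.raises(ValueError, match="species"):
            check_one("TP53", human_map_ext, mouse_opts)

    def test_mouse_capitalization_fix(self, mouse_map_ext, mouse_opts):
        result = check_one("BRCA1", mouse_map_ext, mouse_opts)
        assert (result.approved_flag, result.suggested) == (True, "Brca1")

    def test_mouse_redirect_followed(self, mouse_map_ext, mouse_opts):
        result = check_one("Dec1", mouse_map_ext, mouse_opts)
        assert (result.approved_flag, result.suggested) == (False, "Bhlhe40")

    def test_sci_notation_rendering_reversed(self, mouse_map_ext, mouse_opts):
        result = check_one("2.31001E+19", mouse_map_ext, mouse_opts)
        assert (result.approved_flag, result.suggested) == (False, "2310009E13")


class TestCheckSymbols:
    def test_length_and_order_preserved(self, human_map_ext, human_opts):
        queries = ["TP53", "GCN5L2", "XYZ999", "TP53"]
        results = check_symbols(queries, human_map_ext, human_opts)
        assert [r.input for r in results] == queries
        assert [r.approved_flag for r in results] == [True, False, False, True]
        assert results[0] == results[3]  # per-row independence

    def test_empty_input(self, human_map_ext, human_opts):
        assert check_symbols([], human_map_ext, human_opts) == []

    def test_chromosome_length_mismatch_rejected(self, human_map_ext):
        options = CheckOptions(species="human", chromosomes=["1"])
        with pytest.raises(ValueError, match="length"):
            check_symbols(["FHL1", "TP53"], human_map_ext, options)

    def test_build_date_reported_in_log(self, human_map_ext, human_opts, caplog):
        with caplog.at_level(logging.INFO, logger="genesymcheck.checker"):
            check_symbols(["TP53"], human_map_ext, human_opts)
        assert human_map_ext.build_date.isoformat() in caplog.text


class TestAlgorithmProperties:
    def test_identity_on_every_approved_symbol(self, human_map_ext, human_opts):
        for symbol in human_map_ext.approved_symbols():
            result = check_one(symbol, human_map_ext, human_opts)
            assert (result.approved_flag, result.suggested) == (True, symbol)

    def test_resuggestion_is_idempotent(self, human_map_ext, human_opts):
        queries = list(human_map_ext.keys())
        for result in check_symbols(queries, human_map_ext, human_opts):
            for token in result.suggestions:
                again = check_one(token, human_map_ext, human_opts)
                assert (again.approved_flag, again.suggested) == (True, token)

    def test_case_insensitive_for_symbol_keys(self, human_map_ext, human_opts):
        for key in human_map_ext.keys():
            entries = human_map_ext.lookup(key)
            if all(e.source_kind is SourceKind.MOGRIFIED for e in entries):
                continue  # renderings are case-sensitive artifacts
            reference = check_one(key, human_map_ext, human_opts)
            variant = check_one(key.lower(), human_map_ext, human_opts)
            assert (variant.approved_flag, variant.suggested) == (
                reference.approved_flag,
                reference.suggested,
            )

    def test_approved_identity_beats_alias_for_every_collision(
        self, human_map_ext, human_opts
    ):
        collisions = [
            key
            for key in human_map_ext.keys()
            if any(
                e.source_kind is SourceKind.APPROVED_IDENTITY
                for e in human_map_ext.lookup(key)
            )
            and len(human_map_ext.lookup(key)) > 1
        ]
        assert collisions  # the fixture contains FHL1/CFH
        for key in collisions:
            assert check_one(key, human_map_ext, human_opts).approved_flag

    def test_mogrification_recovery(self, human_map_ext, human_opts):
        from genesymcheck.excel import mogrify

        for symbol in human_map_ext.approved_symbols():
            for rendering in mogrify(symbol).renderings:
                result = check_one(rendering, human_map_ext, human_opts)
                assert symbol in result.suggestions


class TestCheckGeneSymbols:
    def test_dataframe_shape_and_columns(self, human_map_ext):
        frame = check_gene_symbols(
            ["TP53", "GCN5L2", "XYZ999"], species="human", gene_map=human_map_ext
        )
        assert list(frame.columns) == ["x", "Approved", "Suggested.Symbol"]
        assert frame["Approved"].tolist() == [True, False, False]
        assert frame["Suggested.Symbol"].tolist()[:2] == ["TP53", "KAT2A"]

    def test_packaged_default_map_is_used_when_none_given(self):
        frame = check_gene_symbols(["GCN5L2"])
        assert frame.loc[0, "Suggested.Symbol"] == "KAT2A"
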