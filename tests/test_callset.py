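import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varconcord.callset import (
    CallSet,
    FusionCall,
    Platform,
    VariantCall,
    apply_dna_vaf_threshold,
    canonical_fusion_id,
    histology_class,
    normalize_variant_key,
    parse_alteration_label,
    read_callset,
    read_fusion_tsv,
    read_metadata_tsv,
    read_variant_tsv,
    read_vcf,
    write_fusion_tsv,
    write_metadata_tsv,
    write_variant_tsv,
    SampleRecord,
)
from conftest import make_variant_call, random_variant_callset


class TestNormalizeVariantKey:
    @pytest.mark.parametrize(
        "gene,change,exp_gene,exp_change",
        [
            ("braf", "V600E", "BRAF", "p.V600E"),
            ("BRAF", "p.v600e", "BRAF", "p.V600E"),
            ("Nras", "Q61R", "NRAS", "p.Q61R"),
            ("EIF1AX", "A113_splice", "EIF1AX", "p.A113_splice"),
        ],
    )
    def test_canonicalization(self, gene, change, exp_gene, exp_change):
        key = normalize_variant_key(gene, change)
        assert (key.gene, key.protein_change) == (exp_gene, exp_change)
        assert key.is_expressed_locus

    def test_promoter_locus_flagged_non_expressed(self):
        key = normalize_variant_key("TERT", "C228T")
        assert key.protein_change == "C228T"  # no p. prefix for a DNA token
        assert not key.is_expressed_locus
        forced = normalize_variant_key("TERT", "C228T", is_expressed_locus=True)
        assert forced.is_expressed_locus

    def test_case_insensitive_equality(self):
        assert normalize_variant_key("braf", "v600e") == normalize_variant_key(
            "BRAF", "p.V600E"
        )

    @pytest.mark.parametrize(
        "gene,change,field",
        [("", "V600E", "gene"), ("  ", "V600E", "gene"),
         ("BRAF", "", "protein_change"), ("BRAF", "V600 E", "protein_change")],
    )
    def test_rejects_malformed_input_naming_field(self, gene, change, field):
        with pytest.raises(ValueError, match=field):
            normalize_variant_key(gene, change)


class TestParseAlterationLabel:
    def test_comma_joined_entry_is_one_nodule_with_two_variants(self):
        alterations, count = parse_alteration_label("TSHR:p.L629F, EZH1:p.Y642F(1)")
        assert count == 1
        assert [str(a) for a in alterations] == ["TSHR:p.L629F", "EZH1:p.Y642F"]

    def test_multiplicity_and_fusion_labels(self):
        alterations, count = parse_alteration_label("SPOP:p.P94R(3)")
        assert count == 3 and str(alterations[0]) == "SPOP:p.P94R"
        alterations, count = parse_alteration_label("PAX8/PPARG(1)")
        assert count == 1 and alterations[0].canonical_id == "PAX8::PPARG"


class TestCanonicalFusionId:
    def test_colloquial_overrides(self):
        assert canonical_fusion_id("CCDC6", "RET").report_name == "RET/PTC1"
        assert canonical_fusion_id("NCOA4", "RET").report_name == "RET/PTC3"

    def test_plain_fusion_alphabetical_report_name(self):
        fid = canonical_fusion_id("PAX8", "PPARG")
        assert fid.report_name == "PAX8/PPARG"
        assert fid.name_5p3p == "PAX8/PPARG"

    def test_5p3p_order_preserved_in_matching_name(self):
        fid = canonical_fusion_id("STRN", "ALK")
        assert fid.name_5p3p == "STRN/ALK"
        assert fid.report_name == "ALK/STRN"
        # reverse orientation is a distinct canonical identity
        assert fid.canonical_id != canonical_fusion_id("ALK", "STRN").canonical_id

    def test_deterministic_and_idempotent(self):
        fid = canonical_fusion_id("eml4", "alk")
        again = canonical_fusion_id(fid.partner5, fid.partner3)
        assert fid == again

    def test_identical_partners_rejected(self):
        with pytest.raises(ValueError):
            canonical_fusion_id("RET", "RET")


class TestCallInvariants:
    def test_vaf_bounds(self):
        with pytest.raises(ValueError, match="vaf"):
            VariantCall("S1", normalize_variant_key("BRAF", "V600E"), 1.2,
                        None, None, Platform.DNA_PANEL)

    def test_vaf_depth_consistency(self):
        key = normalize_variant_key("BRAF", "V600E")
        with pytest.raises(ValueError, match="inconsistent"):
            VariantCall("S1", key, 0.50, 30, 100, Platform.DNA_PANEL)
        # within the 0.005 rounding tolerance
        VariantCall("S1", key, 0.304, 30, 100, Platform.DNA_PANEL)

    def test_alt_depth_cannot_exceed_total(self):
        key = normalize_variant_key("BRAF", "V600E")
        with pytest.raises(ValueError, match="exceeds"):
            VariantCall("S1", key, 1.0, 101, 100, Platform.DNA_PANEL)

    def test_duplicate_records_collapse_to_max_depth(self, caplog):
        key = normalize_variant_key("BRAF", "V600E")
        shallow = VariantCall("S1", key, 0.3, 30, 100, Platform.DNA_PANEL)
        deep = VariantCall("S1", key, 0.25, 125, 500, Platform.DNA_PANEL)
        with caplog.at_level("WARNING"):
            cs = CallSet(platform=Platform.DNA_PANEL, variant_calls=[shallow, deep])
        assert cs.variant_calls == [deep]
        assert "duplicate" in caplog.text


class TestTsvRoundTrip:
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["S1", "S2", "S3"]),
                st.sampled_from(["BRAF", "NRAS", "TSHR"]),
                st.sampled_from(["V600E", "Q61R", "M453T"]),
                st.integers(min_value=1, max_value=1000),
                st.integers(min_value=0, max_value=1000),
            ),
            max_size=10,
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_variant_tsv_round_trip_is_lossless(self, tmp_path_factory, data):
        calls = []
        seen = set()
        for sample, gene, change, total, alt_raw in data:
            key = normalize_variant_key(gene, change)
            if (sample, key) in seen:
                continue
            seen.add((sample, key))
            alt = min(alt_raw, total)
            calls.append(
                VariantCall(sample, key, alt / total, alt, total, Platform.DNA_PANEL)
            )
        path = tmp_path_factory.mktemp("tsv") / "v.tsv"
        write_variant_tsv(calls, path)
        back = read_variant_tsv(path)
        assert back == calls

    def test_fusion_and_metadata_round_trip(self, tmp_path):
        fusions = [
            FusionCall("S1", "CCDC6", "RET", 25, 30000, Platform.WTS_RNASEQ),
            FusionCall("S2", "PAX8", "PPARG", 40, 50000, Platform.RNA_PANEL),
        ]
        write_fusion_tsv(fusions, tmp_path / "f.tsv")
        assert read_fusion_tsv(tmp_path / "f.tsv") == fusions
        meta = [
            SampleRecord("S1", "III", "suspicious", "PTC"),
            SampleRecord("S2", "IV", "benign", "FA"),
        ]
        write_metadata_tsv(meta, tmp_path / "m.tsv")
        assert read_metadata_tsv(tmp_path / "m.tsv") == meta

    def test_out_of_range_vaf_names_the_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "sample_id\tgene\tprotein_change\tvaf\talt_depth\ttotal_depth\tplatform\n"
            "S1\tBRAF\tV600E\t0.3\t30\t100\tDNA_PANEL\n"
            "S2\tNRAS\tQ61R\t1.2\t\t\tDNA_PANEL\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_variant_tsv(p)


class TestVcf:
    def test_reads_af_dp_and_identity_fields(self, tmp_path):
        p = tmp_path / "s.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
            '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">\n'
            '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            "##contig=<ID=7>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE7\n"
            "7\t140453136\t.\tA\tT\t.\tPASS\tGENE=BRAF;PCHANGE=V600E\tAF:DP\t0.32:500\n"
        )
        calls = read_vcf(p, Platform.DNA_PANEL)
        (call,) = calls
        assert call.sample_id == "SAMPLE7"
        assert str(call.key) == "BRAF:p.V600E"
        assert call.vaf == pytest.approx(0.32)
        assert call.total_depth == 500

    def test_read_callset_dispatch(self, tmp_path):
        calls = [make_variant_call(platform=Platform.DNA_PANEL)]
        write_variant_tsv(calls, tmp_path / "v.tsv")
        cs = read_callset(tmp_path / "v.tsv", "tsv", Platform.DNA_PANEL)
        assert cs.variant_calls == calls


class TestDnaVafThreshold:
    def test_retention_and_removal(self):
        keep = make_variant_call(sample="A", vaf=0.32, platform=Platform.DNA_PANEL)
        drop = make_variant_call(sample="B", vaf=0.04, platform=Platform.DNA_PANEL)
        cs = CallSet(platform=Platform.DNA_PANEL, variant_calls=[keep, drop])
        out = apply_dna_vaf_threshold(cs, 0.05)
        assert out.variant_calls == [keep]

    def test_non_dna_platform_rejected(self):
        cs = CallSet(platform=Platform.WTS_RNASEQ,
                     variant_calls=[make_variant_call()])
        with pytest.raises(ValueError, match="DNA_PANEL"):
            apply_dna_vaf_threshold(cs, 0.05)

    def test_stricter_cutoff_yields_subset(self, rng):
        for _ in range(20):
            cs = random_variant_callset(rng, platform=Platform.DNA_PANEL)
            loose = apply_dna_vaf_threshold(cs, 0.05).variant_events()
            strict = apply_dna_vaf_threshold(cs, 0.20).variant_events()
            assert strict <= loose


def test_histology_grouping_places_ump_with_benign():
    assert histology_class("FT-UMP") == "benign"
    assert histology_class("WDT-UMP") == "benign"
    assert histology_class("FV-PTC") == "malignant"
    assert histology_class("PDTC") == "malignant"
    assert histology_class("something-else") == "unknown"
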