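"""Variant record parsing, quality filtering and the sequencing-error test."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbtrace.variant_model import (
    HET, HOM, INDEL, SNP, INTERGENIC, MISSENSE, OTHER_GENIC, SYNONYMOUS,
    classify_coding_effect, classify_variant_type, make_variant, parse_zygosity,
    passes_quality_filter, read_gene_intervals, read_vcf, sequencing_error_tail,
    write_vcf,
)

from conftest import variant


class TestZygosityParsing:
    @pytest.mark.parametrize("gt,expected", [
        ("0/1", HET), ("1/0", HET), ("1/1", HOM),
        ("0|1", HET), ("1|1", HOM), ("./.", None), ("0/0", None),
    ])
    def test_genotype_codes(self, gt, expected):
        assert parse_zygosity(gt) == expected

    def test_multiallelic_resolved_against_alt_index(self):
        assert parse_zygosity("1/2", n_alts=2, alt_index=2) == HET
        assert parse_zygosity("2/2", n_alts=2, alt_index=2) == HOM
        assert parse_zygosity("1/1", n_alts=2, alt_index=2) is None

    def test_allele_index_beyond_alts_rejected(self):
        with pytest.raises(ValueError, match="allele 2"):
            parse_zygosity("0/2", n_alts=1)

    def test_non_diploid_rejected(self):
        with pytest.raises(ValueError):
            parse_zygosity("0/1/1")


class TestVariantType:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "T", SNP), ("A", "AT", INDEL), ("ACG", "A", INDEL), ("AT", "GC", INDEL),
    ])
    def test_classification(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="not a variant"):
            classify_variant_type("A", "A")


class TestQualityFilter:
    def test_typical_site_passes(self):
        assert passes_quality_filter(variant(depth=20, alt_reads=10))

    @pytest.mark.parametrize("depth,alt", [(10, 5), (50, 3), (10, 3), (5, 4)])
    def test_boundaries_are_strict(self, depth, alt):
        assert not passes_quality_filter(variant(depth=depth, alt_reads=min(alt, depth)))

    def test_unknown_counts_fail(self):
        rec = variant()._replace(depth=None, alt_reads=None)
        assert not passes_quality_filter(rec)

    @given(
        depths=st.lists(st.integers(0, 60), min_size=1, max_size=50),
        min_depth=st.integers(0, 30), min_alt=st.integers(0, 15),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_thresholds(self, depths, min_depth, min_alt):
        """Raising either threshold never lets more records through."""
        recs = [variant(pos=i + 1, depth=d, alt_reads=d // 2)
                for i, d in enumerate(depths)]
        n = sum(passes_quality_filter(r, min_depth, min_alt) for r in recs)
        n_stricter_depth = sum(passes_quality_filter(r, min_depth + 5, min_alt) for r in recs)
        n_stricter_alt = sum(passes_quality_filter(r, min_depth, min_alt + 5) for r in recs)
        assert n_stricter_depth <= n
        assert n_stricter_alt <= n


def binomial_upper_tail(depth: int, alt: int, rate: float) -> float:
    """Brute-force tail: explicit summation of the binomial pmf."""
    return sum(
        math.comb(depth, k) * rate**k * (1 - rate) ** (depth - k)
        for k in range(alt, depth + 1)
    )


class TestSequencingErrorTail:
    def test_zero_alt_covers_whole_space(self):
        assert sequencing_error_tail(20, 0, 0.3) == 1.0

    def test_two_of_two_at_half(self):
        assert sequencing_error_tail(2, 2, 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_matches_pmf_summation_at_study_depth(self):
        """The depth-20/alt-10 site at 1% error, against explicit summation."""
        expected = binomial_upper_tail(20, 10, 0.01)
        assert sequencing_error_tail(20, 10, 0.01) == pytest.approx(expected, rel=1e-12)
        assert expected < 1e-12  # vanishingly unlikely to be an artefact

    @given(depth=st.integers(1, 50), rate=st.floats(0.001, 0.5))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_and_monotonicity(self, depth, rate):
        tails = [sequencing_error_tail(depth, k, rate) for k in range(depth + 1)]
        for k, t in enumerate(tails):
            assert t == pytest.approx(binomial_upper_tail(depth, k, rate), abs=1e-12)
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_invalid_error_rate_rejected(self):
        with pytest.raises(ValueError):
            sequencing_error_tail(20, 10, 0.0)


class TestEffectClassification:
    @pytest.mark.parametrize("ann,expected", [
        ("T|missense_variant|MODERATE|BMP7|g1|transcript|t1", MISSENSE),
        ("T|synonymous_variant|LOW|X|", SYNONYMOUS),
        ("T|intergenic_region|MODIFIER|", INTERGENIC),
        ("T|intron_variant|MODIFIER|", OTHER_GENIC),
        ("", INTERGENIC),
        (None, INTERGENIC),
        ("T|stop_gained&splice_region_variant|HIGH|", OTHER_GENIC),
    ])
    def test_term_mapping(self, ann, expected):
        assert classify_coding_effect(ann) == expected

    def test_first_annotation_wins(self):
        ann = "T|missense_variant|MODERATE|A|,T|synonymous_variant|LOW|B|"
        assert classify_coding_effect(ann) == MISSENSE


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=ANN,Number=.,Type=String,Description="ann">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tH
"""


def write_text_vcf(tmp_path, body, name="x.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestVcfReader:
    def test_simple_het_snp(self, tmp_path):
        path = write_text_vcf(tmp_path, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP:AD\t0/1:20:10,10\n")
        (rec,) = read_vcf(path, "H")
        assert rec.chrom == "chr1" and rec.pos == 100
        assert rec.zygosity == HET and rec.depth == 20 and rec.alt_reads == 10
        assert rec.vtype == SNP

    def test_multiallelic_row_decomposed(self, tmp_path):
        path = write_text_vcf(tmp_path, "chr1\t100\t.\tA\tT,G\t.\t.\t.\tGT:DP:AD\t1/2:30:10,12,8\n")
        recs = read_vcf(path, "H")
        assert [(r.chrom, r.pos, r.alt) for r in recs] == [("chr1", 100, "T"), ("chr1", 100, "G")]
        assert all(r.zygosity == HET for r in recs)
        assert [r.alt_reads for r in recs] == [12, 8]

    def test_missing_ad_yields_unknown_alt_reads(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP\t0/1:20\n"
            "chr1\t200\t.\tC\tG\t.\t.\t.\tGT:DP\t1/1:30\n"
            "chr1\t300\t.\tG\tA\t.\t.\t.\tGT:DP\t0/1:25\n"
        )
        path = write_text_vcf(tmp_path, body)
        recs = read_vcf(path, "H")
        assert len(recs) == 3
        assert all(r.alt_reads is None for r in recs)
        assert not any(passes_quality_filter(r) for r in recs)

    def test_missing_genotype_skipped(self, tmp_path):
        body = ("chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP:AD\t./.:20:10,10\n"
                "chr1\t200\t.\tC\tG\t.\t.\t.\tGT:DP:AD\t0/1:20:10,10\n")
        path = write_text_vcf(tmp_path, body)
        assert [r.pos for r in read_vcf(path, "H")] == [200]

    def test_unknown_sample_lists_available(self, tmp_path):
        path = write_text_vcf(tmp_path, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="available samples.*H"):
            read_vcf(path, "NOSUCH")

    def test_round_trip(self, tmp_path):
        original = [
            variant("chr1", 100, "A", "T", HET, 20, 10, MISSENSE),
            variant("chr1", 250, "C", "CAT", HET, 18, 9, OTHER_GENIC),
            variant("chr2", 50, "GG", "G", HOM, 30, 29, INTERGENIC),
            variant("chr2", 99, "T", "C", HOM, 25, 25, SYNONYMOUS),
        ]
        path = str(tmp_path / "rt.vcf")
        write_vcf(original, path, "H")
        assert read_vcf(path, "H") == original


class TestGeneIntervals:
    def test_gtf_reading_and_candidate_flag(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr17\tsrc\tgene\t100\t500\t.\t+\t.\tgene_id "BMP7";\n'
            'chr1\tsrc\tgene\t10\t90\t.\t-\t.\tgene_id "OTHER1";\n'
        )
        genes = {g.gene_id: g for g in read_gene_intervals(str(gtf))}
        assert genes["BMP7"].is_candidate and genes["BMP7"].start == 100
        assert not genes["OTHER1"].is_candidate

    def test_inverted_span_rejected(self):
        from limbtrace.variant_model import GeneInterval

        with pytest.raises(ValueError):
            GeneInterval("X", "chr1", 10, 5)
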