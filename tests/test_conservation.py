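"""Site mapping, conservation contrasts, clade codon patterns, branch rates."""

import numpy as np
import pytest

from limbtrace.conservation import (
    CLADE_CONSERVED, CONSERVED_EVERYWHERE, GENIC, INTERGENIC_NEAR, OTHER_PATTERN,
    UNASSIGNED, VARIABLE_EVERYWHERE, MapBlock, SiteMap, assign_to_genes,
    clade_branch_rates, clade_codon_pattern, conserved_at,
    conserved_fraction_contrast,
)
from limbtrace.synthetic import simulate_clade_columns
from limbtrace.variant_model import GeneInterval

from conftest import variant
from test_trio_classify import chi_square_by_hand


class TestSiteMap:
    def test_plus_strand_offset(self):
        m = SiteMap([MapBlock("chr1", 100, "chrB1", 500, 50, "+")])
        assert m.map_site("chr1", 110) == ("chrB1", 510)

    def test_outside_every_block_is_unmapped(self):
        m = SiteMap([MapBlock("chr1", 100, "chrB1", 500, 50, "+")])
        assert m.map_site("chr1", 99) is None
        assert m.map_site("chr1", 150) is None
        assert m.map_site("chr2", 110) is None

    def test_minus_strand_full_enumeration(self):
        """Every position of a 5 bp minus-strand block, by hand."""
        m = SiteMap([MapBlock("chrA", 11, "chrB", 101, 5, "-")])
        expected = {11: 105, 12: 104, 13: 103, 14: 102, 15: 101}
        for src, tgt in expected.items():
            assert m.map_site("chrA", src) == ("chrB", tgt)

    def test_injective_and_round_trips_through_inverse(self):
        blocks = [
            MapBlock("chr1", 100, "t1", 900, 40, "+"),
            MapBlock("chr1", 200, "t2", 50, 25, "-"),
            MapBlock("chr2", 10, "t1", 10, 8, "+"),
        ]
        m, inv = SiteMap(blocks), SiteMap(blocks).inverted()
        seen = set()
        for b in blocks:
            for pos in range(b.source_start, b.source_start + b.length):
                tgt = m.map_site(b.source_chrom, pos)
                assert tgt is not None and tgt not in seen
                seen.add(tgt)
                assert inv.map_site(*tgt) == (b.source_chrom, pos)

    def test_overlapping_blocks_rejected_with_index(self):
        with pytest.raises(ValueError, match="block 1"):
            SiteMap([MapBlock("chr1", 100, "t", 1, 50, "+"),
                     MapBlock("chr1", 120, "t", 99, 10, "+")])

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chr1\t100\tchrB1\t500\t50\t+\nchr2\t5\tchrB2\t1\t10\t-\n")
        m = SiteMap.from_tsv(str(p))
        assert m.map_site("chr1", 100) == ("chrB1", 500)
        assert m.map_site("chr2", 5) == ("chrB2", 10)

    def test_malformed_tsv_names_block(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t100\tchrB1\t500\t50\t+\nchr1\t300\tchrB1\t900\t-5\t+\n")
        with pytest.raises(ValueError, match="block 1"):
            SiteMap.from_tsv(str(p))


class TestConservedAt:
    @pytest.mark.parametrize("a,b,expected", [
        ("A", "A", True), ("A", "G", False), ("a", "A", True),
        ("A", "N", None), ("R", "A", None),
    ])
    def test_base_identity_rule(self, a, b, expected):
        assert conserved_at(a, b) is expected


class TestConservedFractionContrast:
    def test_equal_fractions_are_null(self):
        res = conserved_fraction_contrast([True] * 5 + [False] * 5,
                                          [True] * 8 + [False] * 8)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_oracle(self):
        cand = [True] * 80 + [False] * 20
        non = [True] * 50 + [False] * 50
        res = conserved_fraction_contrast(cand, non)
        assert res.chi_square == pytest.approx(
            chi_square_by_hand([[80, 20], [50, 50]]), rel=1e-12)

    def test_ambiguous_sites_excluded_and_counted(self):
        res = conserved_fraction_contrast([True, None, False], [True, False])
        assert res.n_excluded == 1 and res.table.sum() == 4

    def test_seeded_candidate_excess_detected(self, rng):
        """Sites on candidate genes seeded more conserved come out with a
        higher conserved fraction and p < 0.05."""
        cand = [bool(rng.random() < 0.9) for _ in range(300)]
        non = [bool(rng.random() < 0.6) for _ in range(300)]
        res = conserved_fraction_contrast(cand, non)
        assert res.fractions[0][0] > res.fractions[1][0]
        assert res.p_value < 0.05


class TestAssignToGenes:
    GENES = [
        GeneInterval("BMP7", "chr17", 1000, 2000, is_candidate=True),
        GeneInterval("NEAR", "chr17", 2100, 2500),
    ]

    def test_inside_gene_is_genic(self):
        (a,) = assign_to_genes([variant("chr17", 1500)], self.GENES)
        assert a.status == GENIC and a.gene_ids == ("BMP7",)

    def test_one_bp_past_the_end_is_intergenic_but_associated(self):
        (a,) = assign_to_genes([variant("chr17", 2001)], self.GENES, window=500)
        assert a.status == INTERGENIC_NEAR and "BMP7" in a.gene_ids

    def test_beyond_the_window_is_unassigned(self):
        (a,) = assign_to_genes([variant("chr17", 900_000)], self.GENES, window=500)
        assert a.status == UNASSIGNED and a.gene_ids == ()

    def test_overlapping_genes_flagged_ambiguous(self):
        genes = self.GENES + [GeneInterval("OVL", "chr17", 1500, 2200)]
        (a,) = assign_to_genes([variant("chr17", 1600)], genes)
        assert a.status == GENIC and a.gene_ids == ("BMP7", "OVL") and a.ambiguous


MAMMALS = {f"m{i}": "mammal" for i in range(5)}
FISHES = {f"f{i}": "fish" for i in range(5)}
LABELS = {**MAMMALS, **FISHES}


class TestCladeCodonPattern:
    def test_universal_codon_is_conserved_everywhere(self):
        col = {sp: "CGG" for sp in LABELS}
        assert clade_codon_pattern(col, LABELS).pattern == CONSERVED_EVERYWHERE

    def test_mammal_only_conservation(self):
        """All mammals CGG, lower vertebrates mixed: the arginine-to-proline
        site pattern - conserved in mammals, variable elsewhere."""
        col = {**{sp: "CGG" for sp in MAMMALS},
               **{f"f{i}": c for i, c in enumerate(["CCG", "ACG", "GGG", "TCG", "CTG"])}}
        prof = clade_codon_pattern(col, LABELS, focal_clade="mammal")
        assert prof.pattern == CLADE_CONSERVED
        assert prof.clades["mammal"].majority_codon == "CGG"
        assert prof.clades["mammal"].identity == 1.0

    def test_every_species_different_is_variable_everywhere(self):
        codons = ["AAA", "AAC", "AAG", "ACA", "ACC", "ACG", "ATA", "ATC", "CTT", "CTC"]
        col = {sp: c for sp, c in zip(LABELS, codons)}
        assert clade_codon_pattern(col, LABELS, identity_threshold=0.9
                                   ).pattern == VARIABLE_EVERYWHERE

    def test_nonfocal_conservation_is_other(self):
        col = {**{f"m{i}": c for i, c in enumerate(["CCG", "ACG", "GGG", "TCG", "CTG"])},
               **{sp: "CGG" for sp in FISHES}}
        assert clade_codon_pattern(col, LABELS).pattern == OTHER_PATTERN

    def test_invariant_to_species_order(self):
        col = {**{sp: "CGG" for sp in MAMMALS},
               **{f"f{i}": c for i, c in enumerate(["CCG", "ACG", "GGG", "TCG", "CTG"])}}
        shuffled = dict(reversed(list(col.items())))
        a = clade_codon_pattern(col, LABELS)
        b = clade_codon_pattern(shuffled, LABELS)
        assert a.pattern == b.pattern and a.clades == b.clades

    def test_unlabelled_species_rejected(self):
        with pytest.raises(ValueError, match="no clade label"):
            clade_codon_pattern({"mystery": "AAA"}, LABELS)

    def test_simulated_columns_mostly_classified_mammal_conserved(self):
        """Columns generated at 2% mammal / 50% non-mammal substitution
        probability classify clade_conserved >= 80% of the time."""
        rng = np.random.default_rng(2024)
        columns, labels = simulate_clade_columns(100, rng)
        patterns = [clade_codon_pattern(c, labels, focal_clade="mammal").pattern
                    for c in columns]
        assert patterns.count(CLADE_CONSERVED) >= 80


class TestCladeAlignmentReader:
    def test_columns_and_labels_parsed(self, tmp_path):
        from limbtrace.conservation import read_clade_alignment

        fa = tmp_path / "aln.fa"
        fa.write_text(">human clade=mammal\nCGGAAA\n>pig clade=mammal\nCGGAAC\n"
                      ">seaturtle clade=reptile\nCCGAAA\n")
        columns, labels = read_clade_alignment(str(fa))
        assert labels == {"human": "mammal", "pig": "mammal", "seaturtle": "reptile"}
        assert columns[0] == {"human": "CGG", "pig": "CGG", "seaturtle": "CCG"}
        assert columns[1]["pig"] == "AAC"

    def test_missing_clade_tag_rejected(self, tmp_path):
        from limbtrace.conservation import read_clade_alignment

        fa = tmp_path / "aln.fa"
        fa.write_text(">human\nCGG\n")
        with pytest.raises(ValueError, match="clade"):
            read_clade_alignment(str(fa))


class TestCladeBranchRates:
    NEWICK = "((A:1,B:2):1,(C:3,D:4):2);"
    LABELS = {"A": "mammal", "B": "mammal", "C": "fish", "D": "fish"}

    def test_path_sums_match_hand_computation(self):
        df = clade_branch_rates(self.NEWICK, self.LABELS)
        # root-to-tip: A=2, B=3 -> mammal mean 2.5; C=5, D=6 -> fish mean 5.5
        assert df.loc["mammal", "mean_root_to_tip"] == pytest.approx(2.5)
        assert df.loc["fish", "mean_root_to_tip"] == pytest.approx(5.5)
        assert df.loc["fish", "ratio_to_reference"] == pytest.approx(2.2)

    def test_ultrametric_tree_gives_equal_means(self):
        newick = "((A:1,B:1):1,(C:1,D:1):1);"
        df = clade_branch_rates(newick, self.LABELS)
        assert df["mean_root_to_tip"].nunique() == 1
        assert (df["ratio_to_reference"] == 1).all()

    def test_scaling_branch_lengths_scales_means_not_ratios(self):
        doubled = "((A:2,B:4):2,(C:6,D:8):4);"
        a = clade_branch_rates(self.NEWICK, self.LABELS)
        b = clade_branch_rates(doubled, self.LABELS)
        assert np.allclose(b["mean_root_to_tip"], 2 * a["mean_root_to_tip"])
        assert np.allclose(b["ratio_to_reference"], a["ratio_to_reference"])

    def test_missing_branch_length_reported(self):
        with pytest.raises(ValueError, match="branch length"):
            clade_branch_rates("((A:1,B),(C:3,D:4):2);", self.LABELS)

    def test_unlabelled_leaf_rejected(self):
        with pytest.raises(ValueError, match="clade label"):
            clade_branch_rates(self.NEWICK, {"A": "mammal"})
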