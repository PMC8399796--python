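"""Partition the affected offspring's variants against mother and sibling.

A variant is *proband-specific* when it appears in the affected individual
(H) but in neither the mother (M) nor the sequenced sibling (S).  Because
the father was never sequenced, specific variants are the union of
paternal-haplotype differences and de novo mutations; downstream modules
disentangle the two statistically.  This module also runs the 2x2 category
contrasts (zygosity, SNP/Indel, missense/synonymous) between the specific
and non-specific subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .variant_model import MISSENSE, SNP, SYNONYMOUS, GeneInterval, VariantRecord

MATCH_MODES = ("allele", "position")


@dataclass
class TrioPartition:
    """Filtered proband variants split into specific / non-specific subsets."""

    specific: list[VariantRecord]
    nonspecific: list[VariantRecord]
    match_mode: str = "allele"

    @property
    def totals(self) -> dict[str, int]:
        return {
            "specific": len(self.specific),
            "nonspecific": len(self.nonspecific),
            "total": len(self.specific) + len(self.nonspecific),
        }

    @property
    def specific_percent(self) -> float:
        """Share of proband variants that are specific, as a percentage (1 dp)."""
        return specific_percent(len(self.specific), self.totals["total"])


def specific_percent(n_specific: int, n_total: int) -> float:
    """Percentage of specific variants among all proband variants, to 1 decimal."""
    if n_total <= 0:
        raise ValueError("total variant count must be positive")
    return round(100.0 * n_specific / n_total, 1)


def _chrom_style(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else "chr" + name


def _check_chromosome_names(
    proband_chroms: set[str], other_chroms: set[str], roles: str
) -> None:
    """Catch naming-convention mismatches ('chr1' vs '1') across files."""
    offending = sorted(
        c for c in proband_chroms
        if c not in other_chroms and _chrom_style(c) in other_chroms
    )
    if offending:
        raise ValueError(
            f"chromosome naming mismatch between proband and {roles}: "
            f"{offending} present under a different convention"
        )


def partition_specific(
    proband_records: Sequence[VariantRecord],
    mother_records: Sequence[VariantRecord],
    sibling_records: Sequence[VariantRecord],
    match_mode: str = "allele",
) -> TrioPartition:
    """Split proband variants by presence in the mother or sibling.

    A proband record is specific iff no record in the mother *or* the
    sibling matches it under ``match_mode`` ('allele' keys on
    chrom/pos/ref/alt, 'position' on chrom/pos).  Presence in a relative
    counts regardless of that relative's zygosity.
    """
    if match_mode not in MATCH_MODES:
        raise ValueError(f"match_mode must be one of {MATCH_MODES}, got {match_mode!r}")
    if not proband_records:
        raise ValueError("proband record set is empty")
    other = mother_records, sibling_records
    proband_chroms = {r.chrom for r in proband_records}
    other_chroms = {r.chrom for recs in other for r in recs}
    _check_chromosome_names(proband_chroms, other_chroms, "mother/sibling")
    seen = {r.key(match_mode) for recs in other for r in recs}
    specific: list[VariantRecord] = []
    nonspecific: list[VariantRecord] = []
    for r in proband_records:
        (nonspecific if r.key(match_mode) in seen else specific).append(r)
    return TrioPartition(specific, nonspecific, match_mode)


@dataclass
class ContingencyResult:
    """A 2x2 contingency table with its Pearson chi-square test.

    ``fractions`` are row-normalised proportions; ``degenerate`` flags a
    zero row or column margin, where the test statistic is undefined.
    """

    table: np.ndarray
    chi_square: float
    p_value: float
    fractions: np.ndarray
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    n_excluded: int = 0
    degenerate: bool = False


def contingency_test(table: np.ndarray, correction: bool = False) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df) on a 2x2 table; Yates correction optional.

    Returns ``(statistic, p_value, degenerate)``; a zero row/column margin
    yields NaNs with the degenerate flag set.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan"), True
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p), False


def category_contrast(
    partition: TrioPartition,
    labeler: Callable[[VariantRecord], str | None],
    correction: bool = False,
    categories: tuple[str, str] | None = None,
) -> ContingencyResult:
    """2x2 contrast of a binary record label between the two subsets.

    ``labeler`` maps a record to one of two category values or ``None``
    (excluded and counted).  Rows are (specific, nonspecific); columns are
    the two categories, sorted unless given explicitly.
    """
    counts: dict[tuple[int, str], int] = {}
    labels: set[str] = set()
    n_excluded = 0
    for row_i, recs in enumerate((partition.specific, partition.nonspecific)):
        for r in recs:
            lab = labeler(r)
            if lab is None:
                n_excluded += 1
                continue
            labels.add(lab)
            counts[(row_i, lab)] = counts.get((row_i, lab), 0) + 1
    if categories is None:
        if len(labels) > 2:
            raise ValueError(f"labeler produced more than two categories: {sorted(labels)}")
        categories = tuple(sorted(labels)) if len(labels) == 2 else tuple(sorted(labels)) + ("",)
        if len(categories) < 2:
            categories = (categories + ("", ""))[:2]
    table = np.array(
        [[counts.get((i, c), 0) for c in categories] for i in range(2)], dtype=float
    )
    chi2, p, degenerate = contingency_test(table, correction=correction)
    row_sums = table.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        fractions = np.where(row_sums > 0, table / row_sums, np.nan)
    return ContingencyResult(
        table, chi2, p, fractions, ("specific", "nonspecific"),
        (categories[0], categories[1]), n_excluded, degenerate,
    )


def zygosity_label(record: VariantRecord) -> str | None:
    """Heterozygous/homozygous label (None when zygosity is unresolved)."""
    return record.zygosity


def variant_type_label(record: VariantRecord) -> str:
    """SNP/Indel label."""
    return record.vtype


def coding_label(record: VariantRecord) -> str | None:
    """missense/synonymous label for coding SNPs; everything else excluded."""
    if record.vtype == SNP and record.effect in (MISSENSE, SYNONYMOUS):
        return record.effect
    return None


def _gene_trees(gene_intervals: Iterable[GeneInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gene_intervals:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    return trees


def gene_specific_sets(
    partition: TrioPartition, gene_intervals: Sequence[GeneInterval]
) -> tuple[set[str], set[str]]:
    """Split variant-bearing genes into specific and non-specific genes.

    A gene is specific iff at least one specific record overlaps it and no
    non-specific record does; genes carrying any variant but failing that
    are non-specific; genes with no variants appear in neither set.
    """
    trees = _gene_trees(gene_intervals)
    hit_specific: set[str] = set()
    hit_nonspecific: set[str] = set()
    for recs, bucket in ((partition.specific, hit_specific),
                         (partition.nonspecific, hit_nonspecific)):
        for r in recs:
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            for iv in tree.at(r.pos):
                bucket.add(iv.data)
    return hit_specific - hit_nonspecific, hit_nonspecific
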