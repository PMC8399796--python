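"""Chromosome-level enrichment of proband-specific variants.

Under Mendelian independent assortment each offspring inherits either
paternal homolog of a chromosome with probability 0.5.  Chromosomes whose
paternal homolog went to the affected offspring but not to the sequenced
sibling carry an excess of proband-specific variants; the enrichment
statistic F_Hi / F_Ni (a chromosome's share of specific variants over its
share of non-specific variants) localises them, with a per-chromosome
2x2 chi-square for significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan
from typing import Mapping, Sequence

import numpy as np

from .trio_classify import TrioPartition, contingency_test

#: pig karyotype used throughout: autosomes 1-18 plus X
PIG_CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 19)) + ("chrX",)


@dataclass
class ChromosomeEnrichment:
    """Per-chromosome specific/non-specific counts and enrichment."""

    chrom: str
    h_count: int          # specific variants on this chromosome
    n_count: int          # non-specific variants on this chromosome
    f_h: float            # chromosome's share of all specific variants
    f_n: float            # chromosome's share of all non-specific variants
    enrichment: float     # f_h / f_n; NaN when f_n == 0 (flagged undefined)
    p_value: float
    chi_square: float = float("nan")

    @property
    def defined(self) -> bool:
        return not isnan(self.enrichment)


def _counts_by_chrom(
    partition: TrioPartition, chromosomes: Sequence[str]
) -> dict[str, tuple[int, int]]:
    counts = {c: [0, 0] for c in chromosomes}
    for i, recs in enumerate((partition.specific, partition.nonspecific)):
        for r in recs:
            if r.chrom not in counts:
                raise ValueError(
                    f"chromosome {r.chrom!r} in partition but not in chromosome list"
                )
            counts[r.chrom][i] += 1
    return {c: (h, n) for c, (h, n) in counts.items()}


def chromosome_chi_square(counts: Mapping[str, tuple[int, int]], chrom: str) -> float:
    """Chi-square p-value contrasting one chromosome against all others.

    The 2x2 table is (target chromosome vs the rest) x (specific vs
    non-specific), 1 df, no continuity correction.  A zero margin yields NaN.
    """
    if chrom not in counts:
        raise ValueError(f"chromosome {chrom!r} not in counts")
    if len(counts) < 2:
        raise ValueError("need counts for at least two chromosomes")
    return _chi_square_detail(counts, chrom)[1]


def _chi_square_detail(counts: Mapping[str, tuple[int, int]], chrom: str) -> tuple[float, float]:
    h_i, n_i = counts[chrom]
    h_rest = sum(h for c, (h, _) in counts.items() if c != chrom)
    n_rest = sum(n for c, (_, n) in counts.items() if c != chrom)
    chi2, p, degenerate = contingency_test(
        np.array([[h_i, n_i], [h_rest, n_rest]], dtype=float)
    )
    nan = float("nan")
    return (nan, nan) if degenerate else (chi2, p)


def chromosome_enrichment(
    partition: TrioPartition,
    chromosomes: Sequence[str] = PIG_CHROMOSOMES,
) -> list[ChromosomeEnrichment]:
    """Per-chromosome enrichment F_Hi / F_Ni with chi-square p-values.

    Frequencies are normalised over ``chromosomes`` only; every chromosome
    present in the partition must be listed.  Chromosomes with no
    non-specific variants get an undefined (NaN) enrichment.
    """
    if not partition.specific or not partition.nonspecific:
        raise ValueError("both specific and non-specific sets must be non-empty")
    counts = _counts_by_chrom(partition, chromosomes)
    h_total = sum(h for h, _ in counts.values())
    n_total = sum(n for _, n in counts.values())
    out = []
    for c in chromosomes:
        h, n = counts[c]
        f_h = h / h_total
        f_n = n / n_total
        enrichment = f_h / f_n if f_n > 0 else float("nan")
        chi2, p = _chi_square_detail(counts, c)
        out.append(ChromosomeEnrichment(c, h, n, f_h, f_n, enrichment, p, chi2))
    return out


def infer_transmitted(
    enrichments: Sequence[ChromosomeEnrichment],
    alpha: float = 0.05,
    min_enrichment: float = 1.0,
    bonferroni: bool = False,
) -> list[str]:
    """Chromosomes called as differentially transmitted paternal homologs.

    A chromosome is called when its enrichment exceeds ``min_enrichment``
    AND its chi-square p-value is below ``alpha`` (optionally Bonferroni-
    corrected across the tested chromosomes).  Sorted by enrichment,
    descending.
    """
    threshold = alpha / len(enrichments) if bonferroni else alpha
    called = [
        e for e in enrichments
        if e.defined and e.enrichment > min_enrichment
        and not isnan(e.p_value) and e.p_value < threshold
    ]
    return [e.chrom for e in sorted(called, key=lambda e: -e.enrichment)]
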