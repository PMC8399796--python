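"""Orthologous-site conservation and clade-partitioned codon patterns.

Candidate-gene prioritisation rests on where mutations fall: a variant at a
position whose reference base is shared with a second species (pig vs
human) hits a conserved, hence likely constrained, site.  At codon
resolution, alignment columns that are near-invariant within mammals but
variable in lower vertebrates mark residues whose constraint is
mammal-specific - the pattern shown by the proband's Arg->Pro change in
BMP7.  Tree-wide, the same signal appears as short root-to-tip path
lengths within the constrained clade.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from .trio_classify import ContingencyResult, contingency_test
from .variant_model import GeneInterval, VariantRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MapBlock:
    """One colinear block mapping source to target coordinates (1-based)."""

    source_chrom: str
    source_start: int
    target_chrom: str
    target_start: int
    length: int
    strand: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"block length must be >= 1, got {self.length}")
        if self.source_start < 1 or self.target_start < 1:
            raise ValueError("block starts must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class SiteMap:
    """Orthologous-site coordinate map built from non-overlapping blocks.

    A minimal stand-in for chain-based liftover: each block translates a
    contiguous source interval to a target interval, strand-aware.  Blocks
    must not overlap on the source genome.
    """

    def __init__(self, blocks: Sequence[MapBlock]):
        self.blocks = list(blocks)
        self._starts: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[MapBlock]] = {}
        order = sorted(range(len(self.blocks)),
                       key=lambda i: (self.blocks[i].source_chrom, self.blocks[i].source_start))
        prev: MapBlock | None = None
        for i in order:
            b = self.blocks[i]
            if (prev is not None and prev.source_chrom == b.source_chrom
                    and b.source_start <= prev.source_start + prev.length - 1):
                raise ValueError(
                    f"block {i} ({b.source_chrom}:{b.source_start}) overlaps the "
                    f"previous block on the source genome"
                )
            self._by_chrom.setdefault(b.source_chrom, []).append(b)
            self._starts.setdefault(b.source_chrom, []).append(b.source_start)
            prev = b

    @classmethod
    def from_tsv(cls, path: str) -> "SiteMap":
        """Read a block table: source_chrom, source_start, target_chrom,
        target_start, length, strand (tab-separated, 1-based starts)."""
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["source_chrom", "source_start", "target_chrom",
                   "target_start", "length", "strand"],
            dtype={"source_chrom": str, "target_chrom": str},
        )
        blocks = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                blocks.append(MapBlock(row.source_chrom, int(row.source_start),
                                       row.target_chrom, int(row.target_start),
                                       int(row.length), str(row.strand)))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"malformed site map {path}, block {i}: {exc}") from exc
        return cls(blocks)

    def map_site(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Translate a source position; ``None`` when outside every block."""
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        b = self._by_chrom[chrom][i]
        offset = pos - b.source_start
        if offset >= b.length:
            return None
        if b.strand == "+":
            return b.target_chrom, b.target_start + offset
        return b.target_chrom, b.target_start + b.length - 1 - offset

    def inverted(self) -> "SiteMap":
        """Map from target coordinates back to source coordinates."""
        inv = []
        for b in self.blocks:
            inv.append(MapBlock(b.target_chrom, b.target_start,
                                b.source_chrom, b.source_start, b.length, b.strand))
        return SiteMap(inv)


def conserved_at(source_ref_base: str, target_base: str) -> bool | None:
    """True iff the two orthologous bases are identical.

    Ambiguity codes (anything outside ACGT) return ``None``: the site is
    excluded from conservation counts.
    """
    a, b = source_ref_base.upper(), target_base.upper()
    if a not in _VALID_BASES or b not in _VALID_BASES:
        return None
    return a == b


def conserved_fraction_contrast(
    candidate_flags: Iterable[bool | None],
    noncandidate_flags: Iterable[bool | None],
) -> ContingencyResult:
    """2x2 chi-square: (candidate vs non-candidate) x (conserved vs not).

    ``None`` flags (ambiguous bases) are excluded and counted.
    """
    table = np.zeros((2, 2))
    n_excluded = 0
    for row, flags in enumerate((candidate_flags, noncandidate_flags)):
        for f in flags:
            if f is None:
                n_excluded += 1
            else:
                table[row, 0 if f else 1] += 1
    chi2, p, degenerate = contingency_test(table)
    row_sums = table.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        fractions = np.where(row_sums > 0, table / row_sums, np.nan)
    return ContingencyResult(
        table, chi2, p, fractions, ("candidate", "noncandidate"),
        ("conserved", "not_conserved"), n_excluded, degenerate,
    )


GENIC = "genic"
INTERGENIC_NEAR = "intergenic"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GeneAssignment:
    """Gene association for one variant: inside a gene, near one, or neither."""

    gene_ids: tuple[str, ...]
    status: str

    @property
    def ambiguous(self) -> bool:
        return len(self.gene_ids) > 1


def assign_to_genes(
    records: Sequence[VariantRecord],
    gene_intervals: Sequence[GeneInterval],
    window: int = 50_000,
) -> list[GeneAssignment]:
    """Assign each variant to gene bodies or their flanking windows.

    A variant inside a gene span is ``genic`` (all overlapped genes listed;
    overlaps are flagged via :attr:`GeneAssignment.ambiguous`).  A variant
    within ``window`` bp of a span is ``intergenic`` but associated with
    the nearby gene(s); anything else is ``unassigned``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    exact: dict[str, IntervalTree] = {}
    padded: dict[str, IntervalTree] = {}
    for g in gene_intervals:
        exact.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
        padded.setdefault(g.chrom, IntervalTree()).addi(
            max(1, g.start - window), g.end + window + 1, g.gene_id
        )
    out = []
    for r in records:
        hits = sorted(iv.data for iv in exact.get(r.chrom, IntervalTree()).at(r.pos))
        if hits:
            out.append(GeneAssignment(tuple(hits), GENIC))
            continue
        near = sorted(iv.data for iv in padded.get(r.chrom, IntervalTree()).at(r.pos))
        if near:
            out.append(GeneAssignment(tuple(near), INTERGENIC_NEAR))
        else:
            out.append(GeneAssignment((), UNASSIGNED))
    return out


CONSERVED_EVERYWHERE = "conserved_everywhere"
CLADE_CONSERVED = "clade_conserved"
VARIABLE_EVERYWHERE = "variable_everywhere"
OTHER_PATTERN = "other"


@dataclass(frozen=True)
class CladeSummary:
    """Codon identity summary for one clade at one alignment column."""

    n_species: int
    n_distinct: int
    majority_codon: str
    identity: float  # share of species carrying the majority codon


@dataclass
class CladeCodonProfile:
    """Per-clade conservation of one codon column, with its pattern class."""

    column_id: str | int | None
    clades: dict[str, CladeSummary]
    pattern: str
    focal_clade: str


def clade_codon_pattern(
    column: Mapping[str, str],
    clade_labels: Mapping[str, str],
    identity_threshold: float = 0.9,
    focal_clade: str = "mammal",
    column_id: str | int | None = None,
) -> CladeCodonProfile:
    """Classify one codon column by within-clade identity.

    Identity is the share of a clade's species carrying its majority codon
    (ties broken lexicographically, so results are independent of species
    order).  Patterns: ``conserved_everywhere`` when every clade reaches
    the threshold; ``clade_conserved`` when the focal clade does and no
    other clade does; ``variable_everywhere`` when none does; ``other``
    otherwise.  Clades named in ``clade_labels`` but absent from the column
    are excluded (logged).
    """
    by_clade: dict[str, list[str]] = {}
    for species, codon in column.items():
        if species not in clade_labels:
            raise ValueError(f"species {species!r} has no clade label")
        by_clade.setdefault(clade_labels[species], []).append(codon.upper())
    empty = set(clade_labels.values()) - set(by_clade)
    if empty:
        logger.info("clades with no species in column excluded: %s", sorted(empty))
    if focal_clade not in by_clade:
        raise ValueError(f"focal clade {focal_clade!r} has no species in this column")
    clades = {}
    for clade, codons in by_clade.items():
        tally = Counter(codons)
        top = max(tally.values())
        majority = min(c for c, n in tally.items() if n == top)
        clades[clade] = CladeSummary(len(codons), len(tally), majority, top / len(codons))
    reaches = {c: s.identity >= identity_threshold for c, s in clades.items()}
    if all(reaches.values()):
        pattern = CONSERVED_EVERYWHERE
    elif reaches[focal_clade] and not any(v for c, v in reaches.items() if c != focal_clade):
        pattern = CLADE_CONSERVED
    elif not any(reaches.values()):
        pattern = VARIABLE_EVERYWHERE
    else:
        pattern = OTHER_PATTERN
    return CladeCodonProfile(column_id, clades, pattern, focal_clade)


_CLADE_RE = re.compile(r"clade=(\S+)")


def read_clade_alignment(fasta_path: str) -> tuple[list[dict[str, str]], dict[str, str]]:
    """Read an in-frame alignment whose descriptions carry ``clade=<name>``.

    Returns codon columns (one ``{species: codon}`` per column) and the
    species-to-clade labels.
    """
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(fasta_path, "fasta"):
        m = _CLADE_RE.search(rec.description)
        if not m:
            raise ValueError(f"sequence {rec.id!r} lacks a clade=<name> tag")
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(f"sequence {rec.id!r} length differs from the alignment")
        if length % 3 != 0:
            raise ValueError("alignment length must be a multiple of 3")
        seqs[rec.id] = seq
        labels[rec.id] = m.group(1)
    columns = []
    for i in range(0, length or 0, 3):
        columns.append({sp: s[i:i + 3] for sp, s in seqs.items()})
    return columns, labels


def clade_branch_rates(
    tree: "str | dendropy.Tree",
    clade_labels: Mapping[str, str],
    reference_clade: str = "mammal",
) -> pd.DataFrame:
    """Mean root-to-tip path length per clade, relative to a reference.

    ``tree`` is a newick string/path or a dendropy tree with branch
    lengths; every leaf must be labelled with a clade.  Returns a frame
    indexed by clade with columns ``mean_root_to_tip`` and
    ``ratio_to_reference`` (reference defaults to mammals, the clade the
    constrained-gene contrast is anchored on).
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    elif isinstance(tree, str) and ("(" in tree):
        t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    else:
        t = dendropy.Tree.get(path=str(tree), schema="newick",
                              preserve_underscores=True)
    dists: dict[str, list[float]] = {}
    for leaf in t.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else (leaf.label or "")
        if name not in clade_labels:
            raise ValueError(f"leaf {name!r} has no clade label")
        total = 0.0
        node = leaf
        while node.parent_node is not None:
            if node.edge.length is None:
                raise ValueError(f"missing branch length on the edge above {name!r}")
            total += node.edge.length
            node = node.parent_node
        dists.setdefault(clade_labels[name], []).append(total)
    if reference_clade not in dists:
        raise ValueError(f"reference clade {reference_clade!r} not present among leaves")
    means = {c: float(np.mean(v)) for c, v in dists.items()}
    ref = means[reference_clade]
    df = pd.DataFrame(
        {"mean_root_to_tip": pd.Series(means),
         "ratio_to_reference": pd.Series({c: m / ref for c, m in means.items()})}
    ).sort_index()
    df.index.name = "clade"
    return df
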