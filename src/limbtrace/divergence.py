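"""Per-gene divergence between ortholog coding sequences and its contrasts.

Divergence is measured with the Nei-Gojobori (1986) counting estimator:
synonymous and nonsynonymous *sites* are counted per codon (they always sum
to 3), observed differences are averaged over all shortest substitution
pathways between codon pairs, and the resulting proportions are corrected
for multiple hits with the Jukes-Cantor transform
``d = -(3/4) ln(1 - (4/3) p)``.  Low dN marks a gene under strong purifying
selection; genes are ranked by it and contrasted with the per-gene
missense/synonymous ratio of proband-specific SNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import stats

from .trio_classify import TrioPartition, _gene_trees
from .variant_model import GeneInterval, MISSENSE, SNP, SYNONYMOUS

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
_BASES = "ACGT"


def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes creating a stop codon count as
    nonsynonymous.  The two counts always sum to exactly 3.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


_SITE_CACHE: dict[str, tuple[float, float]] = {}


def codon_sites(codon: str) -> tuple[float, float]:
    """Cached (synonymous, nonsynonymous) site counts for a sense codon."""
    if codon not in _SITE_CACHE:
        _SITE_CACHE[codon] = _codon_sites(codon)
    return _SITE_CACHE[codon]


def _step_is_syn(c1: str, c2: str) -> bool:
    aa1 = CODON_TO_AA.get(c1, "*")
    aa2 = CODON_TO_AA.get(c2, "*")
    return aa1 == aa2 and aa1 != "*"


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over substitution pathways.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded.  If every pathway is blocked
    (both endpoints sense codons but all intermediates stops) the average
    falls back to all pathways with stop-involving steps counted as
    nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    fallback = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if _step_is_syn(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if blocked else results).append((sd, nd))
    pool = results or fallback
    sd = sum(s for s, _ in pool) / len(pool)
    nd = sum(n for _, n in pool) / len(pool)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction; NaN (flagged) when p >= 3/4 saturates it."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        logger.warning("difference proportion %.3f >= 3/4; distance undefined", p)
        return float("nan")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class Ng86Result:
    """Nei-Gojobori estimates for one ortholog pair.

    Iterable as ``(dN, dS)`` for convenience.
    """

    dn: float
    ds: float
    pn: float
    ps: float
    nonsyn_sites: float
    syn_sites: float
    nonsyn_diffs: float
    syn_diffs: float
    n_codons: int

    def __iter__(self):
        yield self.dn
        yield self.ds


def _validate_cds(seq: str, name: str) -> str:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} is not a multiple of 3")
    if "-" in seq:
        raise ValueError(f"{name}: gaps are not allowed (pre-aligned gap-free CDS required)")
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if any(b not in _BASES for b in codon):
            raise ValueError(f"{name}: non-ACGT base in codon {i // 3 + 1} ({codon})")
        if codon in STOP_CODONS:
            raise ValueError(f"{name}: stop codon {codon} at codon {i // 3 + 1}")
    return seq


def ng86_pair(cds_a: str, cds_b: str) -> Ng86Result:
    """Nei-Gojobori dN/dS between two equal-length in-frame CDSs.

    Site counts are averaged over the two sequences; differences are
    pathway-averaged per codon pair; Jukes-Cantor corrects both
    proportions (NaN when a proportion reaches 3/4).
    """
    a = _validate_cds(cds_a, "cds_a")
    b = _validate_cds(cds_b, "cds_b")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    syn_sites = nonsyn_sites = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    n_codons = len(a) // 3
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        syn_sites += (sa + sb) / 2
        nonsyn_sites += (na + nb) / 2
        sd, nd = _pathway_counts(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd
    ps = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    return Ng86Result(
        dn=jukes_cantor(pn), ds=jukes_cantor(ps), pn=pn, ps=ps,
        nonsyn_sites=nonsyn_sites, syn_sites=syn_sites,
        nonsyn_diffs=nonsyn_diffs, syn_diffs=syn_diffs, n_codons=n_codons,
    )


def ks_compare(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(values_a, values_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, t approximation).

    Returns NaNs (flagged) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input vector; rank correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def mis_syn_table(
    partition: TrioPartition,
    gene_intervals: Sequence[GeneInterval],
    require_both: bool = True,
) -> pd.DataFrame:
    """Per-gene counts of proband-specific missense and synonymous SNPs.

    Only specific SNPs contribute.  The mis/syn ratio is emitted for genes
    with both counts >= 1 (``require_both=False`` relaxes this to
    synonymous >= 1); other genes keep a NaN ratio.  Indels never count.
    """
    trees = _gene_trees(gene_intervals)
    counts: dict[str, list[int]] = {}
    for r in partition.specific:
        if r.vtype != SNP or r.effect not in (MISSENSE, SYNONYMOUS):
            continue
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.at(r.pos):
            row = counts.setdefault(iv.data, [0, 0])
            row[0 if r.effect == MISSENSE else 1] += 1
    rows = []
    for gid in sorted(counts):
        mis, syn = counts[gid]
        if require_both:
            ok = mis >= 1 and syn >= 1
        else:
            ok = syn >= 1
        rows.append((gid, mis, syn, mis / syn if ok else float("nan")))
    return pd.DataFrame(rows, columns=["gene_id", "mis_count", "syn_count", "mis_syn_ratio"])


@dataclass
class GeneDivergence:
    """Divergence and specific-SNP effect summary for one gene."""

    gene_id: str
    dn: float
    ds: float
    mis_count: int
    syn_count: int
    mis_syn_ratio: float


def read_ortholog_pairs(
    pairs_tsv: str, fasta_a: str, fasta_b: str
) -> dict[str, tuple[str, str]]:
    """Load a two-column ortholog pairing table plus the two CDS FASTAs.

    Returns ``{gene_id_a: (cds_a, cds_b)}``.  Missing sequences raise.
    """
    pairs = pd.read_csv(pairs_tsv, sep="\t", header=None, names=["a", "b"], comment="#")
    seqs_a = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_a, "fasta")}
    seqs_b = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_b, "fasta")}
    out = {}
    for a_id, b_id in zip(pairs["a"], pairs["b"]):
        if a_id not in seqs_a:
            raise ValueError(f"gene {a_id!r} missing from {fasta_a}")
        if b_id not in seqs_b:
            raise ValueError(f"gene {b_id!r} missing from {fasta_b}")
        out[a_id] = (seqs_a[a_id], seqs_b[b_id])
    return out


def divergence_table(
    cds_pairs: Mapping[str, tuple[str, str]],
    partition: TrioPartition | None = None,
    gene_intervals: Sequence[GeneInterval] | None = None,
    require_both: bool = True,
) -> pd.DataFrame:
    """Per-gene NG86 dN/dS, merged with specific mis/syn counts when given."""
    rows = []
    for gid in sorted(cds_pairs):
        a, b = cds_pairs[gid]
        res = ng86_pair(a, b)
        rows.append((gid, res.dn, res.ds))
    df = pd.DataFrame(rows, columns=["gene_id", "dn", "ds"])
    if partition is not None and gene_intervals is not None:
        ms = mis_syn_table(partition, gene_intervals, require_both=require_both)
        df = df.merge(ms, on="gene_id", how="left")
        df["mis_count"] = df["mis_count"].fillna(0).astype(int)
        df["syn_count"] = df["syn_count"].fillna(0).astype(int)
    return df
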