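"""Seeded generators for trio variant data, ortholog pairs and alignments.

The trio generator reproduces the statistical structure the inference
stages rely on: diploid parents with haplotype-private variant sets, one
meiotic draw per chromosome per parent (probability 0.5 per homolog), a
designated pair of "causal" paternal chromosomes forced to differ between
the affected offspring and its sibling, de novo mutations at a mammalian
germline rate, and read support drawn around realistic depth.  A truth
side-channel records every haplotype choice so parameter-recovery tests
can hold the pipeline to account.

The father is simulated but never emitted - as in the study, only the
mother, sibling and affected offspring are "sequenced".
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import repeat
from typing import Mapping, Sequence

import numpy as np

from . import divergence as _div
from .variant_model import (
    HET, HOM, INDEL, INTERGENIC, SNP, GeneInterval, VariantRecord, write_vcf,
)

#: approximate Sus scrofa chromosome lengths (Sscrofa11.1 scale, bp)
PIG_CHROMOSOME_SIZES: tuple[tuple[str, int], ...] = (
    ("chr1", 274_000_000), ("chr2", 151_000_000), ("chr3", 132_000_000),
    ("chr4", 130_000_000), ("chr5", 104_000_000), ("chr6", 170_000_000),
    ("chr7", 121_000_000), ("chr8", 138_000_000), ("chr9", 139_000_000),
    ("chr10", 69_000_000), ("chr11", 79_000_000), ("chr12", 61_000_000),
    ("chr13", 208_000_000), ("chr14", 141_000_000), ("chr15", 140_000_000),
    ("chr16", 79_000_000), ("chr17", 63_000_000), ("chr18", 55_000_000),
    ("chrX", 125_000_000),
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated trio.

    Per-chromosome variant counts are split evenly between a parent's two
    haplotypes.  ``het_fraction_specific`` / ``het_fraction_nonspecific``
    reproduce the observed zygosity mix of specific (89.4% het) and shared
    (70.2% het) variants.  ``sibling_coupled`` makes the sibling inherit
    the same paternal homolog as the proband on every non-causal
    chromosome, the single-family scenario the enrichment statistic is
    designed to detect; set it False for fully independent assortment.
    """

    chromosomes: tuple[tuple[str, int], ...] = PIG_CHROMOSOME_SIZES
    causal_chromosomes: tuple[str, ...] = ("chr7", "chr17")
    father_specific_per_chrom: int = 5_000
    mother_specific_per_chrom: int = 5_000
    shared_per_chrom: int = 10_000
    de_novo_rate: float = 1e-8
    mean_depth: float = 20.0
    error_rate: float = 0.01
    het_fraction_specific: float = 0.894
    het_fraction_nonspecific: float = 0.702
    indel_fraction: float = 0.1
    sibling_coupled: bool = True
    crossovers_per_chrom: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        names = {n for n, _ in self.chromosomes}
        missing = set(self.causal_chromosomes) - names
        if missing:
            raise ValueError(f"causal chromosomes absent from chromosome list: {sorted(missing)}")
        for n, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {n} has non-positive length {length}")
        for rate in (self.de_novo_rate, self.error_rate):
            if not 0 <= rate < 1:
                raise ValueError(f"rates must lie in [0, 1), got {rate}")
        for frac in (self.het_fraction_specific, self.het_fraction_nonspecific,
                     self.indel_fraction):
            if not 0 <= frac <= 1:
                raise ValueError(f"fractions must lie in [0, 1], got {frac}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


#: allele key identifying a variant: (chrom, pos, ref, alt)
AlleleKey = tuple[str, int, str, str]


@dataclass
class TrioTruth:
    """Ground truth for one simulated trio.

    ``paternal_choice``/``maternal_choice`` map offspring -> chromosome ->
    transmitted homolog ('A'/'B').  ``parental_private`` maps
    (parent, homolog) -> chromosome -> the allele keys private to that
    homolog; ``shared`` holds the pedigree-shared keys.  ``de_novo`` lists
    each offspring's de novo mutations.  Truth is never written into the
    emitted VCFs.
    """

    causal: tuple[str, ...]
    paternal_choice: dict[str, dict[str, str]]
    maternal_choice: dict[str, dict[str, str]]
    parental_private: dict[tuple[str, str], dict[str, list[AlleleKey]]]
    shared: dict[str, list[AlleleKey]]
    de_novo: dict[str, list[VariantRecord]]


@dataclass
class SimulatedTrio:
    """Generated records for the three sequenced individuals plus truth."""

    mother: list[VariantRecord]
    sibling: list[VariantRecord]
    proband: list[VariantRecord]
    truth: TrioTruth
    config: SimConfig


def _draw_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """k distinct positions in [1, length]; collisions redrawn."""
    if k > length:
        raise ValueError(f"cannot place {k} distinct variants on {length} bp")
    pos = np.unique(rng.integers(1, length + 1, size=k))
    while pos.size < k:
        extra = rng.integers(1, length + 1, size=k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[rng.permutation(pos.size)] if pos.size == k else pos[:k]


def _draw_alleles(
    rng: np.random.Generator, n: int, indel_fraction: float
) -> tuple[list[str], list[str], list[str]]:
    """Random ref/alt alleles with a configurable Indel share."""
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    refs = _BASES[ref_idx].tolist()
    alts = _BASES[alt_idx].tolist()
    vtypes = [SNP] * n
    is_indel = rng.random(n) < indel_fraction
    ins_mask = rng.random(n) < 0.5
    extra_len = rng.integers(1, 4, size=n)
    extra_bases = _BASES[rng.integers(0, 4, size=(n, 3))]
    for i in np.nonzero(is_indel)[0]:
        tail = "".join(extra_bases[i][: extra_len[i]])
        if ins_mask[i]:
            alts[i] = refs[i] + tail     # insertion
        else:
            refs[i] = refs[i] + tail     # deletion
            alts[i] = refs[i][0]
        vtypes[i] = INDEL
    return refs, alts, vtypes


def simulate_read_support(
    record: VariantRecord, config: SimConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (depth, alt_reads) for one variant.

    Depth is Poisson around the configured mean; heterozygous sites draw
    alternate reads Binomial(depth, 0.5); homozygous sites lose only
    error-rate reads to the reference allele.
    """
    depth = int(rng.poisson(config.mean_depth))
    if record.zygosity == HOM:
        alt = depth - int(rng.binomial(depth, config.error_rate))
    else:
        alt = int(rng.binomial(depth, 0.5))
    return depth, alt


def _read_support_arrays(
    zyg: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = zyg.size
    depth = rng.poisson(config.mean_depth, size=n)
    het_alt = rng.binomial(depth, 0.5)
    hom_alt = depth - rng.binomial(depth, config.error_rate)
    return depth, np.where(zyg, het_alt, hom_alt)


def _records_for(
    chrom: str,
    pos: np.ndarray,
    refs: np.ndarray,
    alts: np.ndarray,
    vtypes: np.ndarray,
    het_prob: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Assemble coordinate-sorted records for one individual/chromosome."""
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    is_het = rng.random(pos.size) < het_prob[order]
    depth, alt_reads = _read_support_arrays(is_het, config, rng)
    zyg = np.where(is_het, HET, HOM).tolist()
    return list(map(VariantRecord._make, zip(
        repeat(chrom), pos.tolist(), refs[order].tolist(), alts[order].tolist(), zyg,
        depth.tolist(), alt_reads.tolist(), vtypes[order].tolist(), repeat(INTERGENIC),
    )))


def _draw_paternal(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """One paternal meiosis: the homolog transmitted per chromosome.

    Non-causal chromosomes are a fair coin; causal chromosomes are forced
    to homolog A for the proband-style gamete (the sibling is assigned B
    downstream).
    """
    choice = {}
    for name, _ in config.chromosomes:
        if name in config.causal_chromosomes:
            choice[name] = "A"
        else:
            choice[name] = "A" if rng.random() < 0.5 else "B"
    return choice


def simulate_meioses(
    config: SimConfig, chrom: str, n_meioses: int, seed: int | None = None
) -> list[str]:
    """Repeat the paternal meiosis step and report the homolog drawn.

    Runs the same per-chromosome assortment code path used by
    :func:`simulate_trio`, ``n_meioses`` times, returning the transmitted
    homolog ('A'/'B') on ``chrom`` for each gamete.
    """
    if chrom not in {n for n, _ in config.chromosomes}:
        raise ValueError(f"chromosome {chrom!r} not in config")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [_draw_paternal(config, rng)[chrom] for _ in range(n_meioses)]


def add_de_novo(
    offspring_records: Sequence[VariantRecord],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Sprinkle de novo germline SNPs over one offspring's genome.

    The count is Poisson(rate x diploid genome length); positions are
    uniform (per-chromosome probability proportional to length); every de
    novo mutation is heterozygous.  Returns (records + de novo, de novo).
    """
    lengths = np.array([length for _, length in config.chromosomes], dtype=float)
    n = int(rng.poisson(config.de_novo_rate * 2 * lengths.sum()))
    de_novo: list[VariantRecord] = []
    if n > 0:
        chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
        for ci in chrom_idx:
            name, length = config.chromosomes[ci]
            pos = int(rng.integers(1, length + 1))
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            rec = VariantRecord(name, pos, str(_BASES[ref_i]), str(_BASES[alt_i]),
                                HET, None, None, SNP, INTERGENIC)
            depth, alt = simulate_read_support(rec, config, rng)
            de_novo.append(rec._replace(depth=depth, alt_reads=alt))
    return list(offspring_records) + de_novo, de_novo


def _transmitted(
    pos: np.ndarray, hap_a: bool, choice: str,
    breakpoints: np.ndarray,
) -> np.ndarray:
    """Mask of variants transmitted from one homolog, crossover-aware.

    With no breakpoints the whole chosen homolog is transmitted; with
    breakpoints the gamete alternates homolog along the chromosome.
    """
    home = 0 if hap_a else 1
    start = 0 if choice == "A" else 1
    if breakpoints.size == 0:
        return np.full(pos.size, start == home)
    segment = np.searchsorted(breakpoints, pos, side="right")
    return (start + segment) % 2 == home


def simulate_trio(config: SimConfig) -> SimulatedTrio:
    """Generate mother (M), sibling (S) and affected offspring (H) records.

    Both parents carry pedigree-shared variants plus haplotype-private
    variant sets; each offspring receives one homolog per chromosome per
    parent.  On causal chromosomes the proband always receives the
    father's homolog A and the sibling homolog B; elsewhere the paternal
    draw is a fair coin (shared between the two offspring when
    ``sibling_coupled``).  De novo mutations are added to both offspring
    at the configured rate.  Identical config (incl. seed) gives identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pat_h = _draw_paternal(config, rng)
    pat_s: dict[str, str] = {}
    mat = {"H": {}, "S": {}}
    for name, _ in config.chromosomes:
        if name in config.causal_chromosomes:
            pat_s[name] = "B"
        elif config.sibling_coupled:
            pat_s[name] = pat_h[name]
        else:
            pat_s[name] = "A" if rng.random() < 0.5 else "B"
        for off in ("H", "S"):
            mat[off][name] = "A" if rng.random() < 0.5 else "B"

    parental_private: dict[tuple[str, str], dict[str, list[AlleleKey]]] = {
        ("father", "A"): {}, ("father", "B"): {},
        ("mother", "A"): {}, ("mother", "B"): {},
    }
    shared_truth: dict[str, list[AlleleKey]] = {}
    mother_recs: list[VariantRecord] = []
    sibling_recs: list[VariantRecord] = []
    proband_recs: list[VariantRecord] = []

    n_f = config.father_specific_per_chrom // 2
    n_m = config.mother_specific_per_chrom // 2
    n_sh = config.shared_per_chrom
    p_spec = config.het_fraction_specific
    p_nonspec = config.het_fraction_nonspecific

    for name, length in config.chromosomes:
        total = n_sh + 2 * n_m + 2 * n_f
        pos = _draw_positions(rng, length, total)
        ref_l, alt_l, vt_l = _draw_alleles(rng, total, config.indel_fraction)
        refs = np.array(ref_l, dtype=object)
        alts = np.array(alt_l, dtype=object)
        vtypes = np.array(vt_l, dtype=object)
        sl = {
            "shared": slice(0, n_sh),
            "mA": slice(n_sh, n_sh + n_m),
            "mB": slice(n_sh + n_m, n_sh + 2 * n_m),
            "fA": slice(n_sh + 2 * n_m, n_sh + 2 * n_m + n_f),
            "fB": slice(n_sh + 2 * n_m + n_f, total),
        }

        def keys_for(s: slice) -> list[AlleleKey]:
            return list(zip(repeat(name), pos[s].tolist(),
                            refs[s].tolist(), alts[s].tolist()))

        # truth: allele keys per parental homolog and for the shared pool
        for parent, hap, key in (("mother", "A", "mA"), ("mother", "B", "mB"),
                                 ("father", "A", "fA"), ("father", "B", "fB")):
            parental_private[(parent, hap)][name] = keys_for(sl[key])
        shared_truth[name] = keys_for(sl["shared"])

        # breakpoints for the optional crossover model, per meiosis
        def draw_breaks() -> np.ndarray:
            if config.crossovers_per_chrom <= 0:
                return np.array([], dtype=int)
            k = rng.poisson(config.crossovers_per_chrom)
            return np.sort(rng.integers(1, length + 1, size=k))

        # mother's own record set: shared + both her private homolog sets
        m_idx = np.arange(0, n_sh + 2 * n_m)
        mother_recs.extend(_records_for(
            name, pos[m_idx], refs[m_idx], alts[m_idx], vtypes[m_idx],
            np.full(m_idx.size, p_nonspec), config, rng))

        # each offspring: shared + transmitted maternal + transmitted paternal
        for off, recs, pat_choice in (("H", proband_recs, pat_h),
                                      ("S", sibling_recs, pat_s)):
            keep_idx: list[np.ndarray] = [np.arange(sl["shared"].start, sl["shared"].stop)]
            mat_breaks = draw_breaks()
            pat_breaks = draw_breaks()
            for parent, choice, breaks in (("mother", mat[off][name], mat_breaks),
                                           ("father", pat_choice[name], pat_breaks)):
                for hap, key in (("A", parent[0] + "A"), ("B", parent[0] + "B")):
                    s = sl[key]
                    idx = np.arange(s.start, s.stop)
                    mask = _transmitted(pos[idx], hap == "A", choice, breaks)
                    keep_idx.append(idx[mask])
            idx = np.concatenate(keep_idx)
            p_het = np.where(idx >= sl["fA"].start, p_spec, p_nonspec)
            recs.extend(_records_for(
                name, pos[idx], refs[idx], alts[idx], vtypes[idx],
                p_het, config, rng))

    de_novo: dict[str, list[VariantRecord]] = {}
    proband_recs, de_novo["H"] = add_de_novo(proband_recs, config, rng)
    sibling_recs, de_novo["S"] = add_de_novo(sibling_recs, config, rng)

    truth = TrioTruth(
        causal=tuple(config.causal_chromosomes),
        paternal_choice={"H": pat_h, "S": pat_s},
        maternal_choice=mat,
        parental_private=parental_private,
        shared=shared_truth,
        de_novo=de_novo,
    )
    return SimulatedTrio(mother_recs, sibling_recs, proband_recs, truth, config)


def _sort_records(records: Sequence[VariantRecord],
                  chrom_order: Sequence[str]) -> list[VariantRecord]:
    rank = {c: i for i, c in enumerate(chrom_order)}
    return sorted(records, key=lambda r: (rank.get(r.chrom, len(rank)), r.pos, r.alt))


def write_trio_vcfs(sim: SimulatedTrio, out_dir: str) -> dict[str, str]:
    """Write M.vcf, S.vcf, H.vcf plus the truth sidecar TSV.

    Truth (haplotype choices and de novo labels) goes only into
    ``truth.tsv``, never into the VCFs, so downstream inference cannot
    peek.  Returns the written paths.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    chrom_order = [n for n, _ in sim.config.chromosomes]
    lengths = dict(sim.config.chromosomes)
    paths = {}
    for label, recs in (("M", sim.mother), ("S", sim.sibling), ("H", sim.proband)):
        path = os.path.join(out_dir, f"{label}.vcf")
        write_vcf(_sort_records(recs, chrom_order), path, label, contig_lengths=lengths)
        paths[label] = path
    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("kind\toffspring\tchrom\tvalue\n")
        for off in ("H", "S"):
            for chrom in chrom_order:
                fh.write(f"paternal_choice\t{off}\t{chrom}\t{sim.truth.paternal_choice[off][chrom]}\n")
                fh.write(f"maternal_choice\t{off}\t{chrom}\t{sim.truth.maternal_choice[off][chrom]}\n")
            for rec in sim.truth.de_novo[off]:
                fh.write(f"de_novo\t{off}\t{rec.chrom}\t{rec.pos}:{rec.ref}>{rec.alt}\n")
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# gene intervals


def simulate_genes(
    config: SimConfig,
    rng: np.random.Generator,
    n_per_chrom: int = 5,
    gene_length: int = 30_000,
) -> list[GeneInterval]:
    """Toy gene intervals, with the six candidate genes on chr7/chr17.

    Mirrors the study gene geography: BMP5, BMP6 and FOXF2 on chromosome 7;
    BMP2, BMP7 and RSPO4 on chromosome 17.  Remaining genes are evenly
    spaced fillers named GENE_<chrom>_<i>.
    """
    placement = {"chr7": ["BMP5", "BMP6", "FOXF2"], "chr17": ["BMP2", "BMP7", "RSPO4"]}
    genes: list[GeneInterval] = []
    for name, length in config.chromosomes:
        named = placement.get(name, [])
        total = n_per_chrom + len(named)
        spacing = length // (total + 1)
        if spacing <= gene_length:
            raise ValueError(f"chromosome {name} too short for {total} genes")
        labels = named + [f"GENE_{name}_{i}" for i in range(n_per_chrom)]
        for j, gid in enumerate(labels, start=1):
            start = j * spacing + int(rng.integers(0, max(1, spacing - gene_length)))
            genes.append(GeneInterval(gid, name, start, start + gene_length - 1,
                                      is_candidate=gid in placement.get(name, [])))
    return genes


def write_gtf(genes: Sequence[GeneInterval], path: str) -> None:
    """Write gene intervals as minimal GTF ``gene`` features."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\tlimbtrace\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# ortholog pairs


_SENSE_CODONS = sorted(_div.CODON_TO_AA)


def _substitution_options() -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    syn: dict[str, list[str]] = {}
    nonsyn: dict[str, list[str]] = {}
    for codon in _SENSE_CODONS:
        aa = _div.CODON_TO_AA[codon]
        s_opts, n_opts = [], []
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                alt = codon[:i] + b + codon[i + 1:]
                if alt in _div.STOP_CODONS:
                    continue  # never introduce stops
                (s_opts if _div.CODON_TO_AA[alt] == aa else n_opts).append(alt)
        syn[codon] = s_opts
        nonsyn[codon] = n_opts
    return syn, nonsyn


_SYN_OPTS, _NONSYN_OPTS = _substitution_options()


def simulate_ortholog_pair(
    n_codons: int,
    target_ds: float,
    target_dn: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Evolve one CDS from another at chosen synonymous/nonsynonymous rates.

    Substitution events are drawn Poisson around ``target x site count``
    and applied one at a time - synonymous events at codons weighted by
    their current synonymous site counts, nonsynonymous likewise - so
    multiple hits accumulate naturally and the Jukes-Cantor-corrected
    NG86 estimates recover the targets.  Stop codons are never created.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    for name, d in (("target_ds", target_ds), ("target_dn", target_dn)):
        if d < 0:
            raise ValueError(f"{name} must be >= 0")
        if d > 2:
            raise ValueError(
                f"{name}={d} saturates the Jukes-Cantor correction; use a value <= 2"
            )
    codons = [ _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons) ]
    cds_a = "".join(codons)
    evolved = list(codons)

    def site_weights(which: int) -> np.ndarray:
        return np.array([_div.codon_sites(c)[which] for c in evolved])

    for which, opts, target in ((0, _SYN_OPTS, target_ds), (1, _NONSYN_OPTS, target_dn)):
        weights = site_weights(which)
        total_sites = weights.sum()
        n_events = int(rng.poisson(target * total_sites)) if target > 0 else 0
        for _ in range(n_events):
            w = weights / weights.sum()
            i = int(rng.choice(len(evolved), p=w))
            choices = opts[evolved[i]]
            if not choices:  # codon lost all options (e.g. ATG/TGG for syn)
                continue
            evolved[i] = choices[int(rng.integers(0, len(choices)))]
            weights[i] = _div.codon_sites(evolved[i])[which]
    return cds_a, "".join(evolved)


# ---------------------------------------------------------------------------
# clade alignments and trees


DEFAULT_CLADE_SIZES: Mapping[str, int] = {
    "mammal": 10, "bird": 6, "reptile": 6, "amphibian": 6, "fish": 6,
}
DEFAULT_SUB_PROBS: Mapping[str, float] = {
    "mammal": 0.02, "bird": 0.5, "reptile": 0.5, "amphibian": 0.5, "fish": 0.5,
}


def simulate_clade_columns(
    n_columns: int,
    rng: np.random.Generator,
    clade_sizes: Mapping[str, int] = DEFAULT_CLADE_SIZES,
    sub_probs: Mapping[str, float] = DEFAULT_SUB_PROBS,
) -> tuple[list[dict[str, str]], dict[str, str]]:
    """Codon columns with clade-specific substitution probabilities.

    Each column starts from one ancestral sense codon; each species
    replaces it with a random different sense codon with its clade's
    probability (defaults: 2% within mammals, 50% elsewhere - a strongly
    mammal-conserved gene).
    """
    labels = {}
    species = []
    for clade, n in clade_sizes.items():
        for i in range(n):
            sp = f"{clade}_{i}"
            labels[sp] = clade
            species.append(sp)
    columns = []
    for _ in range(n_columns):
        anc = _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
        col = {}
        for sp in species:
            if rng.random() < sub_probs[labels[sp]]:
                alt = anc
                while alt == anc:
                    alt = _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
                col[sp] = alt
            else:
                col[sp] = anc
        columns.append(col)
    return columns, labels


def simulate_clade_tree(
    rng: np.random.Generator,
    clade_sizes: Mapping[str, int] = DEFAULT_CLADE_SIZES,
    clade_rates: Mapping[str, float] | None = None,
) -> tuple[str, dict[str, str]]:
    """A rooted newick tree whose tip depths scale with per-clade rates.

    Mammals default to a ten-fold lower rate than the other vertebrate
    clades, mirroring a gene under mammal-specific constraint.
    """
    if clade_rates is None:
        clade_rates = {c: (0.1 if c == "mammal" else 1.0) for c in clade_sizes}
    labels = {}
    clade_strs = []
    for clade, n in sorted(clade_sizes.items()):
        tips = []
        for i in range(n):
            sp = f"{clade}_{i}"
            labels[sp] = clade
            bl = clade_rates[clade] * (0.8 + 0.4 * rng.random())
            tips.append(f"{sp}:{bl:.6f}")
        clade_strs.append(f"({','.join(tips)}):{0.05:.6f}")
    newick = f"({','.join(clade_strs)});"
    return newick, labels


def derive_seed(base_seed: int, *tokens: object) -> int:
    """A stable child seed (< 2**31) derived from a base seed and tokens."""
    digest = hashlib.sha256(("|".join(map(str, (base_seed, *tokens)))).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
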