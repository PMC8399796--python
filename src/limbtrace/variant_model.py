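"""Variant records, VCF/GTF ingestion, and site-level quality statistics.

The pipeline consumes the *outputs* of an upstream short-read workflow
(alignment, variant calling, effect annotation).  This module defines the
in-memory record type shared by every downstream stage, the depth/allele
quality filter, and the binomial test used to argue that an observed
alternate-allele pile-up cannot be a sequencing artefact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from cyvcf2 import VCF
from scipy import stats

logger = logging.getLogger(__name__)

# zygosity codes
HET = "het"
HOM = "hom"

# variant types
SNP = "SNP"
INDEL = "Indel"

# coding-effect categories
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
OTHER_GENIC = "other_genic"
INTERGENIC = "intergenic"

EFFECTS = (MISSENSE, SYNONYMOUS, OTHER_GENIC, INTERGENIC)

#: the six limb/bone-development candidate genes on chromosomes 7 and 17
CANDIDATE_GENES = frozenset({"BMP2", "BMP5", "BMP6", "BMP7", "FOXF2", "RSPO4"})


class VariantRecord(NamedTuple):
    """One called variant for one individual (one ALT allele).

    Coordinates are 1-based as in VCF.  ``depth``/``alt_reads`` are ``None``
    when the source file lacked DP/AD; the quality filter treats unknown as
    failing.  ``zygosity`` is ``None`` for calls that could not be resolved
    against this ALT allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str | None
    depth: int | None
    alt_reads: int | None
    vtype: str
    effect: str = INTERGENIC

    def key(self, mode: str = "allele") -> tuple:
        """Matching key used by the trio partition.

        ``allele`` mode keys on (chrom, pos, ref, alt); ``position`` mode on
        (chrom, pos) only.
        """
        if mode == "allele":
            return (self.chrom, self.pos, self.ref, self.alt)
        if mode == "position":
            return (self.chrom, self.pos)
        raise ValueError(f"unknown match mode {mode!r}; use 'allele' or 'position'")


def make_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    zygosity: str | None = HET,
    depth: int | None = None,
    alt_reads: int | None = None,
    effect: str = INTERGENIC,
) -> VariantRecord:
    """Build a validated :class:`VariantRecord`, deriving the variant type."""
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if depth is not None and alt_reads is not None and not 0 <= alt_reads <= depth:
        raise ValueError(f"alt_reads {alt_reads} outside [0, depth={depth}]")
    if zygosity not in (HET, HOM, None):
        raise ValueError(f"zygosity must be {HET!r}, {HOM!r} or None, got {zygosity!r}")
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    return VariantRecord(
        chrom, pos, ref, alt, zygosity, depth, alt_reads, classify_variant_type(ref, alt), effect
    )


def classify_variant_type(ref: str, alt: str) -> str:
    """SNP iff both alleles are single bases; anything else is an Indel."""
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}); not a variant")
    return SNP if len(ref) == 1 and len(alt) == 1 else INDEL


def parse_zygosity(genotype: str, n_alts: int = 1, alt_index: int = 1) -> str | None:
    """Parse a VCF genotype string into a zygosity code for one ALT allele.

    ``0/1`` (either order, ``/`` or ``|``) is heterozygous, ``1/1`` is
    homozygous, ``./.`` is undefined (``None``).  For records decomposed from
    multi-allelic rows, ``alt_index`` selects which ALT the call is resolved
    against; a genotype not carrying that allele is also undefined.
    """
    sep = "|" if "|" in genotype else "/"
    fields = genotype.split(sep)
    if len(fields) != 2:
        raise ValueError(f"genotype {genotype!r} is not diploid 'a/b' or 'a|b'")
    if "." in fields:
        return None
    try:
        alleles = [int(f) for f in fields]
    except ValueError as exc:
        raise ValueError(f"malformed genotype {genotype!r}") from exc
    if max(alleles) > n_alts:
        raise ValueError(
            f"genotype {genotype!r} references allele {max(alleles)} "
            f"but the row has only {n_alts} ALT allele(s)"
        )
    count = alleles.count(alt_index)
    if count == 2:
        return HOM
    if count == 1:
        return HET
    return None


_UNKNOWN_FILTER_LOGGED = False


def passes_quality_filter(
    record: VariantRecord, min_depth: int = 10, min_alt: int = 3
) -> bool:
    """Depth/allele-support filter with strict inequalities.

    A site passes iff depth > ``min_depth`` AND alt_reads > ``min_alt``.
    Unknown depth or allele counts fail the filter (logged once) so that
    missing annotations can never inflate the proband-specific set.
    """
    global _UNKNOWN_FILTER_LOGGED
    if record.depth is None or record.alt_reads is None:
        if not _UNKNOWN_FILTER_LOGGED:
            logger.warning(
                "records with unknown DP/AD fail the quality filter "
                "(first offender: %s:%d)", record.chrom, record.pos
            )
            _UNKNOWN_FILTER_LOGGED = True
        return False
    return record.depth > min_depth and record.alt_reads > min_alt


def sequencing_error_tail(depth: int, alt_count: int, error_rate: float = 0.01) -> float:
    """Upper-tail probability that sequencing error alone explains the call.

    Returns P(X >= alt_count) for X ~ Binomial(depth, error_rate): the chance
    that at least this many alternate-supporting reads arise purely from
    per-base sequencing error.  Small values mean the variant is genuine.
    """
    if not 0 < error_rate < 1:
        raise ValueError(f"error_rate must be in (0, 1), got {error_rate}")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count {alt_count} outside [0, depth={depth}]")
    # sf(k) = P(X > k), so P(X >= alt_count) = sf(alt_count - 1)
    return float(stats.binom.sf(alt_count - 1, depth, error_rate))


# SnpEff/VEP-style ANN terms that denote positions outside any gene
_INTERGENIC_TERMS = {
    "intergenic_region",
    "intergenic_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
}
_KNOWN_GENIC_TERMS = {
    "missense_variant",
    "synonymous_variant",
    "stop_retained_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "initiator_codon_variant",
    "intron_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_region_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "frameshift_variant",
    "inframe_insertion",
    "inframe_deletion",
    "disruptive_inframe_insertion",
    "disruptive_inframe_deletion",
    "gene_variant",
    "transcript_variant",
    "non_coding_transcript_exon_variant",
    "non_coding_transcript_variant",
}
_UNKNOWN_TERMS_LOGGED: set[str] = set()


def classify_coding_effect(annotation: str | None) -> str:
    """Collapse an ANN-style pipe-delimited annotation to one effect class.

    The first (most severe, by annotator convention) annotation wins; its
    first ``&``-joined term decides the class.  Missing or intergenic
    annotations map to ``intergenic``; unrecognised terms map to
    ``other_genic`` and are logged once per term.
    """
    if not annotation:
        return INTERGENIC
    first = annotation.split(",")[0]
    fields = first.split("|")
    term = (fields[1] if len(fields) > 1 else fields[0]).split("&")[0].strip()
    if not term:
        return INTERGENIC
    if term == "missense_variant":
        return MISSENSE
    if term == "synonymous_variant":
        return SYNONYMOUS
    if term in _INTERGENIC_TERMS:
        return INTERGENIC
    if term not in _KNOWN_GENIC_TERMS and term not in _UNKNOWN_TERMS_LOGGED:
        logger.info("unrecognised annotation term %r mapped to other_genic", term)
        _UNKNOWN_TERMS_LOGGED.add(term)
    return OTHER_GENIC


# effect class -> ANN term used when writing records back to VCF
_EFFECT_TO_TERM = {
    MISSENSE: "missense_variant",
    SYNONYMOUS: "synonymous_variant",
    OTHER_GENIC: "gene_variant",
}


def read_vcf(path: str, sample_name: str) -> list[VariantRecord]:
    """Read one sample's calls from a VCF 4.x file.

    Multi-allelic rows are decomposed into one record per ALT allele carried
    by the sample; rows where the sample genotype is missing are skipped.
    DP and AD are honoured when present; absent fields yield ``None`` (which
    the quality filter treats as failing).
    """
    vcf = VCF(str(path))
    if sample_name not in vcf.samples:
        raise ValueError(
            f"sample {sample_name!r} not in {path}; available samples: {vcf.samples}"
        )
    sample_i = vcf.samples.index(sample_name)
    records: list[VariantRecord] = []
    row = 0
    try:
        for v in vcf:
            row += 1
            gt = v.genotypes[sample_i]
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                continue  # missing genotype
            n_alts = len(v.ALT)
            if max(alleles) > n_alts:
                raise ValueError(
                    f"genotype references allele {max(alleles)} but row has {n_alts} ALT(s)"
                )
            dp_arr = v.format("DP")
            depth = None
            if dp_arr is not None and int(dp_arr[sample_i][0]) >= 0:
                depth = int(dp_arr[sample_i][0])
            ad_arr = v.format("AD")
            ann = v.INFO.get("ANN")
            for alt_i, alt in enumerate(v.ALT, start=1):
                count = alleles.count(alt_i)
                if count == 0:
                    continue
                zyg = HOM if count == 2 else HET
                alt_reads = None
                if ad_arr is not None and ad_arr.shape[1] > alt_i:
                    val = int(ad_arr[sample_i][alt_i])
                    alt_reads = val if val >= 0 else None
                effect = classify_coding_effect(_ann_for_allele(ann, alt))
                records.append(
                    VariantRecord(
                        v.CHROM, v.POS, v.REF, alt, zyg, depth, alt_reads,
                        classify_variant_type(v.REF, alt), effect,
                    )
                )
    except ValueError:
        raise
    except Exception as exc:  # cyvcf2 parse failures carry no location info
        raise ValueError(f"malformed VCF row {row + 1} in {path}: {exc}") from exc
    return records


def _ann_for_allele(ann: str | None, alt: str) -> str | None:
    """Pick the ANN entry describing this ALT allele (first entry otherwise)."""
    if not ann:
        return None
    entries = ann.split(",")
    for entry in entries:
        if entry.split("|", 1)[0] == alt:
            return entry
    return entries[0]


def write_vcf(
    records: Sequence[VariantRecord], path: str, sample_name: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as a minimal single-sample VCF 4.2 file.

    Records are written in input order; callers wanting coordinate-sorted
    output should sort first.  Effects round-trip through the ANN INFO field.
    """
    contigs: dict[str, int | None] = {}
    for r in records:
        contigs.setdefault(r.chrom, None)
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines += [
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name,
    ]
    for r in records:
        gt = {HET: "0/1", HOM: "1/1", None: "./."}[r.zygosity]
        dp = str(r.depth) if r.depth is not None else "."
        if r.depth is not None and r.alt_reads is not None:
            ad = f"{r.depth - r.alt_reads},{r.alt_reads}"
        else:
            ad = "."
        term = _EFFECT_TO_TERM.get(r.effect)
        info = f"ANN={r.alt}|{term}|MODIFIER|" if term else "."
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\tGT:DP:AD\t{gt}:{dp}:{ad}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class GeneInterval:
    """A gene span (1-based, inclusive) with a candidate-gene flag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    is_candidate: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


def read_gene_intervals(
    gtf_path: str, candidate_genes: Iterable[str] = CANDIDATE_GENES
) -> list[GeneInterval]:
    """Load gene features from a GTF into :class:`GeneInterval` rows.

    Duplicate gene_ids are merged to their union span (per the partition
    contract that intervals are non-overlapping per gene).
    """
    import gffutils

    candidates = set(candidate_genes)
    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True, merge_strategy="create_unique",
    )
    spans: dict[str, list] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        if gid in spans:
            cur = spans[gid]
            cur[1] = min(cur[1], feat.start)
            cur[2] = max(cur[2], feat.end)
        else:
            spans[gid] = [feat.seqid, feat.start, feat.end]
    return [
        GeneInterval(gid, chrom, start, end, gid in candidates)
        for gid, (chrom, start, end) in spans.items()
    ]
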