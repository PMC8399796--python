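# Methods

This note documents the models, defaults and design choices behind
`limbtrace`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic-data tests do and do not show.

## Variant model and quality filter

A variant record carries 1-based VCF coordinates, one ALT allele
(multi-allelic rows are decomposed, with zygosity resolved against the
specific ALT index), zygosity (0/1 or 1/0 → heterozygous, 1/1 → homozygous,
./. undefined), read depth (DP), alternate-supporting reads (AD), a
SNP/Indel type (SNP iff both alleles are single bases) and one coding
effect collapsed from ANN-style annotation strings (missense / synonymous /
other-genic / intergenic; the first, most severe annotation wins).

The quality filter requires depth > 10 **and** alternate reads > 3, both
strict inequalities, and fails records with unknown DP/AD. Treating
unknown as failure is deliberate: a missing annotation in a relative could
otherwise delete a match and spuriously inflate the proband-specific set —
in fact even with this rule, relatives' records that fail the filter leak a
small number of truly inherited variants into the specific set (about 1–2%
of matches at Poisson-20 depth). This is a realistic property of
filter-then-compare designs, and the enrichment statistic is robust to it
because the leakage is proportional to per-chromosome variant counts.

The sequencing-artefact argument uses the one-sided binomial upper tail
P(X ≥ alt) for X ~ Binomial(depth, ε), ε = 1% by default. At the study's
cited depth 20 with 10 alternate reads the tail is ≈ 1.9×10⁻¹⁵ — computed,
not asserted; no literature bound is hard-coded.

## Trio partition

A proband variant is specific iff no matching record exists in the mother
or the sibling. Matching defaults to the full allele key
(chrom, pos, ref, alt); position-only matching is available (`match_mode`)
for call sets with inconsistent allele normalisation. Presence in a
relative counts regardless of that relative's zygosity: the contrast is
about presence of the allele in the pedigree, not genotype state. Category
contrasts (het/hom, SNP/Indel, missense/synonymous) are Pearson chi-square
on 2×2 tables without continuity correction (a Yates flag exists); records
with undefined labels are excluded from the table and counted.

A gene is a *specific gene* when it overlaps at least one specific variant
and no non-specific variant. Note that this is a sparse-data notion: at
realistic variant densities most genes overlap some shared variant, so the
specific-gene set is small, and on compact synthetic genomes it is usually
empty — in that case the dN Kolmogorov–Smirnov contrast between specific
and non-specific genes is reported as null rather than fabricated.

## Chromosome enrichment and transmission inference

Frequencies are normalised over an explicit chromosome list (default: pig
autosomes 1–18 plus X; the X is configurable since a male proband would
need different handling). Enrichment is F_Hi/F_Ni; each chromosome's
significance is a 1-df chi-square on (this chromosome vs all others) ×
(specific vs non-specific). Chromosomes are called transmitted when
enrichment > 1 and p < 0.05. Multiple testing is deliberately uncorrected
at the default (matching the stated 0.05 decision rule); a Bonferroni flag
is provided. De novo mutations are not subtracted before enrichment — at
~50 genome-wide they cannot move chromosome-share frequencies computed
from ~10⁶ specific variants, though they do matter on the synthetic null
(below). SNPs and Indels are pooled for inference; per-type tables can be
derived from the emitted records.

## Nei–Gojobori divergence

For each sense codon, each position contributes the fraction of its three
possible substitutions that preserve the amino acid to the synonymous site
count; substitutions creating stop codons count as nonsynonymous, so the
per-codon counts always sum to exactly 3. Observed differences between a
codon pair are averaged over all orderings of the differing positions;
orderings passing through a stop codon are excluded (with a fallback to
all orderings, stop steps counted nonsynonymous, in the degenerate case
where every ordering is blocked). Site counts are averaged over the two
sequences. Proportions are corrected with Jukes–Cantor,
d = −(3/4)ln(1 − (4/3)p); p ≥ 3/4 yields NaN with a warning rather than an
error. Inputs must be equal-length, gap-free, in-frame and stop-free, and
violations raise immediately — the estimator refuses to guess an
alignment. A maximum-likelihood codon model would differ mainly at high
divergence and for transition/transversion bias; for ranking genes by
constraint the counting estimator is adequate, deterministic, and
verifiable by hand, and it agrees with an independent implementation
(Biopython's NG86) to 10⁻⁹ in the test suite.

The per-gene missense/synonymous ratio uses proband-specific SNPs only and
is emitted for genes with at least one of each (configurable to
synonymous ≥ 1), following the restriction to genes where the ratio is
defined. Spearman's rho (average ranks, t approximation) relates it to dN.

## Conservation

The orthologous-site map is a minimal block format (source chrom/start,
target chrom/start, length, strand; 1-based) rather than full UCSC chain
parsing — it is bit-exactly testable, inverts trivially, and a chain-file
converter can be layered on without touching the mapping logic. Mapping is
strand-aware offset arithmetic; positions outside every block are
unmapped. Conservation at a site is strict base identity; ambiguity codes
are excluded and counted.

Codon columns are summarised per clade by the share of species carrying
the majority codon (ties broken lexicographically, so the profile is
independent of species order). The pattern classes use one identity
threshold (default 0.9; no quantitative definition of "relatively
conserved" exists to import, so this is a config value): conserved
everywhere, conserved in the focal clade only (the mammal-conserved /
lower-vertebrate-variable signature of the BMP7 Arg73Pro column),
variable everywhere, or other. The majority codon — not any reference
species' codon — anchors identity, so a single derived lineage cannot flip
its clade to variable. Gene-tree rate summaries are per-clade means of
root-to-tip path lengths with ratios to a reference clade (mammals);
ultrametric trees give equal means, and the statistic is linear in branch
lengths.

The flanking window for associating intergenic variants with a nearby
candidate gene defaults to 50 kb, a typical cis-regulatory neighbourhood;
no distance is prescribed by the source analysis.

## Synthetic trio generator

The generator emulates exactly the structure the inference relies on:

- **Karyotype**: 18 autosomes + X at approximate real pig lengths
  (2.27 Gb total).
- **Variant pools per chromosome**: pedigree-shared variants (default
  10,000; homozygous-tending, present in all three individuals),
  mother-private and father-private sets (default 5,000 each, split evenly
  between the parent's two homologs).
- **Meiosis**: one draw per chromosome per parent at probability 0.5. On
  the designated causal chromosomes (default chr7 and chr17) the proband
  always receives paternal homolog A and the sibling homolog B. On
  non-causal chromosomes the sibling shares the proband's paternal
  homolog by default (`sibling_coupled=True`): this is the single-family
  configuration in which exactly the causal chromosomes are differentially
  inherited, which is the scenario the enrichment statistic is meant to
  recover. With fully independent draws, roughly half the non-causal
  chromosomes would also be genuinely differentially inherited and would
  be correctly — but uninformatively — called; that mode remains available
  for studying the statistic itself. Maternal draws are always
  independent, and an optional Poisson crossover count per chromosome
  turns whole-chromosome assortment into mosaic transmission for
  robustness experiments.
- **De novo mutations**: Poisson(rate × diploid genome length), uniform in
  the genome, always heterozygous; default rate 10⁻⁸ per nucleotide per
  generation (≈ 45 mutations on the default genome, below 100 in ≫95% of
  individuals at 2.5 Gb).
- **Zygosity and read support**: specific-origin variants are labelled
  heterozygous with probability 0.894 and others 0.702, reproducing the
  observed zygosity mix phenomenologically; depth is Poisson(20),
  heterozygous alternate reads Binomial(depth, 0.5), homozygous sites lose
  only error-rate reads (ε = 1%).
- **Truth**: haplotype choices, per-homolog allele keys and de novo labels
  go to a sidecar TSV, never into the VCFs.

Byte-identical output under identical configuration (including seed) is a
tested contract.

**Scale.** The per-chromosome defaults (5,000 + 5,000 parent-private,
10,000 shared) are roughly 5× smaller per chromosome than the real
sequencing study while preserving every ratio the statistics depend on;
one full trio simulates in ~3 s, which keeps the 100-trio recovery suite
and the 1,000-trio null calibration practical on a single CPU. The
recovery property — simulate, filter, partition, enrich, infer returns
exactly the causal set — holds in ≥95 of 100 seeded runs at these
defaults.

**Null calibration.** The null configuration uses 19 equal-length
chromosomes and a raised de novo rate (10⁻⁷) so each chromosome expects
~25 specific variants: with the biological rate the null specific set is
~50 variants genome-wide and the 2×2 chi-square is outside its asymptotic
regime. Equal lengths keep de novo placement (∝ length) proportional to
the per-chromosome non-specific counts (constant per chromosome), which is
the proportional-null the test is calibrated against. Under this
configuration each chromosome rejects at α = 0.05 in ≈5% of 1,000 trios.

**Ortholog pairs** evolve one random stop-free CDS into another by
applying Poisson(target × site count) synonymous and nonsynonymous
single-nucleotide events, codons chosen proportionally to their current
site counts and stop codons never created. Multiple hits accrue
naturally; two-fold degenerate sites toggle rather than diffuse over three
states, which biases recovered dS down by a few percent at dS = 0.3 —
well inside the 15% recovery tolerance tested at ~10 kb.

**Clade alignments** draw one ancestral sense codon per column and
substitute it per species at 2% (mammals) or 50% (other clades). Defaults
use 10 mammal and 6 species per other clade: enough that a non-mammal
clade is rarely identical by chance (0.5⁶ ≈ 1.6%) and that a single mammal
substitution leaves identity at 0.9, so ~92% of columns classify as
mammal-conserved analytically (≥80% is the tested bound).

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of a re-sequenced
trio, not its artefacts: no alignment or mapping errors, no multi-allelic
complexity, no genotyping-caller idiosyncrasies, no linkage disequilibrium
within haplotypes, no population structure in the shared pool, and
whole-chromosome transmission by default (real meioses recombine).
Recovery of causal chromosomes on synthetic data therefore demonstrates
the correctness and calibration of the statistics, not robustness to real
sequencing pathologies. Conversely, nothing in the pipeline can see the
truth sidecar, so recovery is earned, not leaked.

## Pipeline

`run_pipeline` executes simulate → classify → enrich → diverge → conserve
with an enforced dependency graph, writes `report.json` (sorted keys, no
timestamps — reruns are byte-identical), per-stage TSV tables and the
resolved YAML config, and logs seeds and stage timings to stderr. Every
reported statistic is produced by one of the library calls above; the
specific percentage in the report equals 100·|specific|/total rounded to
one decimal by construction. In the simulate stage, genic SNPs are
assigned missense effects with probability increasing in the gene's
simulated dN (and synonymous effects at a flat 0.15), so the positive
dN vs mis/syn rank correlation emerges in the report for the causal-
chromosome genes; with few informative genes the correlation is reported
with its n and can be noisy at very small scale.

## Known limitations

- NG86 assumes equal base frequencies and no transition/transversion
  bias; dN/dS at saturation (p ≥ 3/4) is undefined by design.
- The enrichment test treats variants as independent; within a
  transmitted haplotype they are perfectly linked, so the chi-square
  p-values on real data overstate certainty (a genome-scale transmission
  call should rest on effect size, not the p-value).
- Zygosity in the generator is phenomenological (labels drawn at the
  observed fractions), not a consequence of population allele
  frequencies.
- The site map handles colinear blocks only — no inversions within
  blocks, no many-to-one mappings.
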