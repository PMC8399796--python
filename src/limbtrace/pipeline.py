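"""End-to-end orchestration: simulate -> classify -> enrich -> diverge -> conserve.

Each stage is a thin wrapper over the library modules; the run produces a
machine-readable JSON report plus TSV tables, and reruns with the same
configuration are byte-identical.  Stage outputs flow in memory; the
dependency graph is enforced (e.g. enrichment refuses to run without the
classification stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import assortment, conservation, divergence, synthetic, trio_classify
from .variant_model import (
    MISSENSE, OTHER_GENIC, SNP, SYNONYMOUS,
    GeneInterval, VariantRecord, passes_quality_filter,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "classify", "enrich", "diverge", "conserve")
_STAGE_DEPS = {
    "classify": ("simulate",),
    "enrich": ("classify",),
    "diverge": ("simulate", "classify"),
    "conserve": ("simulate", "classify"),
}


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    out_dir: str = "limbtrace_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    # variant-level quality filter
    min_depth: int = 10
    min_alt: int = 3
    error_rate: float = 0.01
    # trio partition
    match_mode: str = "allele"
    # enrichment / transmission call
    alpha: float = 0.05
    min_enrichment: float = 1.0
    bonferroni: bool = False
    # gene geography / divergence
    n_genes_per_chrom: int = 5
    gene_length: int = 100_000
    ortholog_codons: int = 300
    ortholog_ds: float = 0.3
    # conservation stage
    window: int = 50_000
    identity_threshold: float = 0.9
    focal_clade: str = "mammal"
    conserved_prob_candidate: float = 0.9
    conserved_prob_other: float = 0.6
    n_alignment_columns: int = 100
    # effect-annotation model for simulated genic variants
    synonymous_prob: float = 0.15
    missense_coef: float = 2.0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "chromosomes" in sim_raw:
            sim_raw["chromosomes"] = tuple(
                (str(n), int(l)) for n, l in sim_raw["chromosomes"])
        if "causal_chromosomes" in sim_raw:
            sim_raw["causal_chromosomes"] = tuple(sim_raw["causal_chromosomes"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw, sim=synthetic.SimConfig(**sim_raw))
        return cfg

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        data["sim"]["chromosomes"] = [list(c) for c in self.sim.chromosomes]
        data["sim"]["causal_chromosomes"] = list(self.sim.causal_chromosomes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _check_stage_deps(stages: Sequence[str]) -> None:
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}; valid stages: {ALL_STAGES}")
        for dep in _STAGE_DEPS.get(s, ()):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r} to run first")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _contingency_dict(res: trio_classify.ContingencyResult) -> dict[str, Any]:
    return {
        "rows": list(res.row_labels),
        "cols": list(res.col_labels),
        "table": res.table.astype(int).tolist(),
        "fractions": [[round(x, 6) for x in row] for row in res.fractions.tolist()],
        "chi_square": None if np.isnan(res.chi_square) else round(res.chi_square, 6),
        "p_value": None if np.isnan(res.p_value) else float(res.p_value),
        "n_excluded": res.n_excluded,
        "degenerate": res.degenerate,
    }


def _annotate_effects(
    records: list[VariantRecord],
    genes: Sequence[GeneInterval],
    gene_dn: dict[str, float],
    rng: np.random.Generator,
    synonymous_prob: float,
    missense_coef: float,
) -> list[VariantRecord]:
    """Assign coding effects to simulated variants falling inside genes.

    Genic SNPs become missense with probability proportional to the gene's
    divergence (so constrained genes accumulate fewer missense changes -
    the pattern the rank correlation stage is meant to detect), synonymous
    with a flat probability, otherwise other_genic; intergenic variants
    keep the default label.
    """
    assignments = conservation.assign_to_genes(records, genes, window=0)
    max_dn = max(gene_dn.values()) or 1.0
    out = []
    draws = rng.random(len(records))
    for rec, asn, u in zip(records, assignments, draws):
        if asn.status != conservation.GENIC:
            out.append(rec)
            continue
        if rec.vtype != SNP:
            out.append(rec._replace(effect=OTHER_GENIC))
            continue
        p_mis = min(0.7, missense_coef * gene_dn[asn.gene_ids[0]] / max_dn * 0.3)
        if u < p_mis:
            out.append(rec._replace(effect=MISSENSE))
        elif u < p_mis + synonymous_prob:
            out.append(rec._replace(effect=SYNONYMOUS))
        else:
            out.append(rec._replace(effect=OTHER_GENIC))
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages and write report.json + tables.

    Returns the report dictionary.  Any stage failure aborts with the
    stage name attached.
    """
    _check_stage_deps(config.stages)
    os.makedirs(config.out_dir, exist_ok=True)
    tables_dir = os.path.join(config.out_dir, "tables")
    os.makedirs(tables_dir, exist_ok=True)

    report: dict[str, Any] = {
        "seed": config.seed,
        "stages": list(config.stages),
        "filter": {"min_depth": config.min_depth, "min_alt": config.min_alt,
                   "error_rate": config.error_rate},
        "match_mode": config.match_mode,
    }
    state: dict[str, Any] = {}

    for stage in config.stages:
        t0 = time.monotonic()
        try:
            _STAGE_FUNCS[stage](config, state, report, tables_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)

    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config.to_yaml(os.path.join(config.out_dir, "resolved_config.yaml"))
    return report


def _stage_simulate(config, state, report, tables_dir):
    sim_cfg = replace(config.sim, seed=synthetic.derive_seed(config.seed, "trio"))
    sim = synthetic.simulate_trio(sim_cfg)
    rng = np.random.default_rng(synthetic.derive_seed(config.seed, "annot"))
    genes = synthetic.simulate_genes(sim_cfg, rng, n_per_chrom=config.n_genes_per_chrom,
                                     gene_length=config.gene_length)
    # per-gene divergence targets: lognormal around a few percent
    dn_rng = np.random.default_rng(synthetic.derive_seed(config.seed, "dn"))
    gene_dn = {
        g.gene_id: float(np.clip(dn_rng.lognormal(mean=np.log(0.03), sigma=0.8), 1e-3, 0.5))
        for g in genes
    }
    sim.proband = _annotate_effects(sim.proband, genes, gene_dn, rng,
                                    config.synonymous_prob, config.missense_coef)
    sim.mother = _annotate_effects(sim.mother, genes, gene_dn, rng,
                                   config.synonymous_prob, config.missense_coef)
    sim.sibling = _annotate_effects(sim.sibling, genes, gene_dn, rng,
                                    config.synonymous_prob, config.missense_coef)
    paths = synthetic.write_trio_vcfs(sim, os.path.join(config.out_dir, "inputs"))
    synthetic.write_gtf(genes, os.path.join(config.out_dir, "inputs", "genes.gtf"))
    state.update(sim=sim, genes=genes, gene_dn=gene_dn)
    report["simulate"] = {
        "causal_chromosomes": list(sim_cfg.causal_chromosomes),
        "sim_seed": sim_cfg.seed,
        "n_records": {"M": len(sim.mother), "S": len(sim.sibling), "H": len(sim.proband)},
        "n_de_novo": {k: len(v) for k, v in sim.truth.de_novo.items()},
        "input_digests": {k: _sha256(p) for k, p in sorted(paths.items())},
    }


def _stage_classify(config, state, report, tables_dir):
    sim = state["sim"]
    filt = lambda recs: [r for r in recs
                         if passes_quality_filter(r, config.min_depth, config.min_alt)]
    proband, mother, sibling = filt(sim.proband), filt(sim.mother), filt(sim.sibling)
    partition = trio_classify.partition_specific(proband, mother, sibling,
                                                 match_mode=config.match_mode)
    state["partition"] = partition
    contrasts = {
        "zygosity": trio_classify.category_contrast(partition, trio_classify.zygosity_label),
        "variant_type": trio_classify.category_contrast(partition, trio_classify.variant_type_label),
        "coding": trio_classify.category_contrast(partition, trio_classify.coding_label),
    }
    report["classify"] = {
        "n_filtered": {"H": len(proband), "M": len(mother), "S": len(sibling)},
        "totals": partition.totals,
        "specific_percent": partition.specific_percent,
        "contrasts": {k: _contingency_dict(v) for k, v in contrasts.items()},
    }


def _stage_enrich(config, state, report, tables_dir):
    partition = state["partition"]
    chroms = [n for n, _ in config.sim.chromosomes]
    enr = assortment.chromosome_enrichment(partition, chroms)
    called = assortment.infer_transmitted(enr, alpha=config.alpha,
                                          min_enrichment=config.min_enrichment,
                                          bonferroni=config.bonferroni)
    df = pd.DataFrame(
        [(e.chrom, e.h_count, e.n_count, e.f_h, e.f_n, e.enrichment, e.chi_square,
          e.p_value, e.chrom in called) for e in enr],
        columns=["chrom", "H_i", "N_i", "F_Hi", "F_Ni", "enrichment", "chi_square",
                 "p_value", "called_transmitted"],
    )
    df.to_csv(os.path.join(tables_dir, "enrichment.tsv"), sep="\t", index=False,
              float_format="%.6g")
    report["enrich"] = {
        "transmitted": called,
        "table": {e.chrom: {"H_i": e.h_count, "N_i": e.n_count,
                            "enrichment": None if np.isnan(e.enrichment) else round(e.enrichment, 4),
                            "p_value": None if np.isnan(e.p_value) else float(e.p_value)}
                  for e in enr},
    }


def _stage_diverge(config, state, report, tables_dir):
    partition, genes = state["partition"], state["genes"]
    gene_dn = state["gene_dn"]
    pairs = {}
    for g in genes:
        seed = synthetic.derive_seed(config.seed, "orth", g.gene_id)
        pairs[g.gene_id] = synthetic.simulate_ortholog_pair(
            config.ortholog_codons, config.ortholog_ds, gene_dn[g.gene_id], seed=seed)
    df = divergence.divergence_table(pairs, partition, genes)
    df.to_csv(os.path.join(tables_dir, "divergence.tsv"), sep="\t", index=False,
              float_format="%.6g")
    spec_genes, nonspec_genes = trio_classify.gene_specific_sets(partition, genes)
    ks_entry = None
    dn_spec = df[df.gene_id.isin(spec_genes)]["dn"].dropna()
    dn_nonspec = df[df.gene_id.isin(nonspec_genes)]["dn"].dropna()
    if len(dn_spec) and len(dn_nonspec):
        d, p = divergence.ks_compare(dn_spec, dn_nonspec)
        ks_entry = {"D": round(d, 6), "p_value": p,
                    "n_specific_genes": int(len(dn_spec)),
                    "n_nonspecific_genes": int(len(dn_nonspec))}
    corr_entry = None
    sub = df.dropna(subset=["mis_syn_ratio", "dn"]) if "mis_syn_ratio" in df else df.iloc[0:0]
    if len(sub) >= 3:
        rho, p = divergence.rank_correlation(sub["dn"], sub["mis_syn_ratio"])
        corr_entry = {"rho": round(rho, 6), "p_value": p, "n_genes": int(len(sub))}
    report["diverge"] = {
        "n_genes": int(len(df)),
        "ks_dn_specific_vs_nonspecific": ks_entry,
        "spearman_dn_vs_mis_syn": corr_entry,
    }


def _stage_conserve(config, state, report, tables_dir):
    partition, genes = state["partition"], state["genes"]
    sim_cfg = state["sim"].config
    rng = np.random.default_rng(synthetic.derive_seed(config.seed, "conserve"))

    causal = set(sim_cfg.causal_chromosomes)
    focus = [r for r in partition.specific if r.chrom in causal] or partition.specific
    focus_genes = [g for g in genes if g.chrom in causal] or list(genes)
    assignments = conservation.assign_to_genes(focus, focus_genes, window=config.window)

    # synthetic orthologous bases: conserved with a higher probability on
    # candidate genes than elsewhere
    site_map = _gene_site_map(focus_genes, config.window)
    candidate_ids = {g.gene_id for g in focus_genes if g.is_candidate}
    candidate_flags: list[bool | None] = []
    other_flags: list[bool | None] = []
    n_unmapped = 0
    for rec, asn in zip(focus, assignments):
        if asn.status == conservation.UNASSIGNED:
            continue
        if conservation_map_misses(site_map, rec):
            n_unmapped += 1
            continue
        is_cand = any(gid in candidate_ids for gid in asn.gene_ids)
        p = config.conserved_prob_candidate if is_cand else config.conserved_prob_other
        if rng.random() < p:
            target = rec.ref[0]
        else:
            target = {"A": "G", "C": "T", "G": "A", "T": "C"}.get(rec.ref[0], "N")
        flag = conservation.conserved_at(rec.ref[0], target)
        (candidate_flags if is_cand else other_flags).append(flag)
    contrast = conservation.conserved_fraction_contrast(candidate_flags, other_flags)

    columns, labels = synthetic.simulate_clade_columns(config.n_alignment_columns, rng)
    patterns: dict[str, int] = {}
    for i, col in enumerate(columns):
        prof = conservation.clade_codon_pattern(
            col, labels, identity_threshold=config.identity_threshold,
            focal_clade=config.focal_clade, column_id=i)
        patterns[prof.pattern] = patterns.get(prof.pattern, 0) + 1
    newick, tree_labels = synthetic.simulate_clade_tree(rng)
    rates = conservation.clade_branch_rates(newick, tree_labels,
                                            reference_clade=config.focal_clade)
    rates.to_csv(os.path.join(tables_dir, "clade_rates.tsv"), sep="\t",
                 float_format="%.6g")
    status_counts = {}
    for asn in assignments:
        status_counts[asn.status] = status_counts.get(asn.status, 0) + 1
    report["conserve"] = {
        "site_status": status_counts,
        "n_unmapped_sites": n_unmapped,
        "conserved_fraction_contrast": _contingency_dict(contrast),
        "codon_patterns": dict(sorted(patterns.items())),
        "clade_rate_ratio_to_focal": {
            c: round(float(v), 4) for c, v in rates["ratio_to_reference"].items()},
    }


def _gene_site_map(genes: Sequence[GeneInterval], window: int) -> conservation.SiteMap:
    """An identity-offset site map covering each gene and its flanks."""
    blocks = []
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append((max(1, g.start - window), g.end + window))
    for chrom, ivs in spans.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            blocks.append(conservation.MapBlock(chrom, s, "t" + chrom, s + 1000,
                                                e - s + 1, "+"))
    return conservation.SiteMap(blocks)


def conservation_map_misses(site_map: conservation.SiteMap, rec: VariantRecord) -> bool:
    """True when the variant position has no orthologous coordinate."""
    return site_map.map_site(rec.chrom, rec.pos) is None


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
    "diverge": _stage_diverge,
    "conserve": _stage_conserve,
}
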