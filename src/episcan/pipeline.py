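"""End-to-end orchestration of the interaction-study analysis plan.

Stages, in order: per-cohort QC (pooled MAF over discovery + filter
cohorts) -> discovery scan at |t| >= 5 -> per-cohort refit and
fixed-effects meta-analysis filter at p < 1e-8 -> LD pruning of interaction
terms at r^2 > 0.8 -> Bonferroni bar 0.05/m -> replication meta-analysis in
the held-out cohorts -> medication case-control check and directional
triage. Every intermediate table is persisted as delimited text; a
machine-readable summary records the per-stage counts and the
multiple-testing ledger (the implied p at |t| = 5, the filter cut, the
Bonferroni bar, and the proposed genome-wide interaction significance level
1e-13 as a reference line).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .genodata import qc_filter, read_glide_matrix
from .medcheck import casecontrol_combined, classify_consistency, wald_p
from .metafilter import (
    MetaResult,
    filter_candidates,
    fixed_effects_meta,
    meta_to_frame,
    prune_interaction_terms,
    refit_pair,
)
from .pairscan import ScanConfig, results_to_frame, scan_pairs, scan_pooled, t_to_p
from .phenoprep import adjusted_cohort
from .replicate import replicate_all, report_to_frame
from .synthcohort import CohortData

__all__ = ["PipelineConfig", "load_cohort", "run_pipeline", "compare_onestep_twostep"]

log = logging.getLogger(__name__)

GWIS_REFERENCE_ALPHA = 1e-13  # proposed genome-wide significance level for a GWIS


@dataclass(frozen=True)
class PipelineConfig:
    """Cohort roles and stage thresholds for one run."""

    discovery: str
    filter_cohorts: tuple[str, ...]
    replication_cohorts: tuple[str, ...]
    scan: ScanConfig = ScanConfig()
    filter_p: float = 1e-8
    prune_r2: float = 0.8
    maf_min: float = 0.05
    callrate_min: float = 0.95
    hwe_min: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        roles = [self.discovery, *self.filter_cohorts, *self.replication_cohorts]
        if len(set(roles)) != len(roles):
            raise ValueError("cohort roles must be disjoint")
        if self.filter_p <= 0 or self.prune_r2 <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scan = ScanConfig(**raw.pop("scan", {}))
        raw["filter_cohorts"] = tuple(raw.get("filter_cohorts", ()))
        raw["replication_cohorts"] = tuple(raw.get("replication_cohorts", ()))
        return cls(scan=scan, **raw)


def load_cohort(
    genotype_path, snp_names_path, pheno_path, name: str, include_medicated: bool = False
) -> CohortData:
    """Read one cohort from the GLIDE genotype layout + phenotype table."""
    G = read_glide_matrix(genotype_path, snp_names_path)
    table = pd.read_csv(pheno_path, sep="\t")
    if len(table) != G.n_individuals:
        raise ValueError(
            f"{name}: phenotype rows ({len(table)}) != genotype columns ({G.n_individuals})"
        )
    return CohortData(name, G, table, include_medicated=include_medicated)


def _by_name(cohorts: list[CohortData]) -> dict[str, CohortData]:
    return {c.name: c for c in cohorts}


def run_pipeline(cohorts: list[CohortData], cfg: PipelineConfig, out_dir) -> dict:
    """Run every stage, persist all tables under ``out_dir``, return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        lines.append(msg)

    pool = _by_name(cohorts)
    missing = [
        n
        for n in (cfg.discovery, *cfg.filter_cohorts, *cfg.replication_cohorts)
        if n not in pool
    ]
    if missing:
        raise ValueError(f"cohorts not provided: {missing}")
    disc = pool[cfg.discovery]
    filt = [pool[n] for n in cfg.filter_cohorts]
    repl = [pool[n] for n in cfg.replication_cohorts]
    stage_cohorts = [disc, *filt]

    # --- QC: per-cohort call rate and HWE, MAF pooled over discovery + filter
    qc_kept: list[set[str]] = []
    for c in stage_cohorts:
        others = [o.genotypes for o in stage_cohorts if o is not c]
        filtered, report = qc_filter(
            c.genotypes,
            maf_min=cfg.maf_min,
            callrate_min=cfg.callrate_min,
            hwe_min=cfg.hwe_min,
            maf_pooled_over=others or None,
        )
        report.to_csv(out / f"qc_{c.name}.tsv")
        qc_kept.append(set(filtered.snp_names))
        note(f"qc[{c.name}]: kept {len(filtered.snp_names)}/{c.genotypes.n_snps} SNPs")
    keep_names = [n for n in disc.genotypes.snp_names if all(n in s for s in qc_kept)]
    note(f"qc: {len(keep_names)} SNPs pass in every discovery/filter cohort")

    def restrict(c: CohortData) -> CohortData:
        return CohortData(
            c.name, c.genotypes.subset_snps(keep_names), c.table, c.include_medicated
        )

    disc_q = restrict(disc)
    filt_q = [restrict(c) for c in filt]

    # --- discovery scan (scaled residuals)
    Gd, adj = adjusted_cohort(disc_q, scaled=True)
    hits = scan_pairs(Gd, adj, cfg.scan)
    results_to_frame(hits).to_csv(out / "scan_hits.tsv", sep="\t", index=False)
    scan_p = t_to_p(cfg.scan.t_threshold, adj.n - 4)
    note(
        f"scan[{disc.name}]: {len(hits)} hits at |t| >= {cfg.scan.t_threshold} "
        f"(p < {scan_p:.3g}, n = {adj.n})"
    )

    # --- meta-analysis filter over discovery + filter cohorts
    meta: list[MetaResult] = []
    for h in hits:
        fits = [refit_pair(c, (h.snp1, h.snp2), scaled=True) for c in [disc_q, *filt_q]]
        if not any(f is not None for f in fits):
            continue
        meta.append(fixed_effects_meta(fits, h.snp1, h.snp2))
    meta_to_frame(meta).to_csv(out / "meta_all.tsv", sep="\t", index=False)
    filtered_terms = filter_candidates(meta, cfg.filter_p)
    meta_to_frame(filtered_terms).to_csv(out / "meta_filtered.tsv", sep="\t", index=False)
    note(f"filter: {len(filtered_terms)} terms with pooled p < {cfg.filter_p:g}")

    # --- LD pruning and the Bonferroni bar
    prune = prune_interaction_terms(filtered_terms, disc_q.genotypes, cfg.prune_r2)
    meta_to_frame(prune.kept).to_csv(out / "terms_pruned.tsv", sep="\t", index=False)
    if prune.m_effective:
        bonferroni = prune.bonferroni_alpha
        note(
            f"prune: {prune.m_effective} unique terms (r^2 > {cfg.prune_r2}); "
            f"Bonferroni alpha = {bonferroni:.3g}"
        )
    else:
        bonferroni = 0.05
        note("prune: no terms to carry forward")

    # --- replication in held-out cohorts
    entries = replicate_all(prune.kept, repl, bonferroni) if repl else []
    rep_frame = report_to_frame(entries)
    rep_frame.to_csv(out / "replication.tsv", sep="\t", index=False)
    n_replicated = int(rep_frame["replicated"].sum()) if len(rep_frame) else 0
    n_nominal = int(rep_frame["nominal"].sum()) if len(rep_frame) else 0
    note(f"replication: {n_replicated} replicated, {n_nominal} nominal of {len(entries)}")

    # --- medication case-control + directional triage
    cc_rows = []
    n_consistent = 0
    for e in entries:
        try:
            fit = casecontrol_combined(stage_cohorts, (e.snp1, e.snp2))
        except (ValueError, RuntimeError) as exc:
            note(f"casecontrol[{e.snp1}-{e.snp2}]: skipped ({exc})")
            continue
        b, se, _ = fit["interaction"]
        row = {
            "snp1": e.snp1,
            "snp2": e.snp2,
            "cc_beta": b,
            "cc_se": se,
            "cc_p": wald_p(b, se),
            "verdict": "",
        }
        if e.replication is not None:
            call = classify_consistency(
                "+" if e.discovery.beta >= 0 else "-",
                "+" if e.replication.beta >= 0 else "-",
                "+" if b >= 0 else "-",
                e.snp1,
                e.snp2,
            )
            row["verdict"] = call.verdict
            n_consistent += call.verdict == "consistent"
        cc_rows.append(row)
    pd.DataFrame(
        cc_rows, columns=["snp1", "snp2", "cc_beta", "cc_se", "cc_p", "verdict"]
    ).to_csv(out / "casecontrol.tsv", sep="\t", index=False)
    note(f"casecontrol: {n_consistent} directionally consistent terms")

    summary = {
        "n_snps_post_qc": len(keep_names),
        "scan_hits": len(hits),
        "filtered_terms": len(filtered_terms),
        "m_effective": prune.m_effective,
        "replicated_terms": n_replicated,
        "nominal_terms": n_nominal,
        "consistent_terms": n_consistent,
        "thresholds": {
            "scan_t": cfg.scan.t_threshold,
            "scan_p_implied": float(scan_p),
            "filter_p": cfg.filter_p,
            "prune_r2": cfg.prune_r2,
            "bonferroni_alpha": float(bonferroni),
            "gwis_reference_alpha": GWIS_REFERENCE_ALPHA,
        },
        "seed": cfg.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "log.txt").write_text("\n".join(lines) + "\n")
    return summary


def compare_onestep_twostep(
    cohorts: list[CohortData], cfg: PipelineConfig, out_dir=None
) -> dict:
    """Discovery-only scan vs pooled one-step scan at the same threshold.

    Reports the hit counts of both strategies and the overlap of their hit
    sets (pairs found by both).
    """
    pool = _by_name(cohorts)
    disc = pool[cfg.discovery]
    combined = [disc] + [pool[n] for n in cfg.filter_cohorts]
    if len(combined) < 2:
        raise ValueError("one-step comparison needs at least 2 cohorts")
    Gd, adj = adjusted_cohort(disc, scaled=True)
    single = scan_pairs(Gd, adj, cfg.scan)
    pooled = scan_pooled(combined, cfg.scan, scaled=True)
    set_single = {(r.snp1, r.snp2) for r in single}
    set_pooled = {(r.snp1, r.snp2) for r in pooled}
    report = {
        "single_hits": len(set_single),
        "pooled_hits": len(set_pooled),
        "overlap": len(set_single & set_pooled),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "onestep_twostep.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
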