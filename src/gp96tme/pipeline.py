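"""End-to-end orchestration of the three analyses.

Each pipeline is a pure function of (config, seed): it loads or
generates its inputs, writes every intermediate table as CSV next to a
versioned JSON report, and logs the record-count funnel at each stage
(cores quantified → patients with follow-up → survival analyses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gi_score, group_stats, interferon, io, spatial, synthetic_data
from .quantify import quantification_table

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Single configuration for all three pipelines.

    For each data stream, give either real input paths or a synthetic
    block (kwargs of the matching generator config) — not both.
    """

    seed: int = 0
    outdir: str = "gp96tme_out"
    # TMA stream
    cells_csv: str | None = None
    clinical_csv: str | None = None
    synthetic_cohort: dict | None = field(default_factory=dict)
    cutpoint_epsilon: float = 0.1
    cutpoint_permutations: int = 199
    gi_mode: str = "maxstat"
    # expression stream
    expression_tsv: str | None = None
    gene_sets_gmt: str | None = None
    deg_csv: str | None = None
    synthetic_expression: dict | None = field(default_factory=dict)
    deg_group_size: int = 100   # top/bottom gp96 groups for the synthetic DE table
    conditioning_subset_size: int = 200
    conditioning_n_random: int = 1000
    # spatial stream
    synthetic_spatial: dict | None = field(default_factory=dict)
    n_spatial_cores: int = 5
    spatial_bin_width: float = 5.0
    spatial_max_distance: float = 100.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def _check_stream(self, paths: list[str | None], synth: dict | None, name: str) -> bool:
        """True if the stream is synthetic; validates exclusivity."""
        have_paths = any(p is not None for p in paths)
        if have_paths and not all(p is not None for p in paths):
            raise ValueError(f"{name}: all input paths must be given together")
        if have_paths and synth:
            raise ValueError(f"{name}: give either input paths or a synthetic block, not both")
        return not have_paths


def _write_report(report: dict, path: Path) -> None:
    report["schema_version"] = REPORT_SCHEMA_VERSION
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def _grade_comparisons(quant: pd.DataFrame, clinical: pd.DataFrame) -> dict:
    clin = clinical.set_index("patient_id")
    merged = quant.join(clin["grade"], how="inner")
    out = {}
    for col in ("gp96_extent", "cd4_density", "cd8_density", "pd1_density"):
        groups = [merged.loc[merged["grade"] == g, col].to_numpy()
                  for g in (2, 3, 4)]
        if min(len(g) for g in groups) < 2:
            out[col] = {"skipped": "a grade group has < 2 specimens"}
            continue
        omnibus, pairwise = group_stats.kruskal_wallis_posthoc(groups)
        out[col] = {
            "kruskal_H": omnibus.statistic, "p": omnibus.p_value,
            "group_sizes": list(omnibus.group_sizes),
            "pairwise_bonferroni": [
                {"grades": [2, 3, 4][p["groups"][0]:p["groups"][0] + 1]
                           + [[2, 3, 4][p["groups"][1]]],
                 "p_adjusted": p["p_bonferroni"]} for p in pairwise],
        }
    return out


def run_tma_pipeline(config: PipelineConfig) -> dict:
    """Quantification → cutpoints → GI score → stratified survival."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = config._check_stream([config.cells_csv, config.clinical_csv],
                                 config.synthetic_cohort, "tma")
    if synth:
        cfg = synthetic_data.SyntheticCohortConfig(
            **{"seed": config.seed, **(config.synthetic_cohort or {})})
        cores, clinical = synthetic_data.generate_cohort(cfg)
        io.write_cores(cores, outdir / "cells.csv")
        io.write_clinical(clinical, outdir / "clinical.csv")
    else:
        cores = io.read_cores(config.cells_csv)
        clinical = io.read_clinical(config.clinical_csv)

    quant = quantification_table(cores)
    quant.to_csv(outdir / "quantification.csv")
    n_total = len(quant)
    complete = clinical["os_months"].notna()
    n_complete = int(complete.sum())

    gi = gi_score.build_gi_table(quant, clinical, mode=config.gi_mode,
                                 epsilon=config.cutpoint_epsilon)
    gi.to_csv(outdir / "gi_table.csv")
    cut_rows = [{"marker": ind, "cutoff": float(gi[ind.replace('_high', '_cutoff')].iloc[0]),
                 "n_high": int(gi[ind].sum()), "n_low": int(n_total - gi[ind].sum())}
                for ind in gi_score.INDICATORS]
    pd.DataFrame(cut_rows).to_csv(outdir / "cutpoints.csv", index=False)

    strata = {}
    for stratum in ("all", "IDHmut-LGG", "IDHwt-GBM"):
        try:
            strata[stratum] = gi_score.gi_stratification(gi, clinical, stratum)
        except (ValueError, RuntimeError) as err:
            strata[stratum] = {"skipped": str(err)}

    report = {
        "pipeline": "tma",
        "seed": config.seed,
        "counts": {
            "cores_quantified": n_total,
            "patients_with_followup": n_complete,
            "followup_complete_pct": round(100.0 * n_complete / len(clinical), 1),
        },
        "cutpoints": cut_rows,
        "grade_comparisons": _grade_comparisons(quant, clinical),
        "gi_strata": strata,
    }
    _write_report(report, outdir / "tma_report.json")
    return report


def synthetic_deg_table(tpm: pd.DataFrame, group_size: int = 100) -> pd.DataFrame:
    """Per-gene DE statistics contrasting the ``group_size`` samples with
    the highest vs lowest anchor-gene (HSP90B1) expression — the study
    design the DEG thresholds are applied to. log2 fold change on the
    log2(TPM+0.1) scale, Mann-Whitney p, Benjamini-Hochberg adjusted."""
    anchor = tpm.loc[interferon.ANCHOR_GENE]
    if 2 * group_size > tpm.shape[1]:
        raise ValueError("group_size too large for the sample count")
    order = anchor.sort_values(kind="stable").index
    low, high = order[:group_size], order[-group_size:]
    log2 = np.log2(tpm + interferon.TPM_PSEUDOCOUNT)
    rows = {}
    for gene in tpm.index:
        a, b = log2.loc[gene, high].to_numpy(), log2.loc[gene, low].to_numpy()
        res = group_stats.mann_whitney(a, b)
        rows[gene] = {"log2fc": float(a.mean() - b.mean()), "p": res.p_value}
    deg = pd.DataFrame(rows).T
    deg["padj"] = group_stats.bh_adjust(deg["p"].to_numpy())
    return deg[["log2fc", "padj"]]


def run_expression_pipeline(config: PipelineConfig) -> dict:
    """DEG filter → shared genes → IPA score → conditioning analysis."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = config._check_stream(
        [config.expression_tsv, config.gene_sets_gmt, config.deg_csv],
        config.synthetic_expression, "expression")
    if synth:
        cfg = synthetic_data.SyntheticExpressionConfig(
            **{"seed": config.seed, **(config.synthetic_expression or {})})
        tpm, _ = synthetic_data.generate_expression(cfg)
        gene_sets = synthetic_data.synthetic_gene_sets(cfg.n_isg_genes)
        deg = synthetic_deg_table(tpm, min(config.deg_group_size, tpm.shape[1] // 3))
        io.write_expression(tpm, outdir / "expression.tsv")
        io.write_gene_sets(gene_sets, outdir / "gene_sets.gmt")
        io.write_deg_table(deg, outdir / "deg_stats.csv")
    else:
        tpm = io.read_expression(config.expression_tsv)
        gene_sets = io.read_gene_sets(config.gene_sets_gmt)
        deg = io.read_deg_table(config.deg_csv)
    if config.conditioning_subset_size > tpm.shape[1]:
        raise ValueError(
            f"conditioning_subset_size {config.conditioning_subset_size} exceeds "
            f"sample count {tpm.shape[1]}")
    if interferon.ANCHOR_GENE not in tpm.index:
        raise ValueError(f"anchor gene {interferon.ANCHOR_GENE} missing from matrix")

    degs = interferon.filter_degs(deg)
    sets = list(gene_sets.values())
    shared = interferon.shared_genes(degs, sets[0], sets[1])
    ipa, missing = interferon.ipa_score(tpm, shared)
    ipa.to_frame().to_csv(outdir / "ipa_scores.csv", index_label="sample_id")

    correlations = {}
    anchor_log2 = np.log2(tpm.loc[interferon.ANCHOR_GENE] + interferon.TPM_PSEUDOCOUNT)
    for m in interferon.MARKER_GENES:
        rho, p = interferon.spearman_correlation(
            anchor_log2, np.log2(tpm.loc[m] + interferon.TPM_PSEUDOCOUNT))
        correlations[m] = {"rho": rho, "p": p}
    rho_ipa, p_ipa = interferon.spearman_correlation(anchor_log2, ipa)
    cond = interferon.conditioning_analysis(
        tpm, ipa, subset_size=config.conditioning_subset_size,
        n_random=config.conditioning_n_random, seed=config.seed)

    report = {
        "pipeline": "expression",
        "seed": config.seed,
        "counts": {"genes": int(tpm.shape[0]), "samples": int(tpm.shape[1]),
                   "degs": len(degs), "shared_degs": len(shared)},
        "shared_genes": shared,
        "ipa_missing_genes": missing,
        "gp96_marker_correlations": correlations,
        "gp96_ipa_correlation": {"rho": rho_ipa, "p": p_ipa},
        "conditioning": {
            "subset_size": cond.subset_size,
            "n_random": cond.n_random,
            "ipa_var_mid": cond.ipa_var_mid,
            "ipa_var_random_mean": cond.ipa_var_random_mean,
            "markers": {m: asdict(r) for m, r in cond.markers.items()},
        },
    }
    _write_report(report, outdir / "expression_report.json")
    return report


def run_spatial_pipeline(config: PipelineConfig) -> dict:
    """Per-core and pooled annulus profiles plus attraction tests."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = config._check_stream([config.cells_csv], config.synthetic_spatial,
                                 "spatial")
    if synth:
        child_seeds = np.random.default_rng(config.seed).integers(
            0, 2**31 - 1, size=config.n_spatial_cores)
        cores = [
            synthetic_data.generate_spatial_pattern(
                synthetic_data.SyntheticSpatialConfig(
                    **{**(config.synthetic_spatial or {}), "seed": int(s)}),
                core_id=f"SP{i}")
            for i, s in enumerate(child_seeds)]
        io.write_cores(cores, outdir / "spatial_cells.csv")
    else:
        cores = io.read_cores(config.cells_csv)

    profiles, per_core, skipped = [], {}, []
    pooled_dist = {"CD4+PD1+": [], "CD4+PD1-": []}
    for core in cores:
        try:
            prof = spatial.annulus_profile(
                core, bin_width=config.spatial_bin_width,
                max_distance=config.spatial_max_distance)
            test = spatial.attraction_test(core)
        except ValueError as err:
            skipped.append({"core_id": core.core_id, "reason": str(err)})
            continue
        profiles.append(prof)
        per_core[core.core_id] = {
            "n_reference": prof.n_reference,
            "n_query": prof.n_total,
            "attraction_U": test.statistic,
            "attraction_p": test.p_value,
        }
        dist = spatial.nearest_reference_distance(core)
        for name, phen in spatial.QUERY_PHENOTYPES.items():
            mask = spatial.phenotype_mask(core.cells, **phen) & \
                ~spatial.phenotype_mask(core.cells, **spatial.REFERENCE_PHENOTYPE)
            pooled_dist[name].append(dist.loc[core.cells.index[mask]].to_numpy())
    if not profiles:
        raise ValueError(f"no usable cores; skipped: {skipped}")
    pooled = spatial.pool_profiles(profiles)
    pooled.to_csv(outdir / "spatial_profile.csv", index=False)
    pooled_test = group_stats.mann_whitney(
        np.concatenate(pooled_dist["CD4+PD1+"]),
        np.concatenate(pooled_dist["CD4+PD1-"]))

    first_bin = pooled[pooled["bin_low"] == 0].set_index("phenotype")["proportion"]
    report = {
        "pipeline": "spatial",
        "seed": config.seed,
        "n_cores": len(profiles),
        "skipped_cores": skipped,
        "per_core": per_core,
        "pooled_attraction": {"U": pooled_test.statistic,
                              "p": pooled_test.p_value,
                              "n": list(pooled_test.group_sizes)},
        "first_bin_proportion": {k: float(v) for k, v in first_bin.items()},
    }
    _write_report(report, outdir / "spatial_report.json")
    return report


def run_all(config: PipelineConfig) -> dict:
    return {
        "tma": run_tma_pipeline(config),
        "expression": run_expression_pipeline(config),
        "spatial": run_spatial_pipeline(config),
    }
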