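# gp96tme

Survival and spatial analysis of gp96 (HSP90B1) expression and T-cell
infiltration in glioma, built as a reusable, fully tested pipeline.

Gliomas that overexpress the endoplasmic-reticulum chaperone gp96 tend to
carry more infiltrating T cells and to have worse outcomes. This package
implements the complete analysis chain that turns multiplexed
immunofluorescence cell tables, clinical follow-up and bulk RNA-seq into
that conclusion:

* **Quantification** — per-core staining extent (positive nuclei / all
  nuclei) and phenotype densities (cells/mm²) from cell-centroid tables
  with binary GFAP/gp96/CD4/CD8/PD-1 phenotypes.
* **Cutpoints** — maximally selected rank statistics: the high/low
  threshold of a marker is the split maximizing the absolute standardized
  two-group log-rank statistic |(O−E)/√V| over all admissible midpoints,
  with a permutation p-value that corrects for the selection.
* **GI score** — the gp96–immune cell score
  `GI = I(gp96 high) + I(CD4 high) + I(PD-1 high) ∈ {0,1,2,3}`,
  stratifying patients into four outcome groups (Kaplan–Meier, 4-group
  log-rank, per-unit Cox HR, and a score-3 indicator adjusted for WHO
  grade and IDH status).
* **Interferon arm** — DEG filtering (|FC| > 2, adjusted p < 0.01), the
  interferon-pathway-activity score
  `IPA(s) = mean_g log2(TPM_gs + 0.1)` over the DEGs shared by the
  hallmark IFN-α and IFN-γ response sets, and a conditioning analysis:
  if interferon activity mediates the gp96–T-cell-marker correlation,
  Spearman ρ(HSP90B1, marker) shrinks in the 200 samples with minimal
  IPA variation relative to 200-sample random subsets.
* **Spatial arm** — nearest-neighbour distances from each T cell to the
  nearest gp96+GFAP+ tumor cell, histogrammed into 5 µm annuli out to
  100 µm, and a Mann–Whitney U test contrasting CD4+PD-1+ against
  CD4+PD-1− distance distributions (attraction test).
* **Synthetic data** — generators for cohorts (Gaussian-copula-linked
  marker levels, Weibull proportional-hazards survival), expression
  matrices (latent interferon activity mediating gp96–marker
  correlations) and point patterns (exp(−d/τ) attraction kernel), all
  with known ground truth, so every stage is testable end to end.

## Worked example

Run the TMA pipeline on a synthetic 234-patient cohort in which 22
patients lack follow-up (the generator's defaults: grade mix 22/21/57%,
cohort median CD4 and CD8 densities 8.7 and 3.6 cells/mm², per-indicator
log hazard ratio ln 1.945):

```bash
gp96tme tma --config example.yaml --seed 1 --outdir out
# example.yaml:
#   synthetic_cohort:
#     n_patients: 234
#     n_missing_followup: 22
```

Trimmed output (full JSON report in `out/tma_report.json`):

```json
{
  "counts": {
    "cores_quantified": 234,
    "patients_with_followup": 212,
    "followup_complete_pct": 90.6
  },
  "gi_strata": {
    "all": {
      "n": 212,
      "groups": {
        "0": {"n": 74, "median_os": 12.3491},
        "1": {"n": 50, "median_os": 4.6775},
        "2": {"n": 56, "median_os": 3.7059},
        "3": {"n": 32, "median_os": 1.3742}
      },
      "logrank": {"chi2": 122.18, "df": 3, "p": 2.6e-26},
      "cox_per_unit": {
        "gi_score": {"hr": 2.197, "ci95_low": 1.875, "ci95_high": 2.575}
      }
    }
  }
}
```

Reading: all 234 cores are quantified, survival stages use the 212
patients (90.6%) with follow-up, and the four GI-score groups separate
sharply — median overall survival falls monotonically with the score,
and each one-point increase multiplies the hazard by ≈ 2.2 (95% CI
1.9–2.6) in this realization. `gp96tme expression` and `gp96tme spatial`
run the other two arms; `gp96tme all` runs everything from one config.

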