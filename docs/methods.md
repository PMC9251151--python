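# Methods

This note documents the statistical models implemented in `gp96tme`,
the synthetic generative models used to exercise them, the defaults and
why they were chosen, and the package's numerical conventions and
limitations.

## Measurements

A tissue-microarray core is a table of cell centroids (µm) with binary
phenotype flags for GFAP, gp96, CD4, CD8 and PD-1. Two reductions feed
everything downstream:

* **Staining extent** of a marker = positive cells / all nucleated
  cells, a fraction in [0, 1]. An empty core raises an error rather than
  returning 0: the ratio is undefined, not zero.
* **Phenotype density** = cells matching a conjunction predicate
  (e.g. CD4+PD-1+) divided by core area in mm². PD-1 density counts all
  PD-1+ cells regardless of CD4/CD8 co-positivity; the CD4+PD-1+ and
  CD8+PD-1+ conjunctions are separate measurements.

Dichotomization is always "high iff value > cutoff"; ties go to the low
group. This ≤-to-low convention is applied uniformly (median splits,
fixed cutoffs and maxstat cutpoints alike) so group definitions never
depend on which rule produced the threshold.

## Maximally selected rank statistics

For marker values x and right-censored survival (t, δ), every midpoint
between consecutive distinct sorted values is a candidate cutpoint,
restricted to splits whose low-group proportion lies in
[ε, 1−ε] (default ε = 0.1, the common inner-80% convention). At each
candidate the two-group log-rank statistic is standardized as
z = (O − E)/√V with O, E, V the low-group observed events, expected
events and hypergeometric variance summed over distinct event times
(ties handled by summation). The selected cutpoint maximizes |z|; exact
ties in |z| break toward the candidate nearest the marker median.

Because max|z| over many correlated splits is not a log-rank statistic,
the p-value is computed by permutation: marker values are shuffled
against the fixed survival data B times and
p = (1 + #{max|z*| ≥ max|z|}) / (B + 1). The scan is vectorized over
candidates (risk-set and death-indicator matrices are built once per
dataset and reused across permutations), which keeps a B = 199
permutation test on n = 80 at a few milliseconds. The empirical size of
the test at α = 0.05, measured over 200 null datasets, is ≈ 0.05–0.06.

Candidates are midpoints between *distinct* values, so tied marker
values can never straddle a cutpoint. Any strictly increasing transform
of the marker leaves |z|, the p-value and the group memberships
unchanged (the cutpoint maps through the transform).

## Survival machinery

Kaplan–Meier estimation, the k-sample log-rank test and Cox
proportional-hazards fitting are delegated to lifelines; Greenwood
standard errors are computed from the event table. Conventions:

* Median OS is the first time with S(t) ≤ 0.5; +∞ (reported as null)
  when the curve never reaches 0.5.
* Cox ties use the Efron correction (month-resolution survival times
  guarantee ties; Efron is the less biased standard choice). Confidence
  intervals are Wald, exp(β ± 1.96·se).
* A covariate with zero variance is reported as a null effect
  (β = 0, HR = 1, p = 1) instead of entering the optimizer — this is
  what happens to the IDH term inside an IDH-defined stratum.
* Non-convergence (e.g. monotone likelihood under perfect separation)
  raises an explicit error.

The signed two-group statistic used by the cutpoint search is authored
here and is consistent with lifelines: for any two-group split the
squared signed statistic equals the log-rank chi-square exactly.

## GI score

GI = I(gp96 extent high) + I(CD4 density high) + I(PD-1 density high),
an integer 0–3; missing indicators are an error (no imputation).
Indicators come from maxstat cutpoints by default; a median-split mode
is available and is the generator's own definition of "high". The
stratified report contains per-group KM medians, the log-rank test over
the non-empty score groups (with a warning when fewer than four are
present), a per-unit Cox fit treating the score as a numeric covariate
(one HR with one CI), and a multivariate fit of the score-3 indicator
adjusted for grade (numeric, per step above grade II) and IDH status.
Strata: all patients, IDH-mutant grade II/III, IDH-wildtype grade IV.

## Interferon arm

DEG rule: |fold change| strictly > 2 (two-sided on |log2FC|, so 5-fold
down-regulation qualifies) and adjusted p strictly < 0.01. The
differential-expression model itself is out of scope — the pipeline
consumes any per-gene (log2FC, padj) table; when the synthetic path
must build one it contrasts the 100 highest- vs 100 lowest-gp96 samples
with Mann–Whitney tests and Benjamini–Hochberg adjustment.

IPA score = arithmetic mean of log2(TPM + 0.1) over the DEGs shared by
the IFN-α and IFN-γ response sets ("IPA" and "ISG" score are the same
quantity). A sample whose panel genes are all zero scores
log2(0.1) ≈ −3.322. Genes missing from the matrix are skipped and
reported; the score errors only when no panel gene is present.

Conditioning analysis: the "mid-IPA" subset is the contiguous-in-rank
window of `subset_size` samples centred on the median IPA rank — the
rank-window formalization of "minimal score variation" (its IPA
variance is empirically far below that of every random subset drawn).
For each marker gene, ρ_mid = Spearman(HSP90B1, marker) inside that
window, the reference distribution is ρ over `n_random` seeded random
subsets of the same size, and
p_reduction = (1 + #{|ρ_random| ≤ |ρ_mid|}) / (n_random + 1). Small
p_reduction means the IPA restriction shrinks the correlation more than
chance subsetting — evidence that interferon activity mediates the
association. With `subset_size = n` the analysis degenerates cleanly
(ρ_mid equals the full-cohort ρ, Δ = 0).

## Spatial arm

Each non-reference cell gets the Euclidean distance to its nearest
gp96+GFAP+ reference cell (k-d tree; verified against an O(n²) scan).
"5 µm segments" are nearest-distance bands — annuli of the distance
transform, not per-reference rings, which would double-count cells in
dense reference fields. Counts fall into [0,5), …, [95,100) µm;
proportions are normalized within phenotype over in-range cells (cells
beyond 100 µm are tallied separately), so the two phenotypes' profiles
are directly comparable; per-bin normalization is available as an
option. Multi-specimen pooling averages per-specimen proportions with
equal weight. The attraction test is a two-sided Mann–Whitney U on the
*uncapped* distance distributions of CD4+PD-1+ vs CD4+PD-1− cells —
truncating at 100 µm would discard information and the display profile
and the test are deliberately decoupled.

Mann–Whitney uses exact enumeration below a combined n of 20 (tie-free)
and the tie-corrected normal approximation otherwise; Kruskal–Wallis
post hocs are pairwise Mann–Whitney with Bonferroni multiplication.

## Synthetic generative models

The generators define the study conditions the tests run under; all are
bit-reproducible given their seed.

**Cohort.** 234 patients by default (grade probabilities 0.22/0.21/0.57,
IDH-mutant probability 0.8/0.6/0.1 by grade). Patient-level gp96 extent
is logistic-normal per grade; CD4/CD8/PD-1 densities are lognormal per
grade with per-grade medians calibrated so the grade-mixture cohort
medians are 8.72 (CD4) and 3.64 (CD8) cells/mm². A Gaussian copula with
a single shared factor links gp96 extent to each density; the copula
correlation 2·sin(πρ/6) delivers the target Spearman ρ (default 0.45)
*conditionally on grade*. Because grade shifts both gp96 and the
densities, the marginal Spearman exceeds the copula target — the same
confounding that motivates grade-stratified correlation analyses in
real cohorts. Survival follows a Weibull proportional-hazards model
(shape 1.2, scale 27.2 months → baseline median OS ≈ 20 months) with
linear predictor β_gp96·I(gp96 high) + β_CD4·I(CD4 high) +
β_PD1·I(PD-1 high) + β_grade·(grade−2), where "high" is the cohort
median split of the generated patient-level value; the default marker
βs are ln 1.945 and β_grade = ln 1.6. Censoring is administrative: with
probability `censor_rate` (0.25) a subject receives an independent
U[0, 120] month censoring time — the simplest mechanism satisfying the
independent-censoring assumption. An exact number of patients can be
marked as missing follow-up (the 212/234 = 90.6% funnel).

Cells are placed uniformly in a disc of radius 600 µm (area 1.13 mm²);
population counts are Poisson with mean density × area, with PD-1
positivity split across CD4+/CD8+/standalone compartments (40/20/40%)
so every marginal count is Poisson at its configured density; gp96
flags are Bernoulli(extent) over all nucleated cells, and GFAP marks
tumor cells (500/mm²).

**Expression.** A latent interferon activity A ~ N(0,1) per sample
drives log2(TPM+0.1) of the 24-gene ISG panel and (with loading 0.8) of
HSP90B1; T-cell markers (CD8A, CD4, PDCD1) load on A and, via
`direct_loading`, on the realized HSP90B1 signal. `direct_loading = 0`
is pure mediation: conditioning on A leaves ~zero partial correlation,
which is what the conditioning analysis must detect. TPM is recovered
as max(2^log2 − 0.1, 0), so all values are non-negative. Baselines:
7 log2 units for HSP90B1 (an abundant chaperone), 3 for the T-cell
markers, 4 for ISGs; noise SD 1 on the log2 scale.

**Point patterns.** Reference gp96+GFAP+ cells uniform in the disc;
CD4+PD-1+ cells rejection-sampled with acceptance exp(−d/τ), d the
nearest-reference distance (default τ = 20 µm), CD4+PD-1− cells
uniform. The kernel yields the monotone-decaying annulus profile shape
and degenerates to uniform as τ → ∞.

### What the generators do not emulate

No segmentation error, marker spillover or intensity thresholds (cell
tables are taken as ground truth); no spatial clustering of immune
cells beyond the single attraction kernel; no informative censoring or
cohort entry effects; no batch structure, library-size variation or
count overdispersion in expression. Passing tests demonstrate that the
analysis machinery recovers known structure under these idealized
conditions — not that the biological conclusions transfer to any
particular real cohort.

## Problem sizes and numerical choices

Recovery analyses use n = 500 cohorts (per-unit HR), n = 600 expression
samples with 200-sample subsets and 500–1000 random draws, 200 null
datasets of n = 80 with B = 199 permutations for the cutpoint size
study, and 10³ cells per phenotype for the spatial power check — sizes
at which the Monte-Carlo error is small relative to the effects probed
while the whole suite runs in about a minute.

Two measurement effects are worth knowing about when comparing the
pipeline's outputs to the generator's parameters:

* Densities are measured as Poisson counts over 1.13 mm², so per-core
  values are quantized in steps of ≈ 0.88 cells/mm²; for the skewed
  density distributions this pulls the measured cohort median above the
  latent one (CD8 ≈ 4.4–4.9 vs 3.64, CD4 ≈ 9–12 vs 8.72, on top of
  ±1 cells/mm² sampling spread in the median itself), and it attenuates
  rank correlations and high/low classifications. Consequently the
  per-unit GI hazard ratio fitted from *measured* indicators is
  attenuated (≈ 1.6–1.9 across seeds at a generating 1.945), while
  fitting from the generated patient-level values recovers ≈ 1.85–2.2.
  The acceptance script reports the patient-level recovery; the
  measured-path attenuation is the expected behaviour of median splits
  under classification noise, not an estimator defect.
* The maxstat cutpoint is selected to maximize separation, so the
  univariate HR at the selected split is modestly optimistic; the
  permutation p-value, not the HR, carries the inferential claim.

Degenerate inputs are contracts, not crashes: empty cores, all-identical
marker values, single-group strata, missing anchor genes and absent
phenotypes raise explicit errors; empty *phenotypes* in a profile are
flagged (NaN proportions), and cores without reference cells are
skipped and listed in the spatial report.

## Known limitations

Cutpoints are derived on the whole cohort (stratum-wise derivation is a
config choice, not the default); no multi-cutpoint search, time-varying
covariates or proportional-hazards diagnostics; the conditioning
analysis is a subset-restriction design, not a formal causal mediation
model — it cannot distinguish mediation from a shared upstream driver
of both interferon activity and the markers.
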