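# Methods

This note records the scientific and numerical choices behind the
package: what each score computes, what the statistics assume, what the
synthetic cohort generator does and does not emulate, and where the
design was genuinely open.

## Scoring engines

**GAPP.** The score is a sum over six parameter groups (pattern,
necrosis, cellularity, Ki-67, invasion, secretory type). Two choices are
not forced by the published point table alone and are fixed here:

* The two histological-pattern items (large/irregular nests,
  pseudorosettes) are *additive* — a tumor showing both collects 2
  pattern points. This is the only reading under which the stated
  maximum of 10 is attainable, and the acceptance enumeration confirms
  the engine's range is exactly [0, 10].
* Ki-67 band boundaries are closed on the 1–3% band: [0, 1) → 0 points,
  [1, 3] → 1, (3, ∞) → 2. The M-GAPP dichotomy (below) uses ≥ 1%.

Cellularity is consumed as a pre-assigned class (low < 150,
moderate 150–250, high > 250 cells per unit area); the package does no
image analysis, and the unit area is whatever the reporting pathologist
used. Non-functioning and adrenergic tumors both score 0 on the
catecholamine item; only the noradrenergic type scores.

**PASS.** The published 12-item weight table (eight 2-point items, four
1-point items, maximum 20). Vascular and capsular invasion are stored
once on the histology profile and shared between the GAPP invasion item
and the corresponding PASS items, so the two systems can never disagree
about the same slide finding.

**M-GAPP.** Six binary parameters: combined pattern (nests or
pseudorosettes), comedo necrosis, vascular invasion (capsular invasion
deliberately does *not* count), Ki-67 ≥ 1%, noradrenergic type, and loss
of SDHB immunohistochemical staining ("loss" = no definite granular
cytoplasmic staining against positive internal controls). The individual
point weights of the system were never published; the package defaults to
1 point per parameter (range 0–6), which is consistent with the reported
group medians (1.0 non-metastatic vs 4.0 metastatic) and the reported
Youden-optimal cutoff of ≥ 3. The weights are configurable
(`ScoringConfig` / YAML / `--mgapp-weights`) and are recorded in the run
metadata of every validation report so a reweighted analysis is always
traceable.

Missing histology fields raise a `MissingDataError` naming the field
rather than scoring 0: silent zeros would bias every score toward the
low-risk classes.

Metastases are classed synchronous (< 6 months after diagnosis of the
primary) or metachronous (≥ 6 months); metastasis-free survival (MFS) is
the interval from surgery to first metastasis, with non-metastatic
subjects censored at last follow-up. A subject's follow-up may exceed the
event time (follow-up continues after metastasis), so the record
invariant deliberately does not enforce event time ≤ follow-up.

## Validation statistics

All tests are two-sided; significance is conventionally read at 0.05; no
multiple-testing correction is applied.

* **Contingency tests.** 2×2 tables default to the Yates
  continuity-corrected chi-square (correction clamped at zero); the
  `auto` method switches to Fisher's exact test when any expected count
  falls below 5, and to the uncorrected Pearson chi-square for larger
  tables. On the published classification counts this default reproduces
  the reported P values (PASS dichotomy 0.010; M-GAPP dichotomy < 0.001;
  SDHB 2×2 — min expected count ≈ 2.3, hence Fisher — 0.044).
* **Group comparisons.** Student's t (pooled variance) or Mann–Whitney U;
  the U test enumerates exactly when both groups have n ≤ 8 and the data
  are tie-free, otherwise it uses the tie-corrected normal approximation
  with continuity correction. Two identical-valued groups return P = 1 by
  convention.
* **Cox regression** is written in-package: Newton–Raphson with
  step-halving on the partial likelihood, Breslow ties by default (the
  convention of the legacy statistics packages these analyses are usually
  run in) with Efron available by flag. Wald CIs are exp(β ± 1.96·SE).
  A monotone likelihood (complete separation — e.g. every event in one
  covariate category) is detected by coefficient divergence (|β| > 15)
  and raised as a `ConvergenceError` instead of returning a silently
  enormous hazard ratio; zero-variance covariates and event-free data are
  rejected up front. The test suite checks the fitter against a dense
  grid search of an independently hand-written partial likelihood on all
  small fixtures (|Δβ| < 1e-4), against a closed-form three-subject case
  (HR = 2^(−1/2)), and against lifelines under Efron ties.
* **ROC/AUC.** AUC is the Mann–Whitney probability estimator (ties count
  ½); operating points are evaluated at every distinct score with the
  convention "score ≥ cutoff calls the tumor metastatic". The AUC
  standard error and the paired-AUC comparison use DeLong placement
  values; identical score vectors yield a zero difference reported as
  P = 1. A stratified bootstrap serves as the independent oracle in
  tests. The Youden cutoff maximizes J = sensitivity + specificity − 1
  over distinct observed scores, with ties broken toward the smallest
  cutoff (maximal sensitivity at equal J).
* **Survival.** Kaplan–Meier product-limit curves (events-first at tied
  times) and the standard observed-minus-expected log-rank test, both via
  lifelines behind the module surface. Synchronous metastases enter MFS
  analyses with their recorded (possibly zero) event times; no time is
  nudged for estimation.
* **Correlation.** Sample Pearson r with the t test on n − 2 degrees of
  freedom, applied to metastatic subjects' scores against their
  time-to-metastasis.

## Synthetic cohort generator

The generator emulates the validation-study conditions: n = 72;
metastasis prevalence 20.8%; SDHB-staining loss in 33.3% of metastatic vs
10.5% of non-metastatic tumors; functional tumors in 86.7% / 82.5%, of
which 53.8% / 29.8% noradrenergic; PGL site fraction 12.5%; mean
follow-up 43.5 months; one third of metastases synchronous. Demographic
and tumor-size distributions use the published group means and SDs.

Rates with no published prevalence — the histological features
conditional on outcome and the Ki-67 distributions — were chosen once, in
the published direction of effect and at clinically plausible magnitudes
(e.g. comedo necrosis 40% vs 2%, reflecting its very large reported
hazard ratio; Ki-67 lognormal with median 2.5% vs 0.6%). These choices
make the synthetic cohort separate more cleanly than real patients do
(AUCs near 1 rather than 0.7–0.8), which is intentional: the generator
exists to exercise and calibrate the pipeline, not to be a digital twin.
Passing tests on synthetic cohorts therefore demonstrate correctness of
the computations and recovery of configured parameters, not clinical
performance.

Structure the generator does *not* emulate: correlations among
histological features beyond their common dependence on outcome (features
are conditionally independent given metastasis status), genetic
subtypes, multi-center effects, and any follow-up distribution shape
beyond its mean (only the mean is published; censoring is exponential).
Event times are Weibull (shape 1.2, scale 30 months — a mild
increasing-hazard choice matching the observed mix of early and late
metastases) with the synchronous fraction enforced by quantile mapping,
which preserves the Weibull shape within each stratum. A
proportional-hazards mode replaces the prevalence-based outcome with a
latent Weibull event time whose hazard is scaled by a configured hazard
ratio on one binary feature; the suite uses it to verify that the Cox
fitter recovers a configured log-HR of log 3 within 3 SEs at n = 2000.

Determinism: one `numpy` Generator seeded from the config; identical
seed + config gives a byte-identical cohort file.

## Numerical and design notes

* Problem sizes in the test suite: exhaustive enumerations (864 GAPP
  input combinations, 4096 PASS subsets), 20 cohorts of n = 40 with 10⁴
  bootstrap replicates for the DeLong check, n = 10⁴ for prevalence
  calibration and n = 2000 for hazard-ratio recovery — sizes at which the
  binomial/Monte-Carlo tolerances used are meaningful.
* Cohort files are flat UTF-8 CSV; booleans serialize as 0/1 and parse
  from {0, 1, true, false, yes, no} case-insensitively. Spreadsheet
  import goes through an explicit user-supplied column map (site naming
  is never guessed) and is lossy at the 15-significant-digit precision of
  the spreadsheet format.
* The pipeline degrades gracefully: stages whose preconditions fail
  (single-class cohorts, separated Cox fits) are skipped with the reason
  recorded in the report and log, never silently fabricated.

## Known limitations

The exact unit area behind the cellularity thresholds is not defined by
the scoring systems' sources; cellularity must be supplied as a class.
Reproducing the published per-patient results (AUCs 0.822/0.753/0.728,
Table-level hazard ratios, MFS correlations) requires participant-level
data that is not redistributable with this package; the import shim
exists for users who obtain it. SDHB staining loss is a surrogate that is
not specific to SDHB mutations. No competing-risks or time-dependent
covariate machinery is provided.
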