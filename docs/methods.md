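# Methods

This note documents the statistical model behind `neutroclust`, the design
choices made where the procedure was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## Severity scores

FACED, E-FACED and BSI are implemented as table-driven band rules (ordered,
first match wins, final catch-all band) evaluated over patient fields, so the
point assignments are data, not code, and can be serialised to YAML and
corrected without touching the engine. The shipped defaults follow the
original index publications and carry a provenance note asking users to
verify them against those sources. Two shipped choices deserve mention:

* **BSI colonization (max total 26).** Colonization is scored as two
  additive items — *P. aeruginosa* colonization (3 points) and chronic
  colonization by other organisms (1 point) — matching the separate
  `pa_colonization` / `other_colonization` fields of the record schema. With
  the remaining bands (age 0/2/4/6, BMI < 18.5 → 2, FEV₁ 0/1/2/3, prior
  hospitalization 5, ≥3 exacerbations 2, dyspnea 0/2/3, radiology 1) the
  component maxima sum to the scale's stated maximum of 26.
* **BSI hospital-admission lookback.** The original index used a two-year
  window; registries that record the previous year only are accommodated by
  a `lookback_years` documentation flag (default 1). The scoring rule is the
  same either way (≥1 admission → 5 points).

Dyspnea bands are expressed on the mMRC 0–4 scale (mMRC 3 ↔ MRC 4, mMRC 4 ↔
MRC 5). A component with any missing input contributes no points, is listed
in `missing_components`, and suppresses the total — scores are never imputed.
Category bins are inclusive exactly as printed: FACED 0–2/3–4/5–7,
EFACED 0–3/4–6/7–9, BSI 0–4/5–8/≥9.

## Cut-point discovery

For each candidate threshold *t* the cohort (records complete in
neutrophils, FACED and EFACED) is split at neutrophils ≥ *t* (boundary
inclusive; ties at the threshold go above) and each score is tested with the
two-sided Mann–Whitney U:

* exact enumeration when `n_above · n_below ≤ 400` and the pooled sample has
  no ties;
* otherwise the normal approximation with midranks, tie-corrected variance
  `n₁n₀/12 · [(n+1) − Σ(t³−t)/(n(n−1))]` and a 0.5 continuity correction.

Because the pooled score sample is identical at every split, ranks and the
tie term are computed once and the whole sweep is a cumulative-sum pass:
O(n log n + G) for G candidates. The sweep is property-tested for exact
equality against an independent per-candidate test.

**Grid.** Default: every 10 cells/µL from the 5th to the 95th percentile of
observed neutrophils. The granularity is configurable; duplicated or
unsorted candidate lists are normalised, so selection is invariant to grid
ordering.

**Selection.** Eligible candidates must have p < α (default 0.05) on *both*
scores and a minority-cluster fraction ≥ `min_fraction` (default 0.25).
`most_balanced` (default) returns the eligible candidate maximising the
smaller cluster, ties broken toward the higher threshold;
`highest_significant` returns the largest eligible candidate. Requiring both
scores jointly (an AND rule) is a design decision; either-score eligibility
would be more permissive and is not offered.

**Selection bias.** No multiple-testing correction is applied across the
grid — deliberately, since the procedure mirrors common practice of scanning
raw p-values. The cost is quantified rather than hidden: under the null
model the test suite verifies the per-candidate type-I error is calibrated
(≈ α) and that the joint significance+balance gate still returns *no*
threshold in the large majority of null cohorts.

**Parameter recovery.** The recovery experiment plants the cut at the
neutrophil distribution's balance point (lognormal with log-median 5000
cells/µL) so that the balance criterion is consistent with the plant and the
significance gate is the quantity under test. With the default effect sizes,
1034-patient cohorts and a 10 cells/µL grid, the sweep recovers the planted
cut within ±200 cells/µL in ≳95 of 100 seeds; the recovery rate is monotone
non-decreasing in the planted effect size.

## Comparison tables

Continuous rows: pooled-variance Student's t (df = n₁+n₀−2); Welch is not
the default because the method models the classical registry analysis. The
degenerate zero-pooled-variance case returns p = 1 for equal means and p = 0
otherwise. Categorical rows: Pearson chi-square without continuity
correction (a correction is available in `chi_square` consumers via scipy if
needed), df = k−1, with a warning when any expected count is below 5.
Multi-level variables (smoking status) expand to one level-vs-rest 2×2 row
each, matching registry table layout. Missing data are handled pairwise:
each row uses all patients non-missing for that variable. Exclusion
re-analyses (COPD, PA colonization) drop flagged patients before any
summary, so percent denominators are post-exclusion group sizes. Display
rounding is one decimal (half-up); CSV exports keep full precision.

## Correlations

Pairwise-complete Pearson r with the t-transform p-value
(t = r√((n−2)/(1−r²)) on n−2 df), computed overall and within each cluster.
Entries with p > 0.05 are reported but masked, mirroring the usual
dot-matrix display. Within the above-threshold stratum the
neutrophil–score correlations are attenuated relative to the full cohort —
an expected range-restriction effect that the tests assert on planted data.
Spearman is not the default because the classical analysis uses Pearson;
scores are ordinal, so users may prefer rank correlations for their own
reports.

## Adjusted association

Outcome: severe disease (FACED ≥ 5 or EFACED ≥ 7). Exposure:
above-threshold cluster membership. Confounders (fixed list): PA
colonization, Charlson index, total leukocytes, % lymphocytes,
% eosinophils, platelets, CRP, fibrinogen, total protein, albumin, ESR —
entered simultaneously and untransformed, no interactions. Percentages are
derived from absolute counts at model-building time.

The fitter is plain maximum-likelihood IRLS (Newton steps with
step-halving, so the log-likelihood is non-decreasing by construction;
convergence when the score's max absolute component < 1e-8, cap 100
iterations). Covariates are standardised internally for conditioning and
estimates back-transformed. Inference is Wald: SEs from the inverse observed
information, 95% CI = exp(β̂ ± 1.96·SE); profile-likelihood or Firth
corrections are out of scope, though quasi-separation (non-convergence with
any |β̂| > 15, or convergence to such magnitudes) is detected, flagged and
warned about while estimates are still reported. Complete-case rows only;
the dropped count is recorded. With sparse outcomes (severe FACED is rare in
the synthetic cohorts) Wald intervals run conservative — null-model coverage
of the exposure CI measured slightly above the nominal 95%.

## Synthetic cohort generator

The generator emulates the *structure* of a large bronchiectasis registry,
with below-threshold marginals calibrated to published registry summaries:
age N(67.1, 14.6²) years, FEV₁ N(78, 24²) % predicted, neutrophils
lognormal with log-mean log(4100) and log-SD 0.48 (sub-threshold stratum
mean/SD ≈ 3.4×10³ (0.9×10³) cells/µL, roughly a third of patients above
4990 cells/µL), heavy-tailed analytes (CRP, ESR, lymphocytes) as
moment-matched lognormals, counts as Poisson, binary traits as Bernoulli
(e.g. PA colonization 0.215 below / 0.335 above). Effects are threshold
steps: every affected variable receives its configured additive shift, rate
shift, or above-threshold prevalence/probability vector exactly for patients
whose neutrophils fall at or above the planted cut-off, matching the
dichotomised analysis the pipeline must recover. Score components are
generated as raw ordinal/count/continuous inputs and scores *computed* from
them, so the scoring engine is exercised rather than bypassed. Leukocytes
are built additively (neutrophils + lymphocytes + eosinophils + a truncated
normal residual ≥ 0) to honour the hemogram constraint. Missingness is
missing-completely-at-random per variable. Binary and categorical sampling
uses one uniform draw per patient with stratum-specific inverse CDFs, so
effects are monotone in their parameters at a fixed seed.

What the generator does **not** emulate: between-centre heterogeneity,
informative missingness, measurement error, longitudinal structure,
correlated comorbidity clusters, or graded (non-step) dependence of severity
on neutrophils. Passing tests therefore demonstrate that the pipeline
recovers what it assumes — a discrete threshold effect under MCAR
missingness — not that such a threshold exists in any real cohort, nor that
real-registry means or odds ratios are reproduced.

## Problem sizes and numerical conventions

Simulation-based tests run at the study scale of 1034 patients where the
claim concerns that scale (recovery: 100 seeds; null type-I calibration:
1000 replicates at one fixed candidate; logistic log-OR recovery: 200
seeds); distributional checks that do not depend on cohort size use 150–800
patients. All simulations are seeded and deterministic. Percent reporting
uses half-up rounding to the requested decimals; CSV round-trips preserve at
least 12 significant digits; empty CSV cells mean missing. The threshold
boundary is inclusive (≥) everywhere.
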