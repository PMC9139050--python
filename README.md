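# neutroclust

Neutrophil-count phenotype clustering for non-CF bronchiectasis cohorts.

Blood neutrophilia is a hallmark of airway inflammation in bronchiectasis.
`neutroclust` implements a biostatistics pipeline that asks whether a single
blood neutrophil cut-off separates a stable bronchiectasis cohort into two
clinically distinct phenotypes, and then characterises those phenotypes. It is
aimed at respiratory epidemiologists and biostatisticians working with
registry-style patient tables (one CSV row per patient: demographics, lung
function, blood analytes, exacerbation history, colonization and comorbidity
flags).

## The method

1. **Severity scoring.** FACED (0–7), E-FACED (0–9) and the Bronchiectasis
   Severity Index (BSI, 0–26) are computed per patient from a table-driven
   rule engine, and binned into mild / moderate / severe categories
   (FACED 0–2 / 3–4 / 5–7; EFACED 0–3 / 4–6 / 7–9; BSI 0–4 / 5–8 / ≥9).
2. **Cut-point discovery.** For every candidate threshold *t* on a grid
   (default: every 10 cells/µL between the 5th and 95th neutrophil
   percentiles) the cohort is split at neutrophils ≥ *t* and the separation
   of FACED and EFACED between the groups is tested with the two-sided
   Mann–Whitney U test (exact enumeration for small tie-free splits,
   otherwise the tie-corrected normal approximation with continuity
   correction). The operating threshold is chosen among candidates with
   p < α on *both* scores and a minimum minority-cluster fraction; the
   default strategy picks the most balanced such split (ties to the higher
   threshold). P-values along the grid are raw, so the package also ships
   null-model simulations quantifying the minimum-p selection bias.
3. **Cluster characterisation.** Variable-by-variable comparison tables
   (pooled-variance Student's t for continuous rows, Pearson chi-square for
   categorical rows, star notation `*` p<0.05, `**` p<0.01, `***` p<0.001),
   subgroup re-analyses excluding COPD or chronically PA-colonized patients,
   pairwise-complete Pearson correlation matrices (overall and per cluster),
   severity-category histograms, and a confounder-adjusted logistic
   regression of cluster membership against severe disease (FACED ≥ 5,
   EFACED ≥ 7) with Wald 95% CIs, OR = exp(β̂ ± 1.96·SE).

Because registry data of this kind are not freely redistributable, the
package includes a synthetic cohort generator that emulates the statistical
structure of such a registry (right-skewed neutrophils, score components and
analytes shifting step-wise above a planted cut-off, group-dependent binary
prevalences) so every stage is testable end to end.

## Worked example

```python
import numpy as np
import neutroclust as nc
from neutroclust.compare import VariableSpec

cfg = nc.default_config(n_patients=1034, seed=1,
                        planted_threshold=5000.0,
                        neutrophil_log_mean=float(np.log(5000.0)))
scored = nc.score_cohort(nc.generate_cohort(cfg))

est = nc.ThresholdClusterer(grid_step=10).fit(scored)   # sklearn-style
asg = nc.dichotomize(scored, est.threshold_)
table = nc.comparison_table(scored, asg, [
    VariableSpec("faced", "continuous"), VariableSpec("efaced", "continuous"),
    VariableSpec("fev1_pct", "continuous"), VariableSpec("crp", "continuous"),
    VariableSpec("pa_colonization", "binary")])
fit = nc.adjusted_association(scored, asg, "EFACED")
```

With this seed the sweep selects a threshold of **4920 cells/µL** (planted:
5000), splitting the cohort 516 above / 518 below, and the comparison table
reads:

```
| variable        | below (n=518) | above (n=516) | p        |     |
|-----------------|---------------|---------------|----------|-----|
| faced           | 2.0 (1.4)     | 2.7 (1.6)     | 3.84e-13 | *** |
| efaced          | 2.8 (1.7)     | 4.0 (1.9)     | 1.55e-26 | *** |
| fev1_pct        | 77.6 (24.8)   | 64.2 (23.9)   | 5.43e-18 | *** |
| crp             | 3.4 (17.4)    | 4.6 (4.0)     | 0.134    |     |
| pa_colonization | 103 (19.9)    | 155 (30.0)    | 0.000161 | *** |
```

Continuous cells are mean (SD), binary cells are N (%). The above-threshold
cluster scores higher on both severity indices, has worse airflow obstruction
and a higher PA-colonization prevalence — the planted phenotype. The adjusted
logistic model (confounders: PA colonization, Charlson index, leukocytes,
% lymphocytes, % eosinophils, platelets, CRP, fibrinogen, total protein,
albumin, ESR) gives, for EFACED ≥ 7:

```
adjusted OR 8.32 (95% CI 2.50–27.71), p = 0.000557
```

i.e. above-threshold patients have sharply higher odds of severe disease even
after adjustment.

There is also a CLI:

```bash
neutroclust simulate --n 1034 --seed 1 --out cohort.csv
neutroclust score --in cohort.csv --out scored.csv
neutroclust scan --in scored.csv --grid-step 10 --alpha 0.05
neutroclust run --config cfg.yaml      # full report bundle + manifest
```

Exit codes: 0 success, 2 validation error, 3 no threshold selected.

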