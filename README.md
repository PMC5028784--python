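# actipain

Actigraphy phenotypes, ordinal resilience-scale validation and
resampling-annotated inference for chronic-pain cohort studies.

`actipain` is for biostatisticians and epidemiologists analysing
cross-sectional cohorts in which chronic pain, patient-reported outcomes
(Resilience Scale, CD-RISC, Brief Pain Inventory, EQ5D-3L, worry
frequencies) and objectively measured physical activity (1-minute
accelerometer epochs) are compared between a chronic-pain (CP) and a
pain-free (NoCP) group.  It covers the full computational path of such a
study:

* **Questionnaire scoring** — including renormalisation of truncated
  translated scales by the exact item-count ratio (25/23 ≈ 1.09 for a
  23-item Resilience Scale, 25/24 ≈ 1.04 for a 24-item CD-RISC), and the
  chronic-pain case definition (pain on most days for ≥ 3 months).
* **Scale validation** — polychoric correlation matrices (two-step ML),
  Horn parallel analysis for the factor count, minimum-residual factor
  extraction with direct-oblimin rotation, iterative pruning of items with
  loadings < 0.3, and raw/ordinal Cronbach alpha.
* **Actigraphy** — counts referenced to each device's calibration maximum;
  the last 7 complete worn days; 5-minute windows classed inactive below
  2.5 % of the device maximum; three phenotypes: mean daily active
  minutes, median active intensity, and endurance (minutes at 0, 1–24,
  25–49, 50–74, ≥ 75 % of the individual weekly maximum).
* **Inference** — pooled t, Wilcoxon rank-sum, Fisher exact,
  Cochran–Armitage trend and Spearman correlation, each annotated with a
  95 % percentile bootstrap CI (10,000 stratified resamples) and a
  permutation p-value (10,000 permutations, add-one estimator, exhaustive
  for small designs).
* **Multivariate models** — regression-forest out-of-bag permutation
  importance with `mtry = 3`, the negative-importance threshold rule (a
  predictor is informative if its importance exceeds |most negative
  importance|) and a 4-run stability intersection; moderator OLS with
  simple slopes at moderator mean ± 1 SD; beta regression (logit link,
  constant precision) for quality-of-life outcomes in (0, 1).
* **Synthetic cohorts** — a seeded generator producing questionnaire
  responses from a one-factor graded-response model, worry items from a
  proportional-odds model, and bout-structured diurnal activity traces
  with known expected active minutes, so every stage is testable with
  known ground truth.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

```python
from actipain import (normalize_truncated_score, fisher_exact_2x2,
                      two_sample_t_from_stats)
from actipain.pipeline import run_study
from actipain.synthdata import CohortConfig

# a 23-item isiZulu Resilience Scale raw total of 130, on the 25-item scale
print(normalize_truncated_score(130, 23, 25))   # 141.30434782608694

# published 2x2 counts are directly usable: 65/99 vs 76/98 female
print(round(fisher_exact_2x2([[65, 34], [76, 22]]).p_original, 3))  # 0.082

# a full synthetic study: simulate, score, validate, phenotype, test, model
report = run_study(CohortConfig(n_total=197), seed=42,
                   actigraphy_subset=68, n_boot=1000, n_perm=1000)
print(report.to_text())
```

The report (abridged) prints:

```
== cohort comparisons ==
  age_t: 44 (8) vs 40 (10) p=0.01
  rs_full_t: 141 (21) vs 153 (17) p=<0.0001
  ...
== activity (CP vs NoCP) ==
  time_active_wilcoxon: p=0.86 perm p=0.90
  intensity_wilcoxon: p=0.60 perm p=0.85
  ...
== scale validation == factors=1 retained=23 removed=[] alpha=0.90 ordinal alpha=0.92
== forest == consistently informative: (none)
== pain_qol_beta == r2=0.30 interaction p=0.60
```

Reading it: the simulated pain group is older (t-test p = 0.01) and scores
~12 points lower on the Resilience Scale (t-test p < 0.0001), reflecting
the generator's configured 0.7 SD latent deficit; the activity comparisons
are all non-significant because the generator's default activity
difference is null; the 23 translated resilience items form a single
factor with ordinal alpha 0.92; and with no planted activity signal the
forest's 4-run stability protocol reports no consistently informative
predictor.

The same stages are available from the shell:

```sh
actipain simulate --out sim/ --seed 1 --days 14
actipain score --cohort sim/cohort.csv --out scored.csv
actipain actigraphy --traces sim/traces --devices sim/devices.json \
    --cohort sim/cohort.csv --days 7 --out summaries.csv
actipain validate-scale --cohort sim/cohort.csv --item-prefix rs_item_ --out rs.json
actipain compare --cohort scored.csv --var rs_score --test t
actipain report --out study/ --seed 42
```

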