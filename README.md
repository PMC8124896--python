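# pnetrecur

Early-recurrence cut-off detection and risk modeling after resection of
pancreatic neuroendocrine tumors (pNETs).

## The problem

pNETs behave heterogeneously: some recur within months of curative-intent
surgery, others decades later, and many never do. Patients who recur early
die sooner after recurrence, so an evidence-based *early recurrence* (ER)
window — rather than an arbitrary one — matters for surveillance intensity
and adjuvant-therapy decisions. This package implements, as a tested
library, the full analysis used to define such a window from a surgical
cohort:

1. **Eligibility filtering** — grade 3 tumors, genetic syndromes, R2
   resections, synchronous metastases, unknown recurrence status, and
   recurrences within 3 months of surgery are excluded, with a reason-coded
   log.
2. **Survival kernel** — Kaplan–Meier product-limit estimation
   S(t) = ∏_{t_j ≤ t} (1 − d_j/n_j) with Greenwood variance, median survival
   with a Brookmeyer–Crowley log(−log) confidence interval, and the
   k-sample log-rank test with hypergeometric variance under ties — written
   from scratch on numpy, because the scan below calls it thousands of
   times.
3. **Minimum-p cut-off scan** — for each candidate threshold c on a months
   grid, recurred patients split into early (RFS ≤ c) and late (RFS > c)
   arms and post-recurrence survival (PRS) is compared by log-rank; the c
   with the smallest p is the selected cut-off (the maximally selected
   statistic approach). Because the same data choose and test the
   threshold, a permutation correction for the selection multiplicity is
   available: p_adj = (1 + #{min-p* ≤ min-p}) / (B + 1) over B permutations
   of the PRS outcomes against the RFS labels.
4. **Risk models** — univariable logistic screening (retain p < 0.10),
   multivariable logistic regression by iteratively reweighted least
   squares for three outcomes (any / early / late recurrence), odds ratios
   with Wald intervals exp(β ± 1.96·SE), and midrank ROC/AUC for single
   predictors.
5. **Synthetic cohorts** — a seeded generator with a *planted* 18-month
   changepoint: a never-recurring majority, latent early/late classes with
   Weibull RFS (medians 11 vs 41 months) on either side of the cut-off,
   strongly divergent PRS (medians 10.2 vs 43.4 months), covariate-linked
   class membership (odds ratio 1.20 per cm tumor size, 4.69 for node
   positivity), and administrative censoring. Ground truth is returned with
   every cohort, so threshold recovery and parameter recovery are testable.

Packaged count fixtures encode the published multi-institutional cohort
aggregates (n = 807) and reproduce the printed percentages exactly under
the half-up one-decimal rounding rule.

The intended users are biostatisticians and clinical researchers analyzing
time-to-recurrence cohorts — primarily from Python; a thin `pnetrecur` CLI
covers shell use (`simulate`, `scan`, `riskfactors`, `report`).

## Worked example

```python
from pnetrecur import (SyntheticConfig, generate_cohort, scan_cutoffs,
                       select_optimal, permutation_adjusted_p)

records, truth = generate_cohort(SyntheticConfig(seed=7))
recurred = [r for r in records if r.recurrence]
scan = scan_cutoffs(recurred)               # grid 6..48 months
cutoff, p = select_optimal(scan)
adjusted = permutation_adjusted_p(recurred, n_perm=999, seed=7)
```

Running `examples/03_cutoff_scan.py` (which prints the scan profile around
the optimum) gives:

```
 candidate_month  n_early  n_late  statistic        p  eligible
              16       49      78       78.3 8.95e-19         1
              17       53      74       85.1 2.87e-20         1
              18       54      73       79.7 4.33e-19         1
              19       56      71       57.6 3.26e-14         1

selected cut-off: 17 months (naive min p = 2.87e-20)
permutation-adjusted p: 0.001
planted truth was: 18 months
```

The scan lands one grid step from the planted 18-month changepoint; the
naive minimum p is extreme because the planted PRS divergence is strong,
and the permutation-adjusted p (the fraction of permuted datasets whose own
minimum p beats the observed one) remains small — the detected threshold is
real, not a selection artifact. Across 100 replicate cohorts the selected
cut-off falls within ±3 months of the truth in ~99% of runs
(`recovery_experiment`), while under a null with no PRS divergence the
naive minimum p rejects at ≈30% instead of 5% and the adjusted p stays
calibrated.

The other scripts in `examples/` walk through cohort simulation, KM curves
and medians by recurrence timing, logistic risk-factor models with ROC, the
end-to-end report, and the published-table worked examples.

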