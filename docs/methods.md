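# Methods

This note documents the statistical procedures the package implements, the
modeling choices made where the problem left them open, and what the
synthetic validation does and does not establish.

## Endpoints and eligibility

All durations are continuous months and enter the analysis as given — no
calendar arithmetic. Recurrence-free survival (RFS) runs from surgery to
first detected recurrence; post-recurrence survival (PRS) from recurrence
to death or last follow-up (death from any cause is the PRS event; end of
follow-up censors); overall survival is carried as a separate
surgery-anchored field. Published cohort summaries are ambiguous about the
OS anchor for non-recurrent patients; the data model keeps `os_months`
anchored at surgery for everyone and leaves PRS undefined without
recurrence.

Eligibility mirrors standard practice for this tumor: grade 3 disease,
genetic syndromes, R2 resections, synchronous metastases, unknown
recurrence status, and recurrences within 3 months of surgery (likely
missed synchronous disease) are excluded. A record failing several
criteria is logged once, under the first failing criterion in that fixed
order — an arbitrary but reproducible accounting rule; the eligible set is
unaffected by it.

Recurrence patterns are mutually exclusive: *local* if every
first-recurrence site is the remnant pancreas, cut surface or
peri-pancreatic nodes; *distant* if none is; *local + distant* otherwise.
Recurrences in organs other than pancreas, liver and regional nodes count
as distant — the three-pattern taxonomy admits no fourth class. A
recurrence at exactly the cut-off is *early* (≤ convention), consistent
with reading the window as "within N months" and with the scan's
arm-construction rule.

## Survival kernel

The Kaplan–Meier estimator multiplies (1 − d/n) at each distinct event
time; observations censored at an event time stay in that time's risk set
(censored-after-event tie rule). Greenwood's formula supplies pointwise
variances. The median is the smallest grid time with S(t) ≤ 0.5; its 95%
interval inverts the pointwise test of S(t) = 0.5 on the log(−log S) scale
(Brookmeyer–Crowley). The source analyses never name their CI method; this
is the common default in clinical survival software. Bounds that the data
cannot determine (curve never reaching 0.5, interval running past the last
event) are reported as undefined rather than extrapolated.

The log-rank test compares observed with expected events at each distinct
pooled event time using the multivariate hypergeometric
variance-covariance, which handles tied events; the statistic is the
quadratic form over k−1 groups against χ²(k−1). With a single distinct
event time the statistic equals (N−1)/N times the Pearson χ² of the
induced 2×2 table — the (N−1)/N factor is the hypergeometric
finite-population term, and the tests assert this exact relation.
The implementation is validated to 1e-6 against lifelines on random
censored datasets and against exact permutation enumeration at small n.

## Minimum-p cut-off scan

Candidates run over months 6–48 in steps of 1 by default: the lower end
stays clear of the 3-month exclusion window, the upper end keeps late arms
populated; the grid is configurable. Candidates leaving fewer than 10
recurred patients in either arm (configurable) are flagged ineligible and
not tested — a guard for the χ²(1) approximation. Ties in the minimum p
break toward the smaller threshold.

The naive minimum p is what clinical studies report, so it is the default
output; it is anti-conservative because the data both choose and test the
threshold. The permutation correction permutes the (PRS time, event) pairs
against the RFS values — valid under exchangeability of PRS across
recurred patients under the null of no RFS–PRS association — and
recomputes the minimum eligible p per permutation; the add-one estimator
(1 + #{min-p* ≤ min-p})/(B + 1) is exact-level by construction. Arm sizes,
and hence candidate eligibility, are permutation-invariant. A vectorised
two-group log-rank over the whole grid (risk-set indicator matrices, two
matrix products per permutation) makes B = 999 routine; it is tested to
agree with the reference implementation at every candidate. No analytic
maximally-selected-statistic correction is provided — permutation only.

## Risk models

Three outcomes are modelled from one eligible cohort: any recurrence;
early recurrence (recurrence at or before the cut-off versus *all* other
eligible patients); late recurrence (after the cut-off versus all others).
The comparator sets for the early/late panels are a documented
interpretation — published three-panel tables are computable this way from
a single cohort, and no alternative comparator reproduces their margins.

Fitting is Newton–Raphson/IRLS with step halving (log-likelihood is
monotone by construction), convergence at gradient max-norm ≤ 1e-8, Wald
standard errors from the inverse observed information. Aliased columns are
dropped with a warning before fitting. Separation — any |β| exceeding 30
on the log-odds scale, or a singular information matrix — raises an error
with a hint toward exact/penalized methods; there is no silent fallback.
Tumor size enters per cm, untransformed. The univariable screen retains
factors at strictly p < 0.10; screens and multivariable fits are
complete-case per analysis (no imputation), with a warning below 10 events
per covariate. Coefficients agree with statsmodels GLM to 1e-6 on random
datasets.

ROC curves use the rule score ≥ threshold ⇒ positive; AUC is computed from
midranks and therefore equals the normalized Mann–Whitney U, ties shared.

## Summary tables and tests

Categorical variables are n (percent of the per-variable, per-group
non-missing denominator); continuous ones median (IQR). Percentages round
half-up to one decimal — the rule under which the packaged published
counts reproduce their printed percentages digit for digit. Two-group
tests: Mann–Whitney U for continuous variables (Welch's t on request, if
normality is asserted); χ² without continuity correction when all expected
cells are ≥ 5, else Fisher's exact test for 2×2 tables. For r×c tables
with small expected cells the package falls back to χ² with a flagged test
name; no r×c exact test is implemented (two-group clinical variables
reduce to 2×2).

The packaged fixtures store raw counts. The published tables mix
denominators across columns (some percentages over the full group, some
over recorded cases only, and the recurrence column of the baseline table
uses 126 rather than 127 in places); `unknown` filler rows align each
variable's count sum with the denominator its printed percentages actually
used. A handful of published percentages (functional tumors, symptomatic
disease, multifocality, vascular resection, the local/distant pattern
split) are not reproducible from their counts under any single denominator
and are deliberately excluded from the exact worked-example set.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the published cohort: n = 807, crude recurrence 15.7%, 49/126
of recurrences early, tumor size log-normal (median 2.2 cm, IQR 1.4–3.8),
21.9% node-positive, grade-2 share 32.6% of graded cases, era mix and the
remaining covariates at the published marginals.

Two calibrated logistic stages link covariates to outcomes: recurrence
(log 1.17 per cm, log 2.32 for nodes, log 2.82 for grade 2 — the
published multivariable recurrence effects) and early-class membership
among recurrences (log 1.20 per cm, log 4.69 for nodes). Each intercept is
solved on the realized covariates so the expected recurrence fraction and
early share hit their targets exactly; degenerate targets (0 or 1) clamp
to a ±40 log-odds bound.

Event times are Weibull with shape 1.3 (configurable; the sources state
only medians, and shape 1.3 gives the mildly rising early hazard typical
of post-resection recurrence). The key design choice: class RFS
distributions are **truncated to their side of the planted cut-off** —
early in (3, 18] months, late after 18 — and the scale is solved
(closed-form above, Brent's method for the bounded window) so the
*truncated* median equals the configured class median (11 and 41 months).
This makes the planted cut-off a genuine changepoint of the generative
law, the ground truth a recovery experiment needs. The cost is realism:
real RFS mixtures overlap across any threshold, so recovery rates measured
here are an upper bound on what overlapping classes would give. PRS is
untruncated Weibull per class (medians 10.2 and 43.4 months — the in-text
values; the same source elsewhere prints 42.6/81.5 months for the same
quantities, an irreconcilable internal conflict, and both defaults are
overridable). Administrative censoring draws a uniform follow-up limit on
(0, 120] months (the study window's span), applied to PRS and to the
death time of non-recurrent patients (death Weibull, median 63 months);
recurrence status itself is never masked, mirroring a registry in which
unknown recurrence status is an exclusion, and keeping the realized
recurrence fraction binomial around its target.

Covariates beyond size/nodes/grade are generated independently at their
marginals — no correlation structure (real cohorts correlate location with
resection type, size with stage, etc.), no institutional effects, no
cure-fraction or mixture-hazard refinements. Passing tests therefore show
the *method* recovers planted truth under its own assumptions, not that
the published cohort's patient-level results are reproduced — those data
are available only on request, and the headline real-cohort numbers
(18-month cut-off at p = 0.019, node OR 4.69, AUC 0.766) are not
desk-reproducible targets.

## Validation problem sizes

The suite validates at sizes chosen for statistical resolution:
changepoint recovery over 100 replicate cohorts (±3-month tolerance, ≥80%
required; observed ≈99%); null calibration over 200 replicates with 199
permutations each (naive minimum-p rejection must exceed the binomial 95%
band around 5% — observed ≈30% — while the adjusted p must fall inside
it); parameter recovery as the mean over 25 cohorts of n = 5000 (the 10%
log-odds tolerance sits at >3 standard errors of that mean, sized from the
measured per-fit variance); Weibull median checks on single-class n = 5000
cohorts with censoring disabled (5% tolerance); Fisher's exact test
checked against exact integer enumeration on all 132,470 valid 2×2 tables
with n ≤ 40 (agreement to 4e-16).

## Known limitations

- Early/late comparisons condition on surviving recurrence-free to the
  cut-off (guarantee-time bias is inherent to the design being
  reproduced); the package reproduces, not repairs, this.
- No Cox models, competing risks, interval censoring, cure fractions,
  imputation, or penalized/exact logistic fallbacks.
- The permutation correction assumes PRS exchangeability across recurred
  patients; covariate-dependent censoring would violate it.
- The CLI is a thin convenience layer; the library API is the primary
  interface.
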