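# Methods

## The index and its classification rule

The CTD-IP index is a fixed-coefficient logistic score over eight ordinal
histology grades (0–3). The coefficients are taken as given from the study
that derived them; this package never refits them. The log-odds

Z = +1.65 − 1.09·FF − 0.81·SMH − 0.85·CIP − 0.86·DPVC − 0.57·Fat
    + 0.86·Plasm + 0.64·LyGC + 2.47·AF

passes through the logistic function P = exp(Z)/(1+exp(Z)), implemented
with `scipy.special.expit` for overflow safety. The published decision
rule is strict: P > 0.5 labels a rating CTD-IP, P = 0.5 exactly is
idiopathic. With threshold 0.5 the cutover sits exactly at Z = 0.

Two consequences of the printed constants are worth stating:

* the weights sum to −0.21, so a biopsy marked 3 on *every* item scores
  Z = 1.02 and is still labelled CTD-IP;
* the intercept is positive, so a biopsy scored 0 on every item has
  P = logistic(1.65) ≈ 0.839 and is labelled CTD-IP. Whether a
  featureless biopsy should be classifiable is a clinical question the
  formula does not answer; the package computes what the formula
  dictates and leaves the interpretation to the user.

In double precision the logistic saturates to exactly 0 or 1 beyond
|Z| ≈ 36.7; the index's reachable range is only [−10.89, +13.56], where
P is always strictly inside (0,1) (verified by an exhaustive sweep of
all 4⁸ = 65,536 score vectors, which also confirms P is monotone in each
item with the sign of its coefficient).

Coefficients are configurable (for refitting experiments) but default to
the published constants, and the defaults are asserted in the tests.
Probabilities are written to output files at 4 decimals; full precision
is kept internally.

## Consensus and the IPAF morphological criterion

A case is assigned to the CTD group iff every rater's label is CTD-IP.
The rule is order-invariant and generalises to any rater count (the
original study used four). Dissent is summarised as the minority size
per case, min(votes, raters − votes), with the full vote count also
emitted. The morphological IPAF criterion is operationalised on the
same grades as LyGC ≥ 2 AND Plasm ≥ 2; at cohort level it is applied
with the same unanimity convention as the CTD group.

## Agreement

With four raters the headline statistic is Fleiss' multi-rater kappa
(computed via `statsmodels`): kappa = (Po − Pe)/(1 − Pe) with Po the
mean per-case pairwise agreement and Pe the sum of squared marginal
category proportions. Item grades are treated as nominal categories —
conservative, and what Fleiss' kappa assumes. A pairwise Cohen kappa
(optionally linear-weighted for the ordinal scale) is available as a
secondary two-rater view; on two raters Fleiss differs from Cohen by
the usual pooled-vs-per-rater marginal chance term, a gap that shrinks
with n (documented in a test).

kappa is reported as *undefined* (not a number) when chance agreement
is 1 — every rating in one category — or when only a single case is
available; the report keeps such rows with a status flag rather than
dropping them. Cases with any missing rater are dropped
(complete-case analysis). Which kappa variant produced the originally
published agreement values is not recoverable without per-case data, so
those values are treated as context, not as test targets.

## Group comparison

Binary covariates are tested with Fisher's exact test; the Pearson
chi-squared statistic (optional Yates correction) is carried as a
secondary column. The two-sided Fisher p-value uses the
minimum-likelihood convention — the sum of hypergeometric probabilities
of all same-margin tables whose point probability does not exceed the
observed one — evaluated in exact integer arithmetic (`math.comb`), so
probability ties are resolved at full rational precision rather than
with a floating-point slack. The doubling convention (twice the smaller
tail, capped at 1) is available behind a flag. A zero margin returns
p = 1 with a degeneracy flag. The exact-arithmetic implementation is
cross-checked in the tests against both an independent
fraction-arithmetic enumeration and `scipy.stats.fisher_exact`.

Continuous covariates are compared with a two-sample t-test computed
from per-group summary statistics. The default is the pooled-variance
Student test (sp² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), df = n₁+n₂−2):
recomputation from the published per-group mean±SD summaries reproduces
the published p-values at two decimals under pooling but not under
Welch. Welch's variant (Satterthwaite df) is available as an option.
Several published rows (age, PaCO₂, %DLco, SpO₂, BAL totals and some
differentials, CD4/8) do not reproduce from the printed summaries under
any standard two-sample test — plausibly computed on different subgroup
ns or with a rank test — and are therefore not asserted anywhere.
Missing values are handled by pairwise deletion with per-variable n
reported, since panels such as BAL and blood gas are not run on every
patient. p-values are displayed at 2 decimals, full precision in
machine columns.

## Synthetic cohorts

The generator draws a two-latent-class cohort: class by Bernoulli
prevalence; a true eight-item profile per case from class-conditional
categorical distributions; each rater's observed grade as the true
grade passed through symmetric one-step ordinal noise (probability eps
per item per rater of moving one step toward 0 or 3, equal odds,
clamped at the scale ends); binary covariates as class-conditional
Bernoullis and continuous covariates as class-conditional Gaussians.

Defaults (versioned in `src/ctdip/data/default_cohort.yaml`): 94 cases,
4 raters, prevalence 0.2128, eps = 0.15, covariate rates and lab
moments per class set to the published cohort's per-group frequencies
and mean±SD values. The class-conditional item distributions are a
design choice — the CTD-like class weighted toward high Plasm/LyGC/AF,
the idiopathic-like class toward high FF/SMH/CIP/DPVC/Fat — calibrated
only so the index separates the classes in the right direction. eps =
0.15 was chosen as the smallest noise level that produces the
mid-range item kappas typical of real multi-pathologist grading; the
one-step noise model is the minimal structure that yields intermediate
agreement.

Randomness is hierarchical: each case's draws come from a stream seeded
by (seed, case index) and each rater's from (seed, case index, rater
index), so adding raters or covariates never reshuffles existing cases,
and identical configurations give byte-identical CSVs.

What the generator does *not* emulate: per-pathologist bias or
expertise differences (noise is symmetric and identical across raters),
correlations among items within a case beyond what the latent class
induces, correlations among clinical covariates, non-Gaussian lab
distributions (KL-6 is strongly right-skewed in reality; the Gaussian
can produce negative values, which is harmless for testing the
comparison machinery but not a realistic marginal), and missingness.
Passing tests therefore demonstrate the pipeline's correctness and its
qualitative behaviour (e.g. diagnosis-level agreement exceeding raw
item agreement), not quantitative agreement with any real cohort's
kappas or group sizes.

## Verification design and problem sizes

* Fisher's exact test is checked against a full-support enumeration in
  exact fractions on 250 random tables with N ≤ 60, at 1e-10.
* Fleiss' kappa: 1 under perfect agreement; |kappa| < 0.08 under 500
  cases × 4 raters of seeded independent uniform rating.
* Generator parameter recovery runs one 2,000-case noise-free cohort
  per latent class (prevalence forced to 1 and 0 respectively) and
  requires every class-conditional score frequency within ±0.03 of its
  configured value; ±0.03 is ≈2.7 binomial standard errors at n = 2,000,
  and generating each class at full size keeps that calibration exact
  instead of diluting one class to a few hundred cases.
* The comparison stage's type-I error is measured on 50 null cohorts
  (94 cases each, clinical covariates identically distributed in both
  classes): the t-test false-positive fraction must sit inside the
  binomial 95% CI around 0.05. Fisher's exact test is conservative by
  construction on small 2×2 tables — its true level is below the
  nominal 0.05 — so its fraction is asserted against the upper CI bound
  only.
* Rater-noise degradation: diagnosis-level kappa over eps ∈
  {0, 0.1, 0.2, 0.4} at 500 cases must be non-increasing.

All stochastic checks run under fixed seeds recorded in the tests. The
sizes above keep the full suite under a few tens of seconds while
leaving each check's sampling error well inside its asserted band.

## Pipeline and interchange

CSV (UTF-8, header, comma, "." decimal) is the single interchange
format; YAML/JSON appear only in configuration. `case_id`/`rater_id`
are opaque strings. The end-to-end report writes scored.csv,
groups.csv, agreement.csv, table2.csv and a run log containing the
configuration, its digest, input file digests and per-stage case
counts. When a cohort yields only one consensus group (e.g. a
single-case input) the comparison stage is recorded as skipped rather
than fabricated, and the remaining outputs are still produced.

## Known limitations

* The index coefficients are treated as exact constants; no uncertainty
  is propagated from their original estimation.
* Agreement statistics come without confidence intervals.
* The synthetic generator's item distributions are plausible, not
  fitted; cohort-level quantities (group split, kappas) vary with seed
  and should not be read as predictions of any real cohort.
* Slide handling, case selection, radiology and outcome analysis are
  out of scope: inputs begin at the per-rater score table.
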