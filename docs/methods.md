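# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data validation does and does not establish.

## Disease definition

Pulmonary hypertension is dichotomized at mean pulmonary artery pressure
(mPAP) strictly greater than 25 mmHg, measured at right heart
catheterization; a subject at exactly 25 mmHg is classified as
normal-pressure. mPAP must be positive; non-positive or missing values are
rejected at the I/O boundary rather than silently dropped.

## 2×2 test characteristics

For a finding-vs-disease table (TP, FP, FN, TN):

* **Proportions.** Sn and Sp carry 95% **Wilson score** intervals. The
  Wilson interval was chosen over Wald and Clopper–Pearson because it is
  well behaved at the small counts typical of these studies (n as low as 8)
  and never escapes [0, 1]; bounds are additionally clipped to bracket the
  point estimate, guarding against ~1e-16 float residue at k = 0 or k = n.
* **Likelihood ratios.** 95% intervals use the delta method on the log
  scale: exp(ln LR ± z·SE) with z = Φ⁻¹(0.975) and
  SE(ln LR⁺) = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)); the LR⁻ SE swaps in
  FN and TN. Using the exact quantile (1.959964, not 1.96) matters only in
  the fourth significant figure of very wide intervals.
* **Zero cells.** Any zero cell triggers the Haldane–Anscombe correction:
  0.5 is added to *all four* cells, and the corrected cells are then used
  for point estimates and intervals alike. This keeps the LR point estimate
  and its interval mutually consistent (the identity LR⁺ = Sn/(1−Sp) holds
  exactly on the corrected cells). The record carries a `corrected` flag.
* **Pooling.** Cross-study pooling is a cell-wise sum of raw integer
  tables, applied *before* estimation; fractional (already-corrected)
  tables are refused to prevent double correction.
* **Display.** Percentages print to one decimal and LRs to two; full
  precision is kept internally.

## Hierarchical rater model

Each subject is examined by every rater, so per-assessment pooling treats
312 correlated assessments as independent. The package instead fits, per
sign × phase,

    y_ie ~ Bernoulli(invlogit(β₀ + β₁ D_i + u_e)),   u_e ~ N(0, σ_u²)

with a single shared random intercept per examiner (one random effect per
rater, not separate effects for diseased and non-diseased assessments —
the latter is a known elaboration but is not the default because the design
gives only ~26 subjects per disease class per rater). Under
`grouping="by_group"` the (β₀, β₁) pair becomes stratum-specific
(specialist vs generalist) while u_e and σ_u remain shared across strata;
with three raters per stratum a stratum-specific σ_u would be essentially
unidentified.

**Priors.** "Diffuse normal" is made concrete as N(0, sd = 10) on β —
effectively flat over the plausible logit range (±10 corresponds to rates
between 5e-5 and 1−5e-5) without inviting numerical overflow — and
Uniform(0, 1) on σ_u. Both are configurable on `RaterModelSpec`.

**Derived quantities.** Per draw, the *average examiner* (u = 0, the
median rater) has Sn = invlogit(β₀+β₁) and Sp = 1 − invlogit(β₀); LRs
follow by identity, so every reported CrI is a quantile of exactly
transformed draws. Integrating over u instead of setting u = 0 would give a
population-averaged (slightly attenuated) Sn/Sp; the median-rater summary
is the default because "the average examiner" is the estimand of interest
in rater studies, and the alternative is one line of user code on the
returned draws. Group comparisons report the fraction of draws in which
the specialist LR strictly exceeds the generalist LR; exact ties (possible
only in degenerate hand-built posteriors) count as failures of the strict
inequality.

**Sampling.** The posterior is low-dimensional (7 parameters pooled, 9
grouped, for 6 examiners), so the package uses univariate **slice
sampling** (stepping-out with a randomized step budget, then shrinkage)
within a Gibbs scan — a correct, tuning-free MCMC whose validity does not
depend on step-size calibration. The likelihood is collapsed to sufficient
statistics (positive counts per examiner × disease class), making one
density evaluation O(#examiners) regardless of cohort size. Chains are
seeded from independent `SeedSequence` spawns of one user seed, so a fixed
spec + dataset + seed reproduces the draw sequence exactly.

Sampler correctness is established by behavioural tests rather than by
comparison to a particular reference sampler: with an empty likelihood the
draws reproduce the priors (σ_u uniform moments, β spread ≈ 10); with
σ_u = 0 truth and large n the posterior medians land on the known
generative values and on the descriptive 2×2 proportions; credible-interval
coverage over 20 independent synthetic replicates is ≥ 85%.

**Convergence.** `gelman_rubin` implements the classic potential scale
reduction factor, R̂ = √(((n−1)/n·W + B/n)/W), from ≥ 2 parallel chains.
The reporting threshold is R̂ < 1.1 for every sampled parameter; fits
failing it are flagged on the posterior object and the CLI exits with a
distinct status (3) while still writing the report. Two identical chains
give √((n−1)/n) (the B = 0 limit); if every draw is constant the statistic
is defined as 1.

**Run lengths.** `RaterModelSpec` defaults to the full analysis settings —
3 chains × (10,000 burn-in + 10,000 kept). This posterior mixes quickly
(R̂ ≈ 1.005 at a tenth of that), so the CLI and the bundled experiments
default to 3 × (2,000 + 2,000), which keeps a full 10-fit pipeline in the
minutes range on one CPU; the paper-scale settings are one flag away. Each
sign × phase is fitted independently (8–10 separate models) with no
multiplicity adjustment, matching how such tables are conventionally
reported.

## ROC of ordinal global ratings

The 1–5 Likert rating (orientation: 5 = PH most likely) is swept over its
levels to produce operating points from (0,0) to (1,1). AUC is computed
from midranks, which is identical to the pairwise Mann–Whitney count with
**ties given half credit** — the only defensible choice for a 5-level
scale where ties are the norm — and equals the trapezoidal area under the
operating points exactly (a tested identity). The Hanley–McNeil closed
form supplies SE and a normal 95% CI clipped to [0, 1]. AUC < 0.5 is
reported as-is: a rater can genuinely run against the disease, and
reflecting would hide it. Raters whose rated subjects fall in one disease
class are skipped with a logged warning rather than failing the whole
report.

## Synthetic cohort generator

The generator is the study design in executable form, and its defaults are
the study conditions: 52 subjects with exactly 25 diseased; mPAP uniform on
10–25 mmHg (normal) and 26–61 mmHg (PH) — only the >25 dichotomy is used
downstream, so the uniform is the least-structured choice consistent with
the observed ranges; 3 specialists + 3 generalists; 5 signs × 2 phases.
Binary findings are drawn from the same random-effects logistic model the
inference stage fits, with user-supplied (Sn, Sp) interpreted as
average-examiner (u = 0) probabilities and converted to β₀ = logit(1−Sp),
β₁ = logit(Sn) − β₀.

Default per-sign truths are the model-based specialist/generalist values
reported for the prospective cohort (e.g. loud P2 on inspiration:
specialist 0.37/0.87, generalist 0.22/0.81). Jugular venous distension has
no reported row, so plausible values on the same scale (rest 0.30/0.75,
inspiration 0.25/0.80, both strata) were fixed once. The examiner
random-effect SD defaults to σ_u = 0.3 on the logit scale — modest
heterogeneity (±0.6 logits covers ~95% of raters), as the study did not
publish its estimate.

Ratings come from an ordered probit: latent N(μ_class, 1) plus a
per-examiner shift (SD 0.2), cut at thresholds (−1.2, −0.4, 0.4, 1.2).
μ_PH = 0.36 puts the latent AUC, Φ(μ/√2), near 0.60 — the scale of the
reported per-examiner areas; a per-group μ_PH allows stratum-specific
rating skill. Stochastic ordering of ratings by disease class holds by
construction when μ_PH > μ_nonPH and is property-tested.

**What passing tests show — and don't.** The generator realizes exactly
the model the inference assumes. Recovery and coverage results therefore
validate the *implementation* (sampler, transformations, intervals), not
the model's adequacy for real bedside data, where misclassified gold
standards, non-exchangeable raters, sign-to-sign correlation within a
subject, and drift over an examination session all violate the generative
assumptions. Conclusions about real cohorts need the model criticism this
package does not automate.

## Problem sizes used in the bundled experiments

Recovery experiments use 200–500 subjects × 6 examiners — large enough
that posterior medians pin the truth to a few percent while 20-replicate
batches stay in the minutes range — with reduced, demonstrably converged
MCMC (3 × 2,000 kept after 500 burn-in; R̂ < 1.03 throughout). The
recovery tolerance (mean |median − truth| ≤ 0.05 with ≥ 85% CrI coverage)
reflects an irreducible design limit: with 6 examiners the average-examiner
intercept carries a σ_u/√6 ≈ 0.12-logit uncertainty floor that more
subjects cannot remove.

## Known limitations

* The hierarchical model has no subject-level random effect: assessments
  of one subject by different raters are conditionally independent given
  disease status. With ~6 raters per subject a subject effect is weakly
  identified, but real signs plausibly share subject-level difficulty.
* The Hanley CI is a normal approximation; at AUC near 0 or 1 with small
  samples its clipped bounds are crude (no exact or bootstrap option).
* The log-method LR intervals and the continuity correction are standard
  but approximate at very small counts; the package reports them as the
  field does rather than offering exact alternatives.
* Correlated-AUC comparisons between raters (DeLong) and smoothed ROC
  curves are out of scope, as is any meta-analytic weighting beyond raw
  cell pooling.
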