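# Methods

## The liability-threshold twin model

A binary phenotype is modelled through a latent liability *L* ~ N(0, 1);
individual *i* is affected iff *L_i* > τ. Thresholds are parameterized on
the probit scale and, by default, shared across zygosity within sex
(τ_m, τ_f), matching the assumption that prevalence differs by sex but not
by zygosity. Within a twin pair, (L₁, L₂) is bivariate normal with
correlation

* r_MZ = a² + c² for monozygotic pairs,
* r_DZ = 0.5·a² + c² for dizygotic pairs, same-sex and opposite-sex alike
  (no qualitative sex-limitation model is fitted; opposite-sex pairs differ
  from same-sex DZ pairs only through their sex-specific thresholds).

Each zygosity-by-sex group (MZM, MZF, DZM, DZF, DZOS) contributes a 2×2
concordance table of pairs by (twin 1 affected, twin 2 affected). Cell
probabilities are bivariate-normal orthant probabilities at the group's
thresholds and correlation; the model likelihood is the product of the
group multinomials. −2 log L omits the multinomial coefficient, so the
saturated model's −2 log L equals −2·Σ n_ij·log(n_ij/N) and likelihood
differences are unaffected.

**Pair ordering.** Same-sex pairs have no natural within-pair order; their
tables are double-entered (each pair contributes both orderings at half
weight), which symmetrizes the off-diagonal cells and makes within-pair
threshold equality automatic. Opposite-sex pairs are ordered male-first with
sex-specific thresholds. Double-entered counts may be half-integers; the
multinomial likelihood handles them without change.

## Numerical kernel

P(X > h, Y > k) for a standard bivariate normal with correlation r is
computed from Owen's T function with closed forms for the degenerate cases
(|r| = 1; h = k = 0 gives ¼ + asin(r)/(2π)). Exactly-zero thresholds are
nudged by 1e−12 to stay inside the Owen decomposition's domain; the induced
error is O(1e−12). The kernel is validated against adaptive quadrature to
better than 1e−10 over the full parameter range.

## Estimation

* **Tetrachoric correlation.** For a single 2×2 table the three parameters
  (τ₁, τ₂, r) exactly saturate the multinomial, so the joint MLE is
  analytic: thresholds at the margin probits, r solved so the concordant
  orthant probability matches the observed proportion (Brent root-solve,
  xtol 1e−12). A table whose concordant cell sits on a Fréchet bound is
  reported at r = ±1 with a boundary flag. The 95% CI is profile
  likelihood: −2 log L profiled over the thresholds, endpoints located by
  bisection at the χ²(1) critical value.
* **Saturated model.** Unconstrained (per-group thresholds and
  correlations): solved analytically per group as above, reproducing the
  observed (symmetrized) proportions exactly. Threshold or correlation
  equality constraints across groups (per-sex thresholds; correlations
  pooled by zygosity) are fitted numerically (Nelder–Mead on thresholds and
  atanh-transformed correlations, five correlation starting values).
* **ACE family.** Path coefficients (a, c) with e = √(1 − a² − c²) are
  optimized on the constrained simplex a² + c² ≤ 1 (SLSQP with the
  inequality constraint, bounds a, c ∈ [0, 1], thresholds ∈ [−6, 6], ftol
  1e−12), reporting squared quantities. Five documented starting points
  spread a² + c² over {0.1, 0.3, 0.5, 0.7, 0.9} of the feasible range
  (split 2:1 between a² and c² for ACE); thresholds always start at the
  pooled margin probits. AE fixes c = 0, CE fixes a = 0, E fixes both.
  Component estimates pinned at 0 are flagged as boundary solutions.
* **Model comparison.** Δ(−2 log L) between nested fits is referred to
  χ²(Δ parameters). For tests that pin a variance component at its boundary
  (AE vs ACE, CE vs ACE) this naive reference is conservative — the
  asymptotic null is a 50:50 mixture of χ²(0) and χ²(1) — but the naive
  convention is reported, as is standard in applied twin analyses. Small
  negative differences (< 1e−6, optimizer noise) are clipped to zero.
* **Profile CIs.** For each component, the profiled −2 log L (re-optimizing
  thresholds and the remaining component at each fixed value; for e² the
  fixed quantity is a² + c² with the internal split free) is bisected
  against the χ²(1) 95% critical value (3.84). Intervals are truncated at
  [0, 1] with boundary flags. At an interior optimum these agree with Wald
  intervals to within a few percent; near boundaries they are asymmetric,
  which is why they are the default. A parametric bootstrap alternative
  (per-group multinomial resampling at the observed proportions, percentile
  intervals) is available for the pipeline.

Degrees of freedom are reported as (independent multinomial cells across
groups: 2 per symmetrized table, 3 per ordered table) minus free
parameters. Different software conventions count raw-data rows instead;
only likelihood *differences* are comparable across conventions.

## Synthetic cohort generator

The generator emulates the structure of a large Swedish register-based
child twin sample. Defaults are the study conditions: group sizes
MZM 2465, MZF 2676, DZM 3122, DZF 2739, DZOS 5772 pairs; male prevalence
10.61%, female 5.03% (pooling to ≈7.85%); generating components
(a², c², e²) = (0.75, 0.22, 0.03). Per pair it draws a bivariate-normal
liability at the group's implied correlation, dichotomizes at the
sex-specific threshold, and maps affected twins to questionnaire response 1
("yes, to a certain degree") or 2 ("yes") with a configurable split
(default 0.5 each — the analysis collapses the two, so the split is
analysis-irrelevant) and unaffected twins to 0.

Optional overlays: follow-up cause labels for affected twins drawn from a
configurable categorical distribution over a controlled vocabulary (with a
`no_response` label for parents who indicate a cause but skip the
open-ended question), and comorbidity flags (autism, intellectual
disability, hearing, acquired, chromosomal) drawn per twin. Flags are
independent of liability by default because the source study reports no
joint distribution; a relative-risk parameter can enrich autism/ID among
affected twins (P(flag | affected) = RR × base rate, capped at 1). The
autism flag is understood as the merged indicator (register diagnosis or
parental "autism" answer to the follow-up question). Default comorbidity
rates are zero — the emulated sample is reported post-exclusion, so clean
cohorts are the baseline and flag rates are opt-in.

Randomness uses one root seed with a documented independent stream per
(group, purpose) pair (`SeedSequence(seed, spawn_key=(group_index,
purpose))`), so adding or removing groups or overlays never perturbs the
other draws, and equal seeds give byte-identical tables.

**What the generator does not emulate:** ages and longitudinal waves,
response/attrition processes, quantitative cognitive scores linked to
liability, free-text cause answers (inputs use the controlled vocabulary;
mapping raw comments — e.g. "kindergarten teacher" or "ear wax" to
`not_specified` — is a documentation-level rule for data preparation), and
any dependence of exclusion flags on family structure. Passing tests
therefore demonstrate correct recovery of the *assumed* data-generating
process, not robustness to real-data violations such as shared rater bias
in parent reports (which can inflate C) or diagnostic misclassification.

## Phenotype coding

An individual is affected iff the late-talking item is 1 or 2, unaffected
iff 0. Exclusion flags take precedence over the response (an excluded
individual is never counted affected): hearing, acquired and chromosomal
under both models; autism and intellectual disability additionally under
model 2. Precedence among multiple flags follows that fixed order; only the
first applicable reason is recorded. A missing response without exclusion
flags is a distinct `missing` status, dropped from all denominators (no
imputation). Exclusion is individual-level: prevalence keeps every
non-excluded individual with a phenotype, while twin analyses keep only
pairs with both twins analysable — so a pair with one excluded twin still
contributes one individual to prevalence but no pair to the concordance
tables.

## Descriptive statistics

Wald (normal-approximation) CIs for prevalence, Wilson by flag — the Wald
form reproduces published point estimates and its bounds differ from the
alternatives by ≤0.01 percentage points at these sample sizes. Pearson χ²
without continuity correction on the sex-by-trait 2×2 table. Odds ratio by
cross-product with the Woolf log-scale CI (0.5 continuity correction when a
cell is zero). Two-sample t-tests from summary statistics use the pooled
variance with df = n₁ + n₂ − 2. Twins are treated as independent
individuals in descriptive CIs; pair clustering is modelled only in the
twin analyses.

## Problem sizes in the validation suite

The Monte-Carlo validation uses 100 simulated cohorts at the full study
group sizes for bias and profile-CI coverage of the ACE components, 200
replicates at the full sizes for the AE-vs-ACE likelihood-ratio power
check (c² = 0.25 is detected in essentially every replicate at that scale),
and 200,000 pairs per group for convergence of empirical concordance to the
orthant probabilities (within 3 Monte-Carlo standard errors). Grid-search
cross-checks of the ACE optimizer sweep the (a², c²) simplex at step 0.005
on probability-exact tables, where margin probits make the thresholds exact
so the sweep is two-dimensional.

## Known limitations

* Univariate binary phenotype only: no bivariate/multivariate models, no
  ordinal three-category liability (the 0/1/2 item is dichotomized), no
  sex-limitation models, no covariates or raw-data FIML.
* The DZ correlation reported by the pipeline pools same-sex and
  opposite-sex DZ pairs by default (a flag separates them); with
  sex-specific thresholds this pooled tetrachoric is a summary, not a model
  parameter.
* Boundary inference (components at 0 or 1) uses flags plus truncated
  profile intervals rather than mixture-distribution p-values.
* The cause tally takes a controlled vocabulary as input; free-text
  categorization is out of scope.
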