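# Methods

## The experiment and its model

A single-profile conjoint (discrete-choice) experiment presents each
respondent with hypothetical patient vignettes, one at a time; a vignette
assigns one level to each of a fixed set of attributes. For every vignette
the respondent answers four decision questions: three yes/no (prescribe an
SGLT2 inhibitor, increase lisinopril dose, replace ibuprofen) and one
three-category monitoring question (increase / maintain / decrease
risk-factor monitoring frequency).

The analysis model is an **aggregate binary logit per outcome**. For
evaluation *t* of a profile with level assignment ℓ(t),

    P(yes_t) = logistic( β₀ + Σ_i u_i[ℓ_i(t)] ),

where `u_i` is the vector of part-worth utilities of attribute *i*,
constrained to sum to zero within the attribute (effects coding). Every
respondent-profile evaluation is treated as an independent observation —
there is no respondent-level heterogeneity in the estimator. The monitoring
outcome is recoded to binary before fitting (increase = 1; maintain and the
sparse decrease category = 0). A respondent-clustered sandwich covariance is
available behind a flag (`cluster_robust=True`) but is off by default, since
the aggregate model is the reporting convention for this design.

Reported quantities:

* **Relative importance** of attribute *i*:
  `100 · (max u_i − min u_i) / Σ_j (max u_j − min u_j)`. Shares are
  non-negative and sum to 100% per outcome; they are invariant to shifting
  any attribute's utilities by a constant and to global rescaling.
* **Odds ratios**: `OR = exp(u_level − u_ref)` against each attribute's
  configured reference level (the first level by default, e.g. "No test"
  for the biomarker). Since the contrast is linear in the coefficients, its
  standard error comes from the coefficient covariance (delta method on the
  log-odds scale); CIs are Wald (`± 1.96·SE`, exponentiated) and p-values
  two-sided Wald tests at α = 0.05. By construction the CI excludes 1
  exactly when p < 0.05. Wald rather than profile-likelihood intervals are
  the deliberate default: at 3 200 observations per fit the two agree to
  well within reporting precision.

## Design construction

The template study has six attributes (one with four levels, five with
three), a 972-profile full factorial, and a 14-column main-effects model
(intercept + Σ(Lᵢ−1) contrasts). A 42-profile subset is selected by
**Fedorov exchange**: start from a random nonsingular 42-subset, and
repeatedly apply the single swap (design profile out, catalog profile in)
that most increases det(X'X), using the classical rank-two determinant
update; stop at a local optimum and keep the best over (default) 20 seeded
random restarts. Ties keep the incumbent. Profiles are never repeated
within a design. The quality measure is relative D-efficiency against the
full factorial (1 for the full factorial itself, including replicated
copies). The exchange search reaches ≈ 0.99 for 42/972 with a handful of
restarts; exact orthogonality is impossible at 42 runs (42 is not divisible
by 4·3 level pairs), so the balance report quantifies the residual
deviation of pairwise level counts from uniform rather than asserting zero.

Degenerate designs (singular or near-singular information, condition number
above 1e10) score a D-efficiency of 0 with an explicit flag.

**Least-fill allocation**: respondents are processed in order; each of the
8 draws for a respondent samples uniformly from the profiles currently shown
the fewest times, excluding profiles that respondent already holds. The
final spread of show counts is at most one (400 × 8 over 42 profiles gives
exactly 34 profiles at 76 showings and 8 at 77).

## Synthetic respondents

The generator emulates the fielded survey's structure: 400 respondents × 8
profiles from the 42-profile design, four outcomes per evaluation. Binary
answers are Bernoulli draws from the logit model above. The monitoring
answer is generated in three categories so the binary recode step is
actually exercised: "increase" with its logistic probability, otherwise
"decrease" with conditional probability `decrease_rate` and "maintain" with
the remainder. In the template, `decrease_rate` is calibrated analytically
(over the uniformly-weighted full factorial) so the *marginal* share of
"decrease" answers is 5%, matching the sparsity that motivates the binary
recode; the realized share on a particular 42-profile design deviates only
by sampling noise and slight design imbalance.

Template utilities: the biomarker's part-worths per outcome are log-odds
contrasts of realistic magnitude for this kind of survey (monitoring OR for
high-risk vs no test = 2.56, low-risk 0.48; SGLT2 1.98; lisinopril 1.48;
ibuprofen 1.78), centred to zero-sum; the five clinical attributes are
hand-set zero-sum utilities chosen once so each outcome has a plausible
leading attribute (HbA1c for SGLT2 prescribing, blood pressure for
lisinopril, eGFR for ibuprofen replacement, the biomarker for monitoring).
Intercepts are mild (−0.3 … 0.2) so outcome base rates are moderate.

Randomness uses one named stream per outcome (plus streams for the
monitoring-decrease draw and for optional heterogeneity), spawned from a
single master seed, with draws in deterministic allocation order — so runs
are bit-reproducible and adding an outcome never reshuffles another
outcome's draws. Optional respondent heterogeneity (`heterogeneity_sd`)
adds zero-sum normal perturbations to each respondent's utilities; it is
off by default because the estimator is the aggregate model.

What the generator does **not** emulate: respondent covariates (specialty,
practice setting), attrition or attention screens, order/fatigue effects,
and within-respondent answer correlation beyond what shared profiles
induce. Passing parameter-recovery tests therefore shows the
estimator-reporting chain is correct under the aggregate model's own
assumptions, not that real physician panels satisfy those assumptions.

## Numerical choices

* Logit fits: Newton–Raphson, step-halving to keep the log-likelihood
  non-decreasing, convergence at gradient max-norm < 1e-8 or 100
  iterations; no regularization (it would bias the reported ORs).
  Covariance = inverse observed information at the optimum.
* Separation: any coefficient exceeding 15 in absolute value during
  iteration is treated as a diverging MLE and raised as an error naming
  the offending column (|log-odds| = 15 is far beyond any finite-data
  estimate this design can support). All-constant outcomes hit this guard
  via the intercept.
* Missing outcome values drop the row for that outcome's model only, with
  a logged count.
* Decoded utilities: the omitted level of each attribute is reconstructed
  as minus the sum of the estimated contrasts; its SE is the delta-method
  value from the full covariance (cross-checked against a bootstrap in the
  tests).
* Exchange-search determinism: restart seeds are spawned from the master
  seed, so run *r* is identical whether or not later restarts exist;
  best-over-restarts is therefore monotone in the number of restarts.

## Problem sizes used in the validation suite

The test suite validates at the study's own scale: 400 × 8 evaluations per
simulated survey. Monte-Carlo checks use 200 replicates for parameter
recovery / CI coverage and 500 replicates for null type-I error, sizes at
which the binomial error of an empirical coverage or rejection rate
(≈ 1–1.5 percentage points) is well inside the asserted tolerances. The
brute-force design-search oracle enumerates all subsets only on catalogs of
≤ 8 profiles, where exhaustive enumeration is exact and instant.

## Known limitations

* The estimator is the pooled aggregate logit; no hierarchical Bayes or
  mixed-logit extension is provided, and the default CIs ignore
  within-respondent correlation (use `cluster_robust=True` to quantify the
  difference).
* The design search optimizes main-effects D-efficiency only; interaction
  identifiability is out of scope.
* Choice-based conjoint with multi-alternative choice sets is out of scope;
  the package models single-profile ratings with independent outcomes.
* The actual 42 profiles used in the original fielded study are not
  published; the search reproduces the design *quality* (D-efficiency),
  not the exact profile set.
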