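# Methods

## The estimation problem

A case-cohort study measures an expensive covariate only on (i) the cases
of a cohort of size N (or a random fraction of them) and (ii) a simple
random *subcohort* of size n0 drawn from the entire cohort regardless of
outcome. Because the subcohort is drawn from everyone, m participants
typically belong to both sets. The standard pseudo-likelihood analysis
stacks the n1 case records (membership indicator D = 1) above the n0
subcohort records (D = 0), treats the duplicated participants as two
distinct rows, and fits an ordinary logistic regression

    logit Pr(D = 1 | x) = b0 + b1 x1 + … + bp xp.

The slope estimates are consistent for the *log risk ratios* of the
outcome in the source population (the intercept absorbs the two sampling
fractions and is not interpretable). `caseboot` implements this fit and
three estimators of the slopes' standard errors:

- **robust (sandwich)**: A⁻¹BA⁻¹ with A = Σ p̂ᵢ(1−p̂ᵢ)xᵢxᵢᵀ the
  (expected = observed) information and B = Σ (Dᵢ−p̂ᵢ)²xᵢxᵢᵀ the sum of
  per-row score outer products, *treating every pseudo-row as
  independent*. This is the long-standing default in practice. Because
  the m duplicated participants are not independent contributions, the
  estimator overestimates the true sampling SE; it is retained as the
  comparison baseline, bias included.
- **naive bootstrap**: resample the n1 cases and the full n0-member
  subcohort independently, refit, take the SD of the replicate
  coefficients. This ignores duplication and closely tracks the robust
  estimator.
- **duplication-aware bootstrap** (recommended): per replicate, (1) draw
  n1 cases with replacement; (2) draw n0 − m of the *non-case* subcohort
  members with replacement; (3) pick m of the n1 bootstrap case draws,
  without replacement, and append them to the subcohort block; (4) refit;
  (5) take the SD over replicates. Step 3 reproduces the design's overlap
  structure, so the replicate-to-replicate variability matches the actual
  sampling variability of the estimator.

A *stratified* variant — resample separately within the n1 − m
unduplicated cases, the n0 − m non-case subcohort members, and the m
duplicated participants (each duplicated draw contributing one D=1 and
one D=0 row) — is provided as an asymptotically equivalent alternative.

Confidence intervals are Wald-type throughout: estimate ± z·SE, with the
chosen SE plugged in; risk-ratio-scale intervals are the exponentiated
endpoints. Percentile or BCa bootstrap intervals are deliberately out of
scope.

## Numerical choices in the fit

The logistic maximum-likelihood fit uses iteratively reweighted least
squares (Newton's method with the expected information, which equals the
observed information under the canonical logit link), with step-halving
whenever a step would decrease the log-likelihood. Convergence is
declared when the score max-norm falls below `tol` (default 1e-8);
`max_iter` defaults to 100. Separation is detected as coefficient
divergence (max |β| > 30) and raised as non-convergence carrying the
iteration state — no penalization is applied, because bootstrap
replicates may separate and the resampling layer must decide what to do.
Rank deficiency of the design matrix and single-valued D are rejected up
front. Non-converged bootstrap replicates are dropped and counted
(`n_effective` is reported); the run fails if fewer than
max(min(30, B), B/2) replicates survive, so tiny-B exploratory runs are
allowed but an unreliable production run is not.

## Randomness and reproducibility

Every stochastic component takes an integer seed or a
`numpy.random.SeedSequence`. Bootstrap replicate b uses the b-th spawned
child of the root seed, so enlarging B extends — never perturbs — the
replicate set, and the three schemes consume their streams in the same
order (case draws, subcohort draws, duplication draws), which makes them
bit-identical when m = 0. Study replicates similarly use spawned child
seeds, making results independent of the worker count.

## The synthetic cohort generator

The simulator emulates a Wilms'-tumor-style two-phase setting:

- r1 ~ Bernoulli(0.10): a cheap binary surrogate (the institutional
  histology call);
- r2 ~ N(0, 1): a standardized continuous auxiliary (age);
- Z | r1, r2 ~ Bernoulli(expit(γ0 + γ1 r1 + γ2 r2)): the expensive
  binary covariate (central-laboratory histology), with defaults
  γ = (−3.31, 4.79, 0.14) obtained by fitting this model to the National
  Wilms Tumor Study cohort (`nwtco`: central vs institutional histology
  and standardized age), giving marginal Pr(Z=1) ≈ 0.113;
- a trinomial adjustment covariate with category probabilities
  (0.16, 0.48, 0.36), coded as dummies x2, x3 against the last category;
- outcome Y ~ Bernoulli(exp(β0 + β1 Z + β2 x2 + β3 x3)) — a log-link
  binomial model, so (β1, β2, β3) are log risk ratios; defaults
  (0.96, −0.28, −0.39).

β0 is not free: using the independence of Z and the trinomial covariate,

    E[Y] = e^{β0} (q e^{β1} + 1 − q)(0.16 e^{β2} + 0.48 e^{β3} + 0.36),

with q = Pr(Z=1) computed by 60-node Gauss–Hermite quadrature over r2
mixed over r1, and β0 is solved so E[Y] equals the target event fraction
(default 0.154, i.e. ≈308 expected cases at N = 2,000). Calibration fails
loudly if any covariate pattern would receive an event probability above
one (the log link has bounded support). With a 20% subcohort this yields
E[m] = 0.20 × 0.154 × 2,000 ≈ 61.6 expected duplicated participants.

The γ defaults deserve a note: only the marginal q enters the outcome
distribution (the auxiliaries act purely through Z), so bias and coverage
conclusions are insensitive to how q is split across γ's, but the *scale*
of the β1 standard errors is sensitive to q itself. The nwtco-calibrated
q = 0.113 reproduces reference simulation SEs for β1 to within about
0.008 (and the β2/β3 SEs to ~0.001); the reference values are consistent
with q ≈ 0.10, but q was fixed from the Wilms data a priori and not tuned.

What the generator does not emulate: covariate measurement error,
missingness, any Z–trinomial dependence, or time-to-event structure.
Passing tests therefore demonstrate correctness of the estimators under
the stated sampling design, not robustness to those real-data features.

## The study runner and its scales

`run_study` repeats: generate cohort → draw case-cohort sample (20%
subcohort, all cases by default) → fit → compute the requested SEs →
record Wald-interval coverage of the true slopes. Failed replicates are
excluded from every aggregate symmetrically and counted (warning above
1% failures, error above 10%). Coverage is evaluated against the true
simulation β's.

The shipped desk-scale profile uses S = 2,000 replicates for
non-bootstrap summaries and S = 500 with B = 200 for bootstrap
summaries; the full-scale profile (S = 10,000, B = 2,000, behind
`caseboot study --full-scale`) reproduces the reference table directly.
At desk scale the Monte-Carlo SEs are ≈0.004 on the mean estimate,
≈0.003 on SE summaries and ≈0.010 on a coverage probability, which is
what the test tolerances reflect.

## Design choices that were genuinely open

- *Step 3 selection*: whether the m re-injected bootstrap cases are drawn
  with or without replacement from the n1 bootstrap case draws is not
  dictated by the design; we draw **without** replacement, mirroring the
  m distinct duplicated participants of the real sample.
- *m is held fixed* across replicates at its observed value: the
  bootstrap quantifies uncertainty conditional on the realized overlap,
  matching the design's sampling mechanism (the subcohort size, not m,
  is fixed by the investigator).
- *Proposed vs stratified on one sample*: the two schemes condition
  differently on which participants are duplicated, so on a single fixed
  sample their SEs differ by O(1/√m) (a few percent at m ≈ 60) even at
  B → ∞; they agree unconditionally, and the test suite checks exactly
  that (mean relative difference across independent designs ≈ 0), plus a
  10% per-sample sanity bound.
- *Robust vs model covariance*: the two are asymptotically equivalent
  with or without duplication (duplication biases both relative to the
  truth); the suite asserts ratio ≈ 1 and robust > empirical SD, not
  robust > model.
- *Subcohort size* is fixed (round-half-up of fraction × N), not
  per-participant Bernoulli; cases are always eligible for the subcohort.

## Known limitations

Binary-outcome risk-ratio designs only (no Prentice-style time-to-event
case-cohort analysis); no inverse-probability-weighted estimators; no
cluster-corrected sandwich grouping a participant's two pseudo-rows
(whether such a correction would be valid is an open question we do not
answer); Wald intervals only.
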