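# Methods

This note documents the statistical models implemented in `mobipw`, the
numerical choices behind them, what the synthetic cohort generator does and
does not emulate, and the design decisions that were genuinely open.

## Outcome and exposure derivation

The outcome is a five-level self-rated-health item dichotomized to
good = {very good, good} vs bad = {moderate, bad, very bad}. Two binary
exposures are derived from survey items: *high-quality green-space access*
(positive only when a participant reports access **and** answers "strongly
agree" to both the quality and the maintenance follow-up; participants
without access are negative) and *very green neighbourhood* (top level of a
four-level item vs the rest). Level labels are matched case-insensitively
after trimming. A missing value in any source item makes the derived value
missing; the analysis is strictly complete-case (no imputation — the tree
cannot handle missing values and surrogate splits are out of scope), with an
exclusion report recording per-column missingness and the retained fraction.
Continuous greenness exposures (NDVI-like, range ≈ 0.2–0.8) are taken as
given numbers; deriving them from imagery is out of scope.

## Weighting

**Binary exposure.** Propensity scores are maximum-likelihood logistic
regressions of exposure on the confounders (ordinal confounders enter as
numeric codes, nominal ones as indicator dummies). Stabilized weights
multiply the inverse (of the propensity for the exposed, of its complement
for the unexposed) by the *marginal* exposure probability, taken from the
raw sample; the note below on open choices explains why. Perfect separation
or non-convergence raises a positivity error instead of returning weights.

**Continuous exposure.** Generalized propensity scores: the exposure is
modelled linearly in the confounders; the conditional density f(E|X) is a
Gaussian kernel density estimate of the OLS residuals evaluated at each
record's residual, the marginal density f(E) a KDE of the exposure at each
record's value. Bandwidths use Silverman's rule (the common default;
exposed as a parameter). Stabilized weight = marginal / conditional density.

**Diagnostics.** Balance: per expanded confounder term, the absolute
standardized mean difference before and after weighting (binary exposure)
with the *unweighted* pooled SD as the one fixed denominator, so before and
after are on the same scale; or the absolute (weighted) exposure–covariate
Pearson correlation (continuous exposure). Terms with zero variance are
reported as 0 with a warning flag. The conventional 0.1 threshold flags
residual imbalance. Positivity: weight mean/min/max (a mean far from 1 or
extreme maxima indicate violations; defaults flag |mean−1| > 0.1 or
max > 20, both configurable) plus propensity-overlap quantiles by exposure
arm. No weight truncation is applied by default; a truncation knob exists
but is off.

## The node model and the tree

Each node fits the two-parameter weighted logistic model
`logit P(Y=1) = β₀ + β₁E` by Newton/IRLS with step-halving on the weighted
Bernoulli log-likelihood; weights enter as frequency weights everywhere
(likelihood, scores, information). The fit returns per-record score
contributions `s_i = w_i (y_i − p_i) x_i`, the model-based covariance
(inverse observed information) and the HC0 sandwich covariance (HC1
configurable). With unit weights and a binary exposure the fit is saturated:
exp(β₁) equals the 2×2 cross-product ratio and the model SE of β₁ equals
Woolf's √(1/a+1/b+1/c+1/d) — both are used as exact oracles in the tests.
One-class outcomes and constant exposures are degenerate errors; separation
(|β| > 30) or hitting the iteration cap marks the fit non-converged, which
closes the node (or invalidates the candidate split that produced it).

**Instability tests.** Candidate moderators are screened with M-fluctuation
tests on the decorrelated cumulative score process
`W(t) = Ĵ^{-1/2} Σ_{i≤t·n} s_(i) / √n`, with Ĵ the outer-product-of-scores
matrix (records ordered by the moderator; singular Ĵ skips testing and
closes the node, an individual degenerate moderator is skipped with a
warning). For ordered moderators the statistic is
`max_t ||W(t)||² / (t(1−t))` over candidate cut fractions:

* many distinct values (> 40 cut points, i.e. continuous moderators): the
  supremum over the trimmed interval [0.1, 0.9] (trim configurable),
  compared against the continuum limit — the supremum of a normalized
  squared Brownian bridge — simulated once per (df, trim) on a 1000-point
  grid with 50 000 paths and cached;
* few distinct values (binary, Likert-type ordinal): the maximum over the
  *observed* cut fractions only, with the p-value simulated from the exact
  finite-dimensional Brownian-bridge marginal at those fractions (40 000
  paths, cached per fraction set; a single cut point reduces to an exact
  χ²(2) tail). Using the continuum null here would be noticeably
  conservative; the discrete null is the faithful asymptotic reference and
  passes the type-I-error calibration test. Trimming is not applied to the
  discrete case.

Nominal moderators aggregate decorrelated scores within levels; the
statistic is asymptotically χ² with (C−1)·k degrees of freedom. All
simulated nulls use fixed internal seeds, so p-values are deterministic.

**Selection, split search, stopping.** The moderator with the smallest
Bonferroni-adjusted p-value (adjusting by the number of testable candidates;
the adjustment is on by default and configurable) splits the node if that
p-value is below α = 0.05; ties keep input order. The split point maximizes
the summed maximized child log-likelihoods: ordered moderators over observed
thresholds (thinned to 200 quantile-spaced candidates for continuous ones),
nominal moderators over all binary level partitions (exhaustive up to 10
levels). Candidates leaving a child below `minsize` = 100 records
(unweighted counts, per the protocol) or with a degenerate/non-converged
child fit are discarded; objective ties keep the first candidate in
canonical order (ascending thresholds / subset enumeration order) for
determinism. Growth recurses until no significant instability, no
admissible split, fewer than 2·minsize records, or depth 3. Every executed
split satisfies the likelihood-gain invariant (children's summed
log-likelihood ≥ parent's), checked in the tests.

## Per-subgroup inference

Terminal nodes report OR = exp(β₁) with Wald CIs on the log scale from
robust SEs; for continuous exposures OR and CI are rescaled to a 0.1-unit
increment (exp(0.1·β₁)). Risk differences (binary exposure) are weighted
arm differences with percentile-bootstrap CIs: B = 2000 seeded resamples of
the node's records with replacement, weights carried along, tree structure
held fixed; replicates losing an exposure arm are redrawn up to 100 times,
then counted and reported. The percentile method was chosen over BCa for
transparency; B and the method are configurable. Sibling subgroups are
classified by per-parameter Wald contrasts
`z_j = (β_j^L − β_j^R)/√(se_L² + se_R²)`: a significant slope contrast means
*slope heterogeneity* (genuine effect-modification on the OR scale), an
intercept-only contrast a *prevalence difference*; an informal CI-overlap
indicator is emitted alongside, since published analyses often read
heterogeneity off CI plots.

## Synthetic cohort generator

The generator emulates the study design so that every stage has a testable
ground truth: mixed-type covariates with stated marginals (eight
socio-demographic confounders; a 40-covariate moderator battery of binary,
5/4-level ordinal and 3–4-level nominal items), a confounded exposure model
(logistic in the confounders for binary exposures; linear with Gaussian
noise clamped to the printed min/max for continuous ones), and a logistic
outcome model `logit P(Y=1) = β₀(g) + β₁(g)·E + Σ outcome_strength·X` whose
(β₀, β₁) vary over a planted, mutually exclusive and exhaustive partition
(conjunction depth ≤ 3, matching the tree's depth cap). Random streams are
split per column from the master seed (CRC32 of the column name), so adding
a covariate never perturbs the others' draws; identical configs are
bitwise-reproducible. Cell-wise missingness can be injected per column.

The named default configuration reproduces the study's printed marginals:
n = 2534; exposure prevalence 774/2534 ≈ 0.305 (quality) or 2008/2534 ≈
0.792 (greenness); continuous exposure mean 0.47 (SD 0.09, clamped
[0.16, 0.73]) or 0.50 (SD 0.09, [0.27, 0.71]); marginal good-health rate
0.76. Exposure-model intercepts and a common outcome offset are calibrated
numerically (Brent root-finding on a fixed 40 000-record internal
quasi-sample), so the targets are hit by construction rather than by magic
constants. For continuous exposures the confounder contributions are mapped
from log-odds to exposure units (×0.07, giving a confounder-driven exposure
SD near 0.03, about a tenth of the exposure variance) with the residual
variance assigned to noise.

The default planted truth has three subgroups: a discrimination-based
subgroup (prevalence 15%, lower good-health prevalence ≈ 0.52 before the
common calibration offset, OR 1.3 — an intercept-contrast leaf), and an
education split of the remainder into a basic-education leaf with OR 2.66
and a higher-education leaf with OR 0.91 (per-0.1-unit ORs 1.35/0.95 for
continuous exposures), with unexposed prevalences ≈ 0.68/0.78. The
discriminated-leaf contrast is deliberately strong enough that the intercept
split is identified first, mirroring the intended "one intercept split, one
slope split" structure. Truth variants `constant` (one (β₀, β₁) everywhere;
used for stopping-rule calibration) and `null` (β₁ = 0; used for the
weighting-debias experiments, where logistic non-collapsibility makes the
null the only unambiguous causal target) share the same covariate battery;
a `confounding_scale` knob strengthens all confounder effects for the
strong-confounding debias scenario (scale 2).

**What the generator does not emulate:** covariate correlation structure
(covariates are mutually independent — real survey items are not, which
makes real Bonferroni adjustment more conservative and real balance harder),
item-level measurement error, informative missingness, spatial structure in
the exposure, and any non-logistic outcome mechanism. Passing tests
demonstrate the *procedure's* operating characteristics under its stated
assumptions, not robustness to their violation.

## Operating characteristics (recomputed, not asserted from memory)

The acceptance script and test suite recompute, at the study scale
(n = 2534): the stopping rule keeps root-only trees in ≈ 95% of replicates
under a constant-parameter generator with 40 null moderators (200
replicates, 99% binomial band); the planted split covariates are recovered
on the correct branch in ≥ 80% of 100 replicates; under a null conditional
effect with strong confounding the unweighted OR excludes 1 and the
stabilized-weighted robust CI covers 1 in ≥ 90% of 200 replicates, with all
post-weighting SMDs < 0.1 at n = 10⁴; and the supLM null rejection rate at
α = 0.05 stays inside the 99% binomial band over 500 replicates at
n = 2000. Replicate counts are the package's chosen problem sizes: large
enough for the stated binomial bands, small enough that the whole suite
runs in minutes on one CPU.

## Known limitations

* Post-selection inference: node CIs condition on the discovered tree; no
  honest/sample-splitting correction is applied (out of scope).
* The weighted likelihood-ratio interaction test is only approximately
  calibrated under IPW; a robust Wald interaction z-statistic is emitted
  alongside it.
* The bootstrap resamples within nodes with the tree held fixed; tree
  rebuilding per replicate is a different (and much more expensive) target.
* Weights are treated as frequency weights in the score process and its
  covariance (no effective-sample-size substitution); robust SEs are relied
  on for inference, matching the weighting protocol.
* The marginal (numerator) probabilities/densities of the stabilized
  weights are estimated on the raw sample — the standard choice where the
  protocol is silent.
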