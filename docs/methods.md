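# Methods

This note documents the statistical content of `chegap`: what each stage
computes, the modelling assumptions, the defaults and why they were chosen,
and what the synthetic-data validation does and does not establish.

## Catastrophic health expenditure (CHE)

Annual household health expenditure is

    H = direct_medical + direct_nonmedical + lost_days × daily_valuation,

where the third term monetises productivity losses by the human-capital
approach (patient plus caregiver days at a per-household daily valuation;
pre-monetised losses such as premature death or early retirement are
expected to be folded into days × valuation by the data provider, since no
separate valuation formula is modelled). All components share a 12-month
recall window and currency is treated as a unitless positive real — every
downstream quantity is a within-survey share, so flags are invariant to
rescaling all monetary components by a common factor.

A household is catastrophic when its health share strictly exceeds a
threshold t ∈ [0.10, 0.40] (default 0.10):

    share = H / D,    catastrophic ⇔ share > t.

The default denominator D is total household expenditure with health
spending included (budget-share convention): D = food + nonfood_nonhealth
+ H. Because survey practice varies, both choices are exposed as flags:
`denominator_kind` ∈ {total, nonfood} (nonfood = D − food) and
`include_health_in_denominator`. The strict inequality means a share
exactly at the threshold does not count; the tie is measure-zero on real
expenditure data and is pinned by a test. Households with a zero
denominator have an undefined share and are excluded with an itemised
count.

Headcounts are reported in two conventions: within-stratum (flagged /
stratum size) and share-of-total (flagged / full analytic sample). Both
appear in published tables of this design, and they answer different
questions; `che_headcount` returns both rather than deciding.

## Wealth index

The asset inventory (35 binary indicators by default) is pruned in two
steps before scoring:

1. **Prevalence filter** — assets owned by more than 95% or fewer than 5%
   of households are removed (boundary values retained; the rule is
   strict). Near-constant indicators carry almost no variance and
   destabilise a correlation-matrix PCA.
2. **Correlation filter** — indicators whose pairwise correlations fall
   outside [0.1, 0.9] in absolute value are handled by greedy iterative
   removal: each round drops the variable with the most out-of-range
   pairs (ties broken by lower prevalence, then name), recomputing the
   matrix until no violation remains. A rule stated entry-wise on the
   correlation matrix cannot be applied to a PCA input directly — a
   matrix entry cannot be deleted — so variable-wise greedy removal is
   the implemented interpretation, and every removal is logged with its
   reason.

The retained indicators are standardised and the first eigenvector of
their correlation matrix (not covariance: binary indicators with
heterogeneous prevalence would otherwise be weighted by prevalence alone)
gives unit-norm loadings. The sign is fixed by an orientation anchor —
by default the highest-prevalence retained asset loads positively, so
higher score means wealthier. Scores are cut at their 20/40/60/80th
percentiles into quintiles labelled poorest…richest; tied scores stay in
one bin (a score exactly at a cutpoint falls in the lower bin), so bin
sizes may be unequal when scores cluster — equal-count binning would
misrepresent ties.

## Chi-square screening

Each candidate covariate is cross-classified against the CHE flag and
tested with the Pearson statistic Σ(O−E)²/E, no continuity correction
(a config flag could not restore Yates' correction to published numbers
either way, so the simpler uncorrected default is pinned and documented).
Variables with p < α (default 0.05) enter the decomposition, in candidate
order; the full per-variable report is kept for audit. Rows carrying the
missing sentinel are excluded per table with the count reported, and
screening runs on the same analytic sample as the decomposition so the
selected set is reproducible from a single sample definition. No
multiple-testing correction is applied (screening is a gate, not an
inferential claim).

## Twofold decomposition

Let A be the comparison group (non-insured; coded 1) and B the reference
(insured; coded 0). With group-wise logistic MLEs b_A, b_B and F the
logistic function, the incidence gap on the probability scale is

    R = mean_i F(x_Ai'b_A) − mean_j F(x_Bj'b_B)
      = [mean_i F(x_Ai'b_A) − mean_j F(x_Bj'b_A)]   (E, endowments)
      + [mean_j F(x_Bj'b_A) − mean_j F(x_Bj'b_B)]   (C, coefficients),

averaging transformed linear predictors over each group's observed rows.
E is the part of the gap attributable to composition differences
evaluated at the comparison group's coefficients; C the part attributable
to effect differences at the reference group's composition. E + C = R
holds identically and is asserted at 1e-10 on every call, as is the
exhaustiveness of the detailed terms. A positive R means higher CHE
incidence among the non-insured. Percent contributions 100·E/R and
100·C/R sum to 100 whenever R ≠ 0; individual percentages may lie far
outside [0, 100] when E and C have opposite signs — that is a property of
the split, not an error.

**Detailed attribution** uses first-order (Yun) weights,

    E_k = E · b_Ak(x̄_Ak − x̄_Bk) / Σ_j b_Aj(x̄_Aj − x̄_Bj),
    C_k = C · x̄_Bk(b_Ak − b_Bk) / Σ_j x̄_Bj(b_Aj − b_Bj),

with the intercept in the C family (its composition entry is 1). When a
weight denominator vanishes while its numerator terms do not, attribution
is arbitrary; the terms are zeroed and flagged unstable while the
aggregates remain valid. A substitution oracle (sequentially replacing one
covariate's composition at a time) agrees with these weights to ~10%
relative at moderate effect sizes, bounding the linearisation error.

**Dummy coding.** Treatment (reference-cell) coding is the default,
mirroring tables that print explicit reference rows. Detailed
contributions under treatment coding depend on the reference level;
deviation-from-mean normalisation is available as a flag: each
categorical variable's coefficients are re-expressed to sum to zero over
all its levels (the grand mean folds into the intercept), which makes the
detailed contributions reference-invariant (property-tested over all
reference choices). Aggregates are identical under both codings.

**Logistic MLE.** Fitting is Newton iteration (IRLS) with step-halving on
log-likelihood decrease, score max-norm tolerance 1e-8, at most 100
iterations, covariance from the inverse observed information — fixed so
results are bit-stable across runs. Perfect separation is detected as a
coefficient exceeding 15 in magnitude with a non-vanishing score and
raises an error naming the covariate; an aliased design raises a
collinearity error. The implementation is cross-checked in the test suite
against an independent Newton fit (statsmodels) to 1e-6 on a 20-column
design.

**Standard errors.** Delta-method propagation of both coefficient
covariance matrices through R, E, C and each detailed term; Wald p-values
and 95% CIs as estimate ± 1.96·SE. By default the aggregate variances
additionally include the sampling variance of the per-group means of the
transformed linear predictors (households are random draws, so the
covariate composition is stochastic); this matches a household-resampling
bootstrap, which is provided (default 500 replicates) for
cross-validation — the two agree within ~25% on synthetic data at
n = 2000/group. Conditional-on-design inference (coefficient uncertainty
only, the convention of some published decomposition software) is
available via `design_variance=False`. Detailed-term SEs are always
conditional; the neglected covariance between estimated coefficients and
their own group's design means is second-order at these sample sizes, and
shows up as empirical CI coverage of ~0.92 rather than 0.95 in the
replication tests.

## Synthetic data generator

Two modes, both fully determined by the config seed.

**Outcome-level** (decomposition validation): covariates are drawn
independently within each insurance stratum from per-group categorical
marginals; the CHE flag is Bernoulli with probability F(x'β_group). The
generator returns the truth: the coefficients, the counterfactual-mean
E/C/R over the realized designs (the estimand conditional on the drawn
covariates), and the population E/C/R computed exactly by convolving the
independent per-covariate effect distributions (3840 support points for
the default nine covariates) — the latter is free of covariate sampling
noise and is the target used for CI-coverage tests. Expenditure profiles
are synthesised to encode each household's flag unambiguously at the 10%
threshold, so the measurement stage reproduces the generated outcome.

**Expenditure-level** (measurement and wealth validation): expenditure
components are lognormal (strictly positive, right-skewed — the standard
shape for health spending), lost days Poisson; the direct-medical scale is
calibrated by bisection until the realized headcount is within ±1
percentage point of the stratum target, erroring if unattainable. Assets
follow a one-factor structure: a latent standard-normal wealth score z per
household, asset j owned with probability F(α_j + λ_j z). Default
intercepts span (−3.5, 3.5) so prevalences cover ~3%–97% and both wealth
filters have realistic work; default loadings are 1.2.

**Default conditions.** Group sizes 194 insured / 631 non-insured and
per-stratum covariate marginals follow the reference survey's printed
per-stratum counts (see `chegap.benchmarks`). The reference study prints
no group-wise logit coefficients, so defaults were chosen once on
substantive grounds — chronic illness (+1.4) and traditional-medicine use
strongly positive, a rising age gradient, moderate family-size and tenure
effects, with ownership, traditional-medicine and intercept differing
between groups so both E and C are nonzero — and intercepts were solved
analytically so within-stratum CHE prevalence under the default marginals
is 0.22 (insured) and 0.30 (non-insured), an overall gap near 0.08, the
order of magnitude the reference study reports.

**What passing synthetic tests shows — and does not.** Covariates are
independent within stratum (only marginals are published; independence is
the minimal assumption, and a pairwise-dependence hook can be added via
custom marginal tables per group). Real surveys have correlated
covariates, measurement error, recall bias and missingness patterns the
generator does not emulate; recovery of E and C here validates the
estimator's correctness, not robustness to those features.

## Reference-survey benchmark counts

`chegap.benchmarks` carries the published descriptive counts of the
n = 825 reference survey (marginals and per-stratum cross counts) used as
generator defaults and integer-arithmetic test fixtures. Two printed
tables are mutually inconsistent there — the CHE-by-insurance cross
(46/201/148/430, CHE total 194) versus the marginal CHE count (247) — and
the package reproduces each table as printed without reconciling them.
For the same reason the reference study's decomposition table cannot be
reproduced numerically from published information; the synthetic-recovery
tests are the validation surface for the decomposition core.

## Problem sizes used in the validation suite

Chosen to make Monte-Carlo bands tight at desk scale: 200 outcome-level
replicates at n = 1000/group for unbiasedness and CI coverage (band
[0.91, 0.985] at nominal 95%); 2000 null tables (n = 800, 2×5) for
chi-square type-I calibration against [0.03, 0.07]; n = 2000 households
for wealth-index recovery (|corr| with the latent score > 0.9, quintile
Spearman > 0.85); n = 100 000 draws for generator marginal recovery at
three binomial SDs.

## Survey-design arithmetic

`sample_size` reproduces the printed design chain of the reference
survey: base n = z²p(1−p)/d² truncated to an integer (384 for p = 0.5,
d = 0.05, z = 1.96 — the exact value 384.16 is truncated, not rounded
up, matching the published arithmetic), non-response inflation rounded up
(×1.10 → 423), then the design-effect multiplier (×2 → 846). The
truncation-then-ceiling sequence is deliberately the published arithmetic
rather than an idealised all-ceiling convention, and is pinned by test.

## Missing data

`referral_history` is the only field allowed to be missing, via an
explicit `"missing"` sentinel (never an empty cell), making listwise
behaviour auditable. The pipeline offers `listwise` (drop households with
a missing value among the analysed covariates) and `drop_variable` (drop
the covariate, keep all households); published reports of this design do
not always state which was used, so neither is guessed — the mode is
explicit config.

## Known limitations

- Logit link only; no probit or count outcomes, no survey weights, no
  threefold (interaction) decomposition.
- Detailed SEs condition on the design; aggregate SEs ignore the
  coefficient–composition covariance (see above).
- The wealth index is classical PCA on binary indicators; no polychoric
  PCA or multiple correspondence analysis.
- No impoverishment metrics (overshoot, mean positive overshoot,
  poverty-line logic) — the flag and headcount only.
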