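# chegap

Catastrophic health expenditure (CHE) measurement and logit-based twofold
decomposition of the CHE incidence gap between insured and non-insured
households.

Out-of-pocket health spending is the dominant financial risk to households
in low-income settings; a household whose health spending exceeds a fixed
share of its budget (conventionally 10–40%) has incurred *catastrophic*
health expenditure. Community-based health insurance (CBHI) is meant to
protect against exactly this, so health-financing equity analyses ask: how
large is the CHE incidence gap between non-insured and insured households,
and how much of it is explained by who the households are (their covariate
composition) versus how their characteristics translate into risk (the
covariate effects)? `chegap` is a library for analysts running that
analysis on household survey microdata — or validating it end to end on
synthetic data with known truth.

## What it computes

**CHE measurement.** Annual health expenditure per household is
H = direct medical + direct non-medical + lost days × daily valuation
(human-capital approach for indirect costs). The household is flagged when
H/D > t, with D total household expenditure (health included; non-food
denominator available) and t the threshold (default 0.10).

**Wealth index.** DHS-style asset index: binary asset indicators filtered
by prevalence (keep 5% ≤ p ≤ 95%) and by an iterative pairwise-correlation
rule (|r| inside [0.1, 0.9]), scored by the first principal component of
the correlation matrix, ranked into quintiles with tie-preserving bins.

**Screening.** Pearson chi-square (no continuity correction) of each
covariate against the CHE flag; covariates with p < 0.05 enter the model.

**Twofold decomposition.** With group-wise logistic MLEs β_A (non-insured,
comparison) and β_B (insured, reference), and F the logistic function,

    R = mean F(X_A β_A) − mean F(X_B β_B)
      = [mean F(X_A β_A) − mean F(X_B β_A)]  +  [mean F(X_B β_A) − mean F(X_B β_B)]
                      E (endowments)                      C (coefficients)

on the probability scale, with detailed per-covariate attribution by
first-order (Yun) weights, delta-method standard errors (a household
bootstrap is provided for cross-validation), optional deviation-from-mean
normalisation making detailed terms reference-level invariant, and the
identities E + C = R and Σ detailed = aggregate enforced at 1e-10.

**Synthetic surveys.** Two generator modes: expenditure-level (lognormal
spending calibrated to a target CHE prevalence, one-factor asset
inventory) and outcome-level (known group logit coefficients, returning
the true E and C for recovery testing). Defaults emulate a reference CBHI
survey of 825 households (194 insured / 631 non-insured).

## Worked example

```python
from chegap import SyntheticConfig, decompose_groups, generate_outcome_level, screen_variables
from chegap.che import che_flag
from chegap.survey import records_to_frame
from chegap.synthetic import OUTCOME_COVARIATES

config = SyntheticConfig(seed=42, n_insured=2000, n_non_insured=2000)
records, truth = generate_outcome_level(config)
frame = records_to_frame(records)
frame["che"] = ["yes" if che_flag(r.expenditure).catastrophic else "no" for r in records]

report = screen_variables(frame, list(OUTCOME_COVARIATES), alpha=0.05)
result, *_ = decompose_groups(frame, report.selected)
print(f"gap R = {result.R:.4f}  (p = {result.p_R:.4f})")
print(f"  E = {result.E:.4f} ({result.pct_E:.1f}% of R, se {result.se_E:.4f})")
print(f"  C = {result.C:.4f} ({result.pct_C:.1f}% of R, se {result.se_C:.4f})")
```

prints

```
gap R = 0.0770  (p = 0.0000)
  E = -0.0329 (-42.7% of R, se 0.0075)
  C = 0.1099 (142.7% of R, se 0.0140)
```

The non-insured CHE incidence exceeds the insured one by 7.7 percentage
points. The endowment component is negative: on composition alone the
non-insured group would have *lower* incidence (it is, for instance, less
burdened by chronic illness in this draw), so covariate composition
narrows the gap by 42.7% while differences in covariate effects account
for 142.7% — percentages outside [0, 100] are expected when E and C have
opposite signs, and they always sum to 100. The generating truth for this
configuration is E = −0.0526, C = 0.1387 (the estimate screens one truly
active covariate out at α = 0.05, as a real analysis would). The
`examples/` directory has one short script per capability: simulation,
CHE measurement, wealth index, screening + decomposition, full pipeline;
a thin CLI (`chegap simulate|che|wealth|screen|decompose|run|samplesize`)
wraps the same stages.

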