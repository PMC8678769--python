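# bptraj

Group-based trajectory modelling (GBTM) of 24-hour blood-pressure courses
after intravenous thrombolysis, and their association with early stroke
outcomes.

## The problem

After alteplase thrombolysis for acute ischaemic stroke, blood pressure is
monitored intensively for 24 h (every 15 min for 2 h, every 30 min to 8 h,
then hourly — 37 readings).  Single summaries (admission BP, 24-h mean, SD,
successive variation) discard the *shape* of the BP course, yet patients
cluster into distinct longitudinal patterns — e.g. a small low-BP group, a
large "rapid drop to a medium plateau" group, and a continuously fluctuating
very-high group — and these patterns carry different risks of early
neurological deterioration (END), early neurological improvement (ENI) and
3-month disability (modified Rankin Scale 3–6).

`bptraj` is for biostatisticians and stroke researchers who want to run this
trajectory analysis end to end on serial BP data, or to study its operating
characteristics on realistic synthetic cohorts.

## The model

For patient *i* with readings *y<sub>it</sub>* at hours *t* ∈ [0, 24], GBTM is
a finite mixture of polynomial regressions with a censored-normal (CNORM)
outcome distribution:

> P(y<sub>i</sub>) = Σ<sub>j=1..J</sub> π<sub>j</sub> ∏<sub>t</sub>
> φ( y<sub>it</sub> ; β<sub>j0</sub> + β<sub>j1</sub>t + … +
> β<sub>j4</sub>t⁴ , σ )

with group shares π<sub>j</sub> from an intercept-only multinomial logit
(θ₁ = 0) and optional censoring mass at scale bounds.  Estimation is
multi-start EM; the E-step is the posterior membership probability, the
M-step a posterior-weighted polynomial least squares.  The number of groups
is chosen by BIC = k ln n − 2 ln L among candidates passing two adequacy
rules: every group holds ≥ 5% of patients by modal assignment, and each
group's average posterior probability of assignment (APPA) exceeds 0.7.

Around the mixture model the package provides

* classic BP-variability parameters (mean / max / min / range / SD / SV over
  24 h and day/night windows, admission and post-infusion point values),
* nested logistic models (crude; + age/sex; + covariates screened at
  p < .1) reporting odds ratios with Wald 95% CIs, and ROC AUCs with
  Hanley–McNeil intervals,
* a synthetic cohort generator whose defaults reproduce the published
  structure: five SBP and four DBP trajectory groups with their printed
  polynomial equations and membership shares, outcome models with the
  printed odds ratios, and intercepts calibrated to the printed prevalences
  (END 19.0%, ENI 37.1%, mRS 0–2 68.6%).

## Worked example

```python
import bptraj as bt

cohort = bt.simulate_cohort(seed=1)                    # n=353, 37-point grid
sel = bt.select_model(cohort.series("SBP"), j_range=range(2, 7),
                      n_starts=2, tol=1e-6, seed=1)
print(sel.result.summary())
```

```
Group-based trajectory model (SBP), J=5, n=353
logL=-46145.347  k=30  AIC=92350.694  BIC=92466.688  sigma=7.957 mmHg
adequacy: min share 0.062 (>= 0.05), min APPA 1.000 (> 0.7) -> PASS

group   share   APPA  coefficients (intercept first)
    1   0.062  1.000  [115.2, -4.327, 0.5874, -0.02861, 0.0004616]
    2   0.218  1.000  [136.4, -5.993, 0.7639, -0.0391, 0.0006885]
    3   0.348  1.000  [151.1, -5.906, 0.7042, -0.03297, 0.0005988]
    4   0.241  1.000  [165.3, -3.925, 0.2861, -0.007027, 5.446e-05]
    5   0.130  1.000  [174.2, -3.044, 0.313, -0.01227, 0.0001711]
```

BIC selects five SBP groups; the recovered intercepts (115.2, 136.4, 151.1,
165.3, 174.2 mmHg) and shares (6.2–34.8%) match the generating trajectory
equations, and every group is adequately classified (APPA 1.0).  Relating the
modal groups to the 3-month outcome (reference: the medium group 3):

```python
m = cohort.truth.merge(cohort.outcomes, on="patient_id")
print(bt.trajectory_association(m["sbp_group"], m["mrs_unfavorable"],
                                reference=3, models=(1,)).round(3))
```

```
exposure  model_id  or_hat  ci_low  ci_high  p_value  converged
 group_1         1   0.906   0.328    2.502    0.849       True
 group_2         1   1.094   0.589    2.033    0.775       True
 group_4         1   1.387   0.770    2.498    0.275       True
 group_5         1   2.417   1.204    4.849    0.013       True
```

The continuously fluctuating very-high group carries a significantly raised
odds of an unfavourable outcome (OR 2.42, 95% CI 1.20–4.85) in this cohort,
as the generator's effect sizes dictate.

A `bptraj` console command exposes the same stages
(`simulate`, `fit`, `select`, `summarize`, `associate`, `report`).

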