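# Methods

## Trajectory model

Each patient contributes one series per channel (SBP or DBP): readings
y_it (mmHg) at times t (hours since infusion start, 0–24).  Conditional on
latent group j, readings are independent draws from a censored normal
distribution centred on the group's polynomial mean trajectory
μ_j(t) = β_j0 + β_j1 t + … + β_jm t^m with common residual scale σ.  Interior
readings contribute the normal density; readings at or beyond a scale bound
contribute cumulative mass (log Φ((S_min−μ)/σ) below, log(1−Φ((S_max−μ)/σ))
above).  Group membership follows an intercept-only multinomial logit with
θ₁ = 0, so π_j = exp(θ_j)/Σ_k exp(θ_k).

Assumptions worth keeping in mind: a *single* shared σ across groups and
times (a per-group σ is available via `shared_sigma=False`), within-patient
independence of residuals given the group, and membership independent of
covariates.  Time is raw hours, uncentred — the shipped published
coefficients are only meaningful on that scale.

### Estimation

EM with multiple starts.  The E-step computes posterior membership in the
log domain (log-sum-exp).  With inactive censoring the M-step is closed
form: posterior-weighted polynomial least squares per group, pooled
weighted RMS residual for σ, and π as posterior column means.  With active
bounds those closed forms seed a short L-BFGS ascent of the expected
complete-data log-likelihood.  The observed-data log-likelihood is
non-decreasing across iterations (tested to 1e−8).

Starts: (1) a quantile cut of patients by their mean BP level, (2) k-means
on the mean level alone, (3) k-means on (mean level, OLS slope), then
jittered quantile cuts.  Level-based starts matter: the published groups
differ mainly in level, and with a 6% group a poor start reliably lands in
a merged-groups local optimum several hundred log-likelihood units below
the global one.  The best converged start is kept; a start whose smallest
group drops below one expected patient is discarded as collapsed.

Numerical choices: convergence when the relative log-likelihood change is
below `tol` (default 1e−8) within `max_iter` = 500; σ floored at 0.5 mmHg
to prevent degenerate spikes; modal-assignment ties broken toward the
lowest group label; final groups relabelled in ascending order of mean
trajectory over the observed grid, which makes labels invariant to
initialisation order.

### Selection and adequacy

Candidates J = 2…6 are fitted (quartic shapes by default — the published
group equations are cubic or quartic, so degree 4 is the ceiling) and the
minimum-BIC candidate among those passing adequacy is chosen; BIC uses
n = patients (switchable to observations).  Adequacy: every group's modal
share ≥ 5% (inclusive) and every group's average posterior probability of
assignment strictly > 0.7.  If nothing passes, the best-BIC fit is returned
flagged inadequate.  The `prune` order policy backward-drops each group's
highest-degree term while its Wald |z| < 1.96 and refits; the SEs come from
the posterior-weighted least-squares covariance of the final M-step — a
complete-data approximation (standard in trajectory software) that ignores
classification uncertainty, so pruning is mildly anti-conservative.

## BP-variability parameters

Over a window (full 24 h, daytime, nighttime): mean, max, min,
range = max−min, sample SD (divisor n−1), and SV — implemented as the
root-mean-square of successive differences, the usual reading of
"successive variation" in the BP-variability literature; a coefficient-style
variant normalised by the window mean is available (`sv_cv`).  Daytime
defaults to clock time [06:00, 22:00), half-open, anchored by the infusion
start clock time; both window and anchor are configurable since no single
convention exists.  Point values: admission = earliest reading;
post-thrombolysis = reading nearest t = 1 h (end of the 1-h infusion), ties
toward the earlier time.

## Outcome associations

Nested logistic models: model 1 crude; model 2 adds age and sex; model 3
adds every remaining covariate passing a univariate logistic screen at
p < .1 (likelihood-ratio test for multi-level categorical blocks).  Fits
use Newton/IRLS with observed-information Wald covariance; any coefficient
beyond ±15 on the logit scale flags quasi-separation and the results carry
`converged=False` rather than being suppressed — with a 6% group and a 19%
outcome this happens regularly at n = 353, as it would in real cohorts.
References: SBP group 3 and DBP group 2 (both configurable).  Continuous BP
parameters enter per unit (per mmHg); a per-SD option exists.  No
multiple-testing adjustment is applied; α = 0.05 two-sided.

ROC AUC is the Mann–Whitney rank statistic (ties count ½), with the
Hanley–McNeil normal-approximation CI clipped to [0, 1] and a normal test
against 0.5.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

* **Grid**: 37 readings — every 15 min to 2 h, every 30 min to 8 h, hourly
  to 24 h.
* **Trajectories**: the shipped per-group polynomials and membership shares
  for 5 SBP and 4 DBP groups.  Residual noise defaults to i.i.d. Normal
  with σ = 8 (SBP) / 6 (DBP) mmHg, chosen so within-group spread roughly
  fills the gaps between adjacent group bands without erasing them; a
  stationary AR(1) option (marginal σ, lag-1 ρ in measurement index) is a
  stress test, not a claim about real autocorrelation.
* **Membership**: by default group counts are the largest-remainder
  rounding of n·π with shuffled labels, reproducing the published cohort's
  fixed group sizes at n = 353 (22/77/123/85/46); i.i.d. multinomial draws
  are available via `membership="multinomial"`.
* **Covariates**: age ~ N(62.49, 11.79²), male sex Bernoulli(0.728),
  glucose ~ N(6.78, 3.0²) truncated at 2 mmol/L (mean/SD read off the
  cohort's descriptive tables), onset clock time uniform over 24 h.
* **Outcomes**: each of END, ENI and unfavourable mRS is Bernoulli with a
  logistic linear predictor over group effects (shipped crude odds ratios)
  plus an optional per-mmol/L glucose effect on centred glucose.  The
  intercept is calibrated by 1-d root finding (bisection to 1e−10) so the
  *marginal* rate matches the target prevalence, integrating over the joint
  group distribution (independent SBP × DBP) and, when active, the glucose
  distribution by Gauss–Hermite quadrature.  Each outcome is driven by one
  channel (END, mRS → SBP; ENI → DBP), so a crude refit on that channel's
  groups recovers the generating conditional OR without cross-channel
  confounding; both-channel effects are supported.  Outcomes are drawn
  independently given covariates; an optional joint-categorical mode makes
  END and ENI mutually exclusive.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: antihypertensive treatment dynamics (the fluctuating
top groups' polynomials already embody the treated pattern), NIHSS score
paths behind the binary outcome labels, missing or irregular readings,
SBP–DBP within-patient correlation, and any dependence of group membership
on covariates.  All randomness flows from a single seeded generator;
cohorts are bit-reproducible.

## Problem sizes

The test suite and the acceptance script use sizes at which each check is
statistically meaningful but quick: structure recovery at the published
n = 353 (selection frequency over 20 seeds with 2 EM starts and tol 1e−6 —
sufficient for the well-separated published trajectories); effect recovery
at n = 50,000–100,000 so the Monte-Carlo error of a refitted OR sits well
inside the ±10–15% bands; prevalence calibration at n = 100,000 (binomial
SE ≈ 0.15 pp); null CI coverage over 500 replicates of n = 500.

## Known limitations

Standard errors for trajectory coefficients are complete-data
approximations; no sandwich or mixture-Hessian variance is provided.  The
multinomial-logit membership model carries no predictors (by design).  BIC
with n = patients is a convention, not a theorem, for mixtures of
longitudinal series.  Very small groups (a few patients) can trigger
quasi-separation in crude outcome models at realistic cohort sizes; results
are flagged, not repaired — penalised (Firth) logistic regression is out of
scope.
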