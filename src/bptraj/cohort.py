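"""Synthetic post-thrombolysis cohort generator.

Emulates the statistical structure the trajectory analysis assumes: patients
draw a latent SBP group (5 groups) and DBP group (4 groups) with the published
membership proportions, their readings follow the published polynomial mean
trajectories on the 37-point 24-h monitoring grid plus Gaussian noise, and the
binary outcomes (END, ENI, unfavourable 3-month mRS) follow logistic models
whose group odds ratios are the published estimates and whose intercepts are
calibrated so the marginal event rates match the published prevalences
(END 19.0%, ENI 37.1%, mRS 3-6 31.4%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from .series import BPSeries
from .trajectories import TrajectoryShape, group_table

__all__ = [
    "DEFAULT_SCHEDULE",
    "measurement_grid",
    "OutcomeSpec",
    "CohortConfig",
    "Cohort",
    "sample_bp_series",
    "calibrate_intercept",
    "sample_outcomes",
    "simulate_cohort",
    "default_outcome_specs",
]

# (step_h, end_h) segments, contiguous from t=0: every 15 min for 2 h, every
# 30 min to 8 h, hourly to 24 h -> 37 readings.
DEFAULT_SCHEDULE = ((0.25, 2.0), (0.5, 8.0), (1.0, 24.0))


def measurement_grid(schedule=DEFAULT_SCHEDULE) -> np.ndarray:
    """Measurement times (hours) for a contiguous piecewise-regular schedule."""
    times = [0.0]
    prev_end = 0.0
    for step, end in schedule:
        if step <= 0 or end <= prev_end:
            raise ValueError("schedule segments must be contiguous with positive steps")
        n = round((end - prev_end) / step)
        if abs(prev_end + n * step - end) > 1e-9:
            raise ValueError("segment length must be a multiple of its step")
        times.extend(prev_end + step * np.arange(1, n + 1))
        prev_end = end
    out = np.round(np.asarray(times, dtype=float), 10)
    if np.any(np.diff(out) <= 0):
        raise ValueError("schedule produced non-increasing times")
    return out


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative logistic model for one binary outcome.

    Odds-ratio tables are keyed by 1-based group label relative to the
    reference group (OR 1).  ``prevalence`` is the marginal target rate the
    intercept is calibrated to.  ``glucose_or`` is a per-mmol/L odds ratio
    applied to mean-centred glucose (centring keeps the group-based intercept
    calibration accurate).
    """

    name: str
    prevalence: float
    sbp_or: dict | None = None
    dbp_or: dict | None = None
    glucose_or: float | None = None

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


def default_outcome_specs() -> dict:
    """Shipped outcome models: published crude (model 1) group odds ratios.

    Each outcome is driven by the channel whose published association it
    mirrors (END and mRS by SBP group, ENI by DBP group), so a crude refit on
    that channel's groups recovers the generating contrast directly.
    """
    return {
        "end_24h": OutcomeSpec(
            "end_24h", 0.190,
            sbp_or={1: 0.263, 2: 1.140, 3: 1.0, 4: 1.507, 5: 2.852},
        ),
        "eni_24h": OutcomeSpec(
            "eni_24h", 0.371,
            dbp_or={1: 0.693, 2: 1.0, 3: 0.446, 4: 0.443},
        ),
        "mrs_unfavorable": OutcomeSpec(
            "mrs_unfavorable", 0.314,
            sbp_or={1: 0.963, 2: 1.251, 3: 1.0, 4: 2.228, 5: 2.883},
        ),
    }


def _default_channel(channel):
    shapes, probs = group_table(channel)
    return {"shapes": shapes, "probs": probs}


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort (defaults = published cohort)."""

    n_patients: int = 353
    sbp: dict = field(default_factory=lambda: _default_channel("SBP"))
    dbp: dict = field(default_factory=lambda: _default_channel("DBP"))
    sigma_sbp: float = 8.0
    sigma_dbp: float = 6.0
    noise_model: str = "iid"  # "iid" or "ar1"
    rho: float = 0.6
    schedule: tuple = DEFAULT_SCHEDULE
    outcome_specs: dict = field(default_factory=default_outcome_specs)
    age_mean: float = 62.49
    age_sd: float = 11.79
    male_prob: float = 0.728
    glucose_mean: float = 6.78
    glucose_sd: float = 3.0
    mutually_exclusive_end_eni: bool = False
    # "exact": group counts are the largest-remainder rounding of n*pi and
    # labels are shuffled (reproduces the published cohort's group sizes);
    # "multinomial": i.i.d. membership draws.
    membership: str = "exact"

    def __post_init__(self):
        for spec in (self.sbp, self.dbp):
            probs = np.asarray(spec["probs"], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("group membership probabilities must sum to 1")
        if self.sigma_sbp <= 0 or self.sigma_dbp <= 0:
            raise ValueError("residual sigma must be positive")


@dataclass
class Cohort:
    """A simulated cohort: long BP table, covariates, outcomes, and the truth."""

    bp_long: pd.DataFrame | None
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig
    seed: int

    def series(self, channel):
        """The cohort's readings for one channel as a list of BPSeries."""
        from .io import series_from_frame

        if self.bp_long is None:
            raise ValueError("cohort was simulated without BP series")
        return series_from_frame(self.bp_long, channel=channel)


def sample_bp_series(shape: TrajectoryShape, grid, sigma, noise_model="iid",
                     rng=None, rho=0.6, patient_id="P0", channel="SBP") -> BPSeries:
    """One noisy series around a group trajectory.

    ``iid`` noise is Normal(0, sigma^2); ``ar1`` is a stationary AR(1) in
    measurement index with marginal SD sigma and lag-1 correlation rho.
    """
    rng = rng or np.random.default_rng()
    grid = np.asarray(grid, dtype=float)
    noise = _noise_matrix(1, len(grid), sigma, noise_model, rho, rng)[0]
    mu = shape(grid)
    return BPSeries(patient_id, channel, grid, mu + noise)


def _noise_matrix(n, m, sigma, noise_model, rho, rng):
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if noise_model == "iid":
        return rng.normal(0.0, sigma, size=(n, m))
    if noise_model == "ar1":
        e = np.empty((n, m))
        e[:, 0] = rng.normal(0.0, sigma, size=n)
        innov_sd = sigma * np.sqrt(1.0 - rho**2)
        for k in range(1, m):
            e[:, k] = rho * e[:, k - 1] + rng.normal(0.0, innov_sd, size=n)
        return e
    raise ValueError(f"unknown noise model {noise_model!r}")


def _solve_intercept(offsets, probs, target):
    """alpha with sum_i probs[i] * expit(alpha + offsets[i]) = target."""
    offsets = np.asarray(offsets, dtype=float)
    probs = np.asarray(probs, dtype=float)

    def f(a):
        return float(probs @ expit(a + offsets)) - target

    return brentq(f, -60.0, 60.0, xtol=1e-10)


def calibrate_intercept(or_table, group_probs, target) -> float:
    """Logistic intercept giving the target marginal rate under group effects.

    ``or_table`` maps 1-based group labels to odds ratios (the reference
    group's entry is 1, or may be omitted); ``group_probs`` are the
    membership probabilities in label order.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    probs = np.asarray(group_probs, dtype=float)
    offsets = np.log([or_table.get(j + 1, 1.0) for j in range(len(probs))])
    return _solve_intercept(offsets, probs, target)


def _spec_cells(spec: OutcomeSpec, sbp_probs, dbp_probs, glucose_sd):
    """Flatten a spec's effects into (log-odds offsets, probabilities) cells.

    SBP x DBP cells assume independent memberships; an active glucose effect
    is integrated out by Gauss-Hermite quadrature over its centred normal law.
    """
    offsets, probs = np.zeros(1), np.ones(1)
    for or_table, marg in ((spec.sbp_or, sbp_probs), (spec.dbp_or, dbp_probs)):
        if or_table is None:
            continue
        o = np.log([or_table.get(j + 1, 1.0) for j in range(len(marg))])
        offsets = (offsets[:, None] + o[None, :]).ravel()
        probs = (probs[:, None] * np.asarray(marg)[None, :]).ravel()
    if spec.glucose_or is not None:
        nodes, weights = roots_hermitenorm(32)
        g = np.log(spec.glucose_or) * glucose_sd * nodes
        w = weights / np.sqrt(2.0 * np.pi)
        offsets = (offsets[:, None] + g[None, :]).ravel()
        probs = (probs[:, None] * w[None, :]).ravel()
    return offsets, probs


def calibrated_intercepts(config: CohortConfig) -> dict:
    """Per-outcome intercepts hitting each spec's target marginal prevalence."""
    sbp_probs = np.asarray(config.sbp["probs"])
    dbp_probs = np.asarray(config.dbp["probs"])
    out = {}
    for name, spec in config.outcome_specs.items():
        offsets, probs = _spec_cells(spec, sbp_probs, dbp_probs, config.glucose_sd)
        out[name] = _solve_intercept(offsets, probs, spec.prevalence)
    return out


def _linear_predictor(spec, alpha, sbp_groups, dbp_groups, glucose_centered):
    lp = np.full(len(sbp_groups), alpha)
    if spec.sbp_or is not None:
        lo = np.log([spec.sbp_or.get(j, 1.0) for j in range(1, max(spec.sbp_or) + 1)])
        lp += lo[sbp_groups - 1]
    if spec.dbp_or is not None:
        lo = np.log([spec.dbp_or.get(j, 1.0) for j in range(1, max(spec.dbp_or) + 1)])
        lp += lo[dbp_groups - 1]
    if spec.glucose_or is not None:
        lp += np.log(spec.glucose_or) * glucose_centered
    return lp


def sample_outcomes(sbp_groups, dbp_groups, covariates: pd.DataFrame,
                    config: CohortConfig, rng) -> pd.DataFrame:
    """Draw the binary outcome table given group labels and covariates."""
    sbp_groups = np.asarray(sbp_groups, dtype=int)
    dbp_groups = np.asarray(dbp_groups, dtype=int)
    glucose_c = covariates["glucose"].to_numpy() - config.glucose_mean
    alphas = calibrated_intercepts(config)
    p = {
        name: expit(_linear_predictor(spec, alphas[name], sbp_groups, dbp_groups, glucose_c))
        for name, spec in config.outcome_specs.items()
    }
    out = {"patient_id": covariates["patient_id"].to_numpy()}
    if config.mutually_exclusive_end_eni and {"end_24h", "eni_24h"} <= p.keys():
        # joint categorical END / ENI / neither from the two marginal rates
        p_end, p_eni = p.pop("end_24h"), p.pop("eni_24h")
        total = p_end + p_eni
        scale = np.minimum(1.0, 1.0 / np.maximum(total, 1e-12))
        u = rng.uniform(size=len(sbp_groups))
        out["end_24h"] = (u < p_end * scale).astype(int)
        out["eni_24h"] = ((u >= p_end * scale) & (u < total * scale)).astype(int)
    for name, prob in p.items():
        out[name] = (rng.uniform(size=len(prob)) < prob).astype(int)
    cols = ["patient_id"] + list(config.outcome_specs)
    return pd.DataFrame(out)[cols]


def _sample_membership(probs, n, mode, rng):
    """1-based group labels for n patients with membership probabilities probs."""
    probs = np.asarray(probs, dtype=float)
    if mode == "multinomial":
        return rng.choice(len(probs), size=n, p=probs) + 1
    if mode != "exact":
        raise ValueError(f"unknown membership mode {mode!r}")
    base = np.floor(n * probs).astype(int)
    frac = n * probs - base
    short = n - base.sum()
    base[np.argsort(-frac, kind="stable")[:short]] += 1
    labels = np.repeat(np.arange(1, len(probs) + 1), base)
    rng.shuffle(labels)
    return labels


def _sample_covariates(config, patient_ids, rng):
    n = len(patient_ids)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = (rng.uniform(size=n) < config.male_prob).astype(int)  # 1 = male
    glucose = np.maximum(rng.normal(config.glucose_mean, config.glucose_sd, size=n), 2.0)
    onset_min = rng.integers(0, 24 * 60, size=n)
    onset = [f"{m // 60:02d}:{m % 60:02d}" for m in onset_min]
    return pd.DataFrame({
        "patient_id": patient_ids,
        "age": np.round(age, 2),
        "sex": sex,
        "glucose": np.round(glucose, 2),
        "onset_clock": onset,
    })


def _simulate_channel(config, channel, groups, grid, patient_ids, rng):
    spec = config.sbp if channel == "SBP" else config.dbp
    sigma = config.sigma_sbp if channel == "SBP" else config.sigma_dbp
    shapes = spec["shapes"]
    mu = np.stack([s(grid) for s in shapes])  # (J, m)
    values = mu[groups - 1] + _noise_matrix(len(groups), len(grid), sigma,
                                            config.noise_model, config.rho, rng)
    values = np.maximum(values, 1.0)  # BP readings are positive
    n, m = values.shape
    return pd.DataFrame({
        "patient_id": np.repeat(patient_ids, m),
        "channel": channel,
        "time_h": np.tile(grid, n),
        "value_mmhg": np.round(values.ravel(), 4),
    })


def simulate_cohort(config: CohortConfig | None = None, seed=0, with_series=True) -> Cohort:
    """Generate a full cohort; all randomness flows from one seeded generator.

    ``with_series=False`` skips the BP time series (group labels, covariates
    and outcomes only) — useful for large-n outcome studies.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = config.n_patients
    width = max(4, len(str(n)))
    patient_ids = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    sbp_groups = _sample_membership(config.sbp["probs"], n, config.membership, rng)
    dbp_groups = _sample_membership(config.dbp["probs"], n, config.membership, rng)
    covariates = _sample_covariates(config, patient_ids, rng)
    outcomes = sample_outcomes(sbp_groups, dbp_groups, covariates, config, rng)

    bp_long = None
    if with_series:
        grid = measurement_grid(config.schedule)
        bp_long = pd.concat(
            [
                _simulate_channel(config, "SBP", sbp_groups, grid, patient_ids, rng),
                _simulate_channel(config, "DBP", dbp_groups, grid, patient_ids, rng),
            ],
            ignore_index=True,
        )
    truth = pd.DataFrame({
        "patient_id": patient_ids,
        "sbp_group": sbp_groups,
        "dbp_group": dbp_groups,
    })
    return Cohort(bp_long=bp_long, covariates=covariates, outcomes=outcomes,
                  truth=truth, config=config, seed=seed)
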