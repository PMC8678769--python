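"""Group-based trajectory modelling (GBTM) for censored-normal BP series.

The model is a finite mixture of polynomial regressions: patient i's readings
y_it are, given latent group j, independent censored-normal draws around the
group's polynomial mean trajectory with common residual scale sigma, and the
prior group shares pi_j follow an intercept-only multinomial logit
(theta_1 = 0).  Estimation is by EM with multiple starts; model selection over
the number of groups uses BIC among candidates passing the adequacy screen
(every group holds >= 5% of patients by modal assignment, and the average
posterior probability of assignment exceeds 0.7 in every group).

Exposed both as module-level operations (likelihood pieces, E/M steps,
information criteria, adequacy) and as the statsmodels-style pair
``GroupTrajectoryModel`` / ``GroupTrajectoryResults``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.cluster import KMeans

from .series import BPSeries, CensoringBounds
from .trajectories import TrajectoryShape, evaluate_trajectory

__all__ = [
    "GBTMModel",
    "PosteriorMatrix",
    "AdequacyReport",
    "GroupTrajectoryModel",
    "GroupTrajectoryResults",
    "SelectionResult",
    "cnorm_obs_loglik",
    "patient_group_loglik",
    "mixture_loglik",
    "e_step",
    "m_step",
    "fit_gbtm",
    "information_criteria",
    "adequacy",
    "select_model",
    "EstimationError",
    "GBTMConvergenceError",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class EstimationError(RuntimeError):
    """Numerical failure inside the E-step (zero-likelihood patient row)."""


class GBTMConvergenceError(RuntimeError):
    """No EM start converged; carries the best partial fit if one exists."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class GBTMModel:
    """Fitted GBTM parameter set with fit statistics.

    Groups are labelled 1..J in ascending order of mean trajectory value over
    the observed time grid, matching the published group numbering.
    """

    n_groups: int
    shapes: tuple
    theta: np.ndarray
    pi: np.ndarray
    sigma: float
    bounds: CensoringBounds
    log_likelihood: float
    n_patients: int
    n_free_params: int
    aic: float
    bic: float

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        if len(self.shapes) != self.n_groups or len(self.pi) != self.n_groups:
            raise ValueError("inconsistent group dimensions")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("group shares must sum to 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class PosteriorMatrix:
    """Per-patient posterior group-membership probabilities and modal labels."""

    patient_ids: tuple
    probs: np.ndarray
    assignments: np.ndarray  # modal group labels, 1-based

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        object.__setattr__(self, "assignments", np.asarray(self.assignments, dtype=int))

    @property
    def n_groups(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class AdequacyReport:
    """Group-size and classification-quality screen for a fitted model."""

    group_shares: np.ndarray
    appa: np.ndarray
    passes_min_share: bool
    passes_appa: bool
    min_share: float = 0.05
    min_appa: float = 0.7

    @property
    def passes(self) -> bool:
        return self.passes_min_share and self.passes_appa


# ---------------------------------------------------------------------------
# stacked-data representation used by all vectorised routines


class _Stacked:
    """Long-form arrays for a list of series: obs -> (time, value, patient)."""

    def __init__(self, data):
        if not data:
            raise ValueError("empty data")
        channels = {s.channel for s in data}
        if len(channels) != 1:
            raise ValueError(f"all series must share one channel, got {sorted(channels)}")
        self.channel = channels.pop()
        self.patient_ids = tuple(s.patient_id for s in data)
        self.n = len(data)
        self.t = np.concatenate([s.times for s in data])
        self.y = np.concatenate([s.values for s in data])
        counts = np.array([len(s) for s in data])
        if np.any(counts == 0):
            raise ValueError("empty series in data")
        self.idx = np.repeat(np.arange(self.n), counts)
        self.n_obs = len(self.t)
        self._vander = {}

    def design(self, order: int) -> np.ndarray:
        if order not in self._vander:
            self._vander[order] = np.vander(self.t, order + 1, increasing=True)
        return self._vander[order]


def _polyval(coefs, t):
    out = np.zeros_like(t, dtype=float)
    for c in reversed(coefs):
        out = out * t + c
    return out


def _cnorm_logpdf_vec(y, mu, sigma, bounds: CensoringBounds):
    z = (y - mu) / sigma
    if not bounds.active:
        return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI
    ll = -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI
    lo = y <= bounds.lower
    hi = y >= bounds.upper
    if np.any(lo):
        ll = np.where(lo, norm.logcdf((bounds.lower - mu) / sigma), ll)
    if np.any(hi):
        ll = np.where(hi, norm.logsf((bounds.upper - mu) / sigma), ll)
    return ll


def _group_logliks(st: _Stacked, shapes, sigma, bounds) -> np.ndarray:
    """(n_patients, J) matrix of per-patient per-group log-likelihoods."""
    J = len(shapes)
    L = np.empty((st.n, J))
    for j, shape in enumerate(shapes):
        mu = _polyval(shape.coefficients, st.t)
        ll = _cnorm_logpdf_vec(st.y, mu, sigma, bounds)
        L[:, j] = np.bincount(st.idx, weights=ll, minlength=st.n)
    return L


# ---------------------------------------------------------------------------
# spec-level operations


def cnorm_obs_loglik(y, mu, sigma, bounds: CensoringBounds | None = None):
    """Log-density of one censored-normal reading.

    Interior readings get the normal log-density; readings at/below the lower
    bound get log Phi((lower-mu)/sigma), at/above the upper bound
    log(1 - Phi((upper-mu)/sigma)).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    bounds = bounds or CensoringBounds()
    out = _cnorm_logpdf_vec(np.asarray(y, dtype=float), np.asarray(mu, dtype=float), sigma, bounds)
    return float(out) if np.ndim(out) == 0 else out


def patient_group_loglik(series: BPSeries, shape: TrajectoryShape, sigma, bounds=None):
    """Log-likelihood of one patient's series under one group's trajectory."""
    if len(series) == 0:
        raise ValueError("empty series")
    mu = evaluate_trajectory(shape, series.times)
    return float(np.sum(cnorm_obs_loglik(series.values, mu, sigma, bounds)))


def mixture_loglik(data, model: GBTMModel) -> float:
    """Observed-data log-likelihood of the mixture (stable log-sum-exp)."""
    st = data if isinstance(data, _Stacked) else _Stacked(data)
    L = _group_logliks(st, model.shapes, model.sigma, model.bounds)
    return float(np.sum(logsumexp(np.log(model.pi) + L, axis=1)))


def e_step(data, model: GBTMModel) -> PosteriorMatrix:
    """Posterior group-membership probabilities and modal assignments."""
    st = data if isinstance(data, _Stacked) else _Stacked(data)
    L = _group_logliks(st, model.shapes, model.sigma, model.bounds)
    W, _ = _posterior_from_logliks(L, model.pi)
    return _posterior_matrix(st, W)


def _posterior_from_logliks(L, pi):
    with np.errstate(divide="ignore"):
        logw = np.log(pi)[None, :] + L
    lse = logsumexp(logw, axis=1)
    if not np.all(np.isfinite(lse)):
        raise EstimationError("zero mixture likelihood for at least one patient")
    W = np.exp(logw - lse[:, None])
    return W, float(lse.sum())


def _posterior_matrix(st, W):
    # argmax returns the first maximal index: ties break to the lowest label
    return PosteriorMatrix(st.patient_ids, W, np.argmax(W, axis=1) + 1)


def m_step(data, posterior, orders, bounds=None, sigma_min=0.5, shared_sigma=True):
    """Maximise the expected complete-data log-likelihood.

    With inactive censoring the update is closed-form: posterior-weighted
    polynomial least squares per group, pooled weighted RMS residual for
    sigma, and theta back-solved from the mean posterior columns.  With
    active bounds the closed forms seed a short numerical maximiser.
    """
    st = data if isinstance(data, _Stacked) else _Stacked(data)
    W = posterior.probs if isinstance(posterior, PosteriorMatrix) else np.asarray(posterior)
    bounds = bounds or CensoringBounds()
    betas, sigma = _wls_update(st, W, orders, sigma_min, shared_sigma)
    if bounds.active:
        betas, sigma = _censored_refine(st, W, orders, bounds, betas, sigma, sigma_min)
    pi = W.mean(axis=0)
    theta = np.log(np.maximum(pi, 1e-300) / max(pi[0], 1e-300))
    shapes = tuple(TrajectoryShape(tuple(b)) for b in betas)
    return shapes, float(sigma), theta


def _wls_update(st, W, orders, sigma_min, shared_sigma):
    betas = []
    sse = 0.0
    for j, order in enumerate(orders):
        X = st.design(order)
        w = W[st.idx, j]
        sw = np.sqrt(w)
        beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], st.y * sw, rcond=None)
        if rank < order + 1:
            raise np.linalg.LinAlgError(
                f"singular design for group {j + 1}: need {order + 1} distinct times"
            )
        resid = st.y - X @ beta
        sse += float(np.sum(w * resid * resid))
        betas.append(beta)
    sigma = max(float(np.sqrt(sse / st.n_obs)), sigma_min)
    return betas, sigma


def _censored_refine(st, W, orders, bounds, betas0, sigma0, sigma_min):
    """Short numerical ascent on the expected complete-data log-likelihood."""
    sizes = [o + 1 for o in orders]
    splits = np.cumsum(sizes)[:-1]

    def unpack(x):
        bs = np.split(x[:-1], splits)
        return bs, max(np.exp(x[-1]), sigma_min)

    def neg_q(x):
        bs, sigma = unpack(x)
        total = 0.0
        for j, (order, b) in enumerate(zip(orders, bs)):
            mu = st.design(order) @ b
            ll = _cnorm_logpdf_vec(st.y, mu, sigma, bounds)
            total += float(np.sum(W[st.idx, j] * ll))
        return -total

    x0 = np.concatenate([np.concatenate(betas0), [np.log(sigma0)]])
    res = optimize.minimize(neg_q, x0, method="L-BFGS-B", options={"maxiter": 50})
    bs, sigma = unpack(res.x)
    return list(bs), sigma


def _wls_coef_se(st, W, orders, sigma):
    """Approximate SEs of polynomial coefficients from the weighted LS step."""
    ses = []
    for j, order in enumerate(orders):
        X = st.design(order)
        w = W[st.idx, j]
        XtWX = X.T @ (X * w[:, None])
        cov = sigma**2 * np.linalg.pinv(XtWX)
        ses.append(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    return ses


def information_criteria(log_likelihood, k, n):
    """(AIC, BIC) in the positive convention: smaller is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    aic = 2.0 * k - 2.0 * log_likelihood
    bic = k * np.log(n) - 2.0 * log_likelihood
    return float(aic), float(bic)


def adequacy(model: GBTMModel, posterior: PosteriorMatrix,
             min_share=0.05, min_appa=0.7) -> AdequacyReport:
    """Minimum-group-share and APPA screen (share >= 5%, APPA > 0.7)."""
    J = model.n_groups
    labels = posterior.assignments
    n = len(labels)
    shares = np.array([(labels == j + 1).sum() / n for j in range(J)])
    appa = np.zeros(J)
    for j in range(J):
        members = labels == j + 1
        appa[j] = posterior.probs[members, j].mean() if members.any() else 0.0
    return AdequacyReport(
        group_shares=shares,
        appa=appa,
        passes_min_share=bool(np.all(shares >= min_share)),
        passes_appa=bool(np.all(appa > min_appa)),
        min_share=min_share,
        min_appa=min_appa,
    )


# ---------------------------------------------------------------------------
# EM driver


def _em_run(st, W0, orders, bounds, sigma_min, shared_sigma, max_iter, tol):
    """One EM run from an initial posterior.  Returns a dict of results."""
    shapes, sigma, theta = m_step(st, W0, orders, bounds, sigma_min, shared_sigma)
    pi = W0.mean(axis=0)
    history = []
    prev = -np.inf
    converged = False
    W = W0
    for _ in range(max_iter):
        L = _group_logliks(st, shapes, sigma, bounds)
        W, llf = _posterior_from_logliks(L, pi)
        history.append(llf)
        if np.isfinite(prev) and abs(llf - prev) <= tol * (1.0 + abs(prev)):
            converged = True
            break
        prev = llf
        pi = W.mean(axis=0)
        if pi.min() * st.n < 1.0:
            return {"collapsed": True, "llf": llf}
        shapes, sigma, theta = m_step(st, W, orders, bounds, sigma_min, shared_sigma)
    return {
        "collapsed": False,
        "shapes": shapes,
        "sigma": sigma,
        "theta": theta,
        "pi": pi,
        "W": W,
        "llf": history[-1],
        "history": history,
        "converged": converged,
    }


def _hard_posterior(labels, n, J):
    W = np.full((n, J), 1e-3)
    W[np.arange(n), labels] = 1.0
    return W / W.sum(axis=1, keepdims=True)


def _quantile_labels(score, J):
    """Cut patients into J contiguous blocks by ascending score."""
    n = len(score)
    labels = np.empty(n, dtype=int)
    labels[np.argsort(score, kind="stable")] = (np.arange(n) * J) // n
    return labels


def _init_posteriors(st, J, n_starts, seed):
    """Initial posteriors: quantile cut on patient mean level, k-means on
    (mean, slope) summary features, then jittered quantile cuts."""
    rng = np.random.default_rng(seed)
    if J == 1:
        return [np.ones((st.n, 1))]
    # per-patient summary features: mean level and OLS slope
    sum_t = np.bincount(st.idx, weights=st.t, minlength=st.n)
    sum_y = np.bincount(st.idx, weights=st.y, minlength=st.n)
    cnt = np.bincount(st.idx, minlength=st.n)
    mean_t, mean_y = sum_t / cnt, sum_y / cnt
    cov_ty = np.bincount(st.idx, weights=(st.t - mean_t[st.idx]) * (st.y - mean_y[st.idx]),
                         minlength=st.n)
    var_t = np.bincount(st.idx, weights=(st.t - mean_t[st.idx]) ** 2, minlength=st.n)
    slope = np.divide(cov_ty, var_t, out=np.zeros(st.n), where=var_t > 0)
    feats = np.column_stack([mean_y, slope])
    std = feats.std(axis=0)
    std[std == 0] = 1.0

    # k-means on mean level alone (the dominant separating feature), then on
    # (mean, slope), then a quantile cut, then jittered quantile cuts
    inits = []
    km1 = KMeans(n_clusters=J, n_init=10, random_state=int(rng.integers(2**31 - 1)))
    inits.append(_hard_posterior(km1.fit_predict(mean_y[:, None]), st.n, J))
    if n_starts > 1:
        km2 = KMeans(n_clusters=J, n_init=10, random_state=int(rng.integers(2**31 - 1)))
        inits.append(_hard_posterior(km2.fit_predict(feats / std), st.n, J))
    if n_starts > 2:
        inits.append(_hard_posterior(_quantile_labels(mean_y, J), st.n, J))
    jitter = max(mean_y.std(), 1e-12)
    for _ in range(n_starts - 3):
        noisy = mean_y + rng.normal(0.0, 0.5 * jitter, size=st.n)
        inits.append(_hard_posterior(_quantile_labels(noisy, J), st.n, J))
    return inits


def _relabel_ascending(st, shapes, pi, W, theta):
    """Permute groups so labels ascend with mean trajectory over the grid."""
    grid = np.unique(st.t)
    means = [float(np.mean(_polyval(s.coefficients, grid))) for s in shapes]
    order = np.argsort(means, kind="stable")
    shapes = tuple(shapes[k] for k in order)
    pi = pi[order]
    W = W[:, order]
    theta = np.log(np.maximum(pi, 1e-300) / max(pi[0], 1e-300))
    return shapes, pi, W, theta


def _n_free_params(orders, J, shared_sigma=True):
    return sum(o + 1 for o in orders) + (J - 1) + (1 if shared_sigma else J)


def fit_gbtm(data, n_groups, orders=4, *, bounds=None, sigma_min=0.5, shared_sigma=True,
             n_starts=10, max_iter=500, tol=1e-8, seed=0, bic_n="patients",
             return_details=False):
    """Fit a J-group trajectory model by multi-start EM.

    Returns ``(GBTMModel, PosteriorMatrix)``.  ``orders`` may be a single
    degree applied to every group or a per-group list.  The best converged
    start by log-likelihood is kept and groups are relabelled in ascending
    order of mean trajectory.
    """
    st = data if isinstance(data, _Stacked) else _Stacked(data)
    J = int(n_groups)
    if J < 1:
        raise ValueError("n_groups must be >= 1")
    orders = [int(orders)] * J if np.isscalar(orders) else [int(o) for o in orders]
    if len(orders) != J:
        raise ValueError("orders length must equal n_groups")
    bounds = bounds or CensoringBounds()

    best = None       # best converged run
    best_any = None   # best run regardless of convergence (partial on failure)
    for W0 in _init_posteriors(st, J, n_starts, seed):
        run = _em_run(st, W0, orders, bounds, sigma_min, shared_sigma, max_iter, tol)
        if run["collapsed"]:
            warnings.warn("degenerate group (posterior mass < 1 patient); start discarded")
            continue
        if best_any is None or run["llf"] > best_any["llf"] + 1e-9:
            best_any = run
        if run["converged"] and (best is None or run["llf"] > best["llf"] + 1e-9):
            best = run
    if best is None:
        if best_any is None:
            raise GBTMConvergenceError("all EM starts collapsed", partial=None)
        raise GBTMConvergenceError("no EM start converged", partial=best_any)

    shapes, pi, W, theta = _relabel_ascending(st, best["shapes"], best["pi"], best["W"],
                                              best["theta"])
    # orders follow their group through relabelling
    order_perm = [s.order for s in shapes]
    k = _n_free_params(order_perm, J, shared_sigma)
    n_ic = st.n if bic_n == "patients" else st.n_obs
    aic, bic = information_criteria(best["llf"], k, n_ic)
    model = GBTMModel(
        n_groups=J, shapes=shapes, theta=theta, pi=pi, sigma=best["sigma"], bounds=bounds,
        log_likelihood=best["llf"], n_patients=st.n, n_free_params=k, aic=aic, bic=bic,
    )
    posterior = _posterior_matrix(st, W)
    if return_details:
        details = {"loglik_history": list(best["history"]),
                   "n_iter": len(best["history"])}
        return model, posterior, details
    return model, posterior


# ---------------------------------------------------------------------------
# statsmodels-style surface


class GroupTrajectoryModel:
    """Latent-group polynomial trajectory model for one BP channel.

    Parameters
    ----------
    data : list of BPSeries
        One series per patient, all the same channel.
    n_groups : int
        Number of latent trajectory groups J.
    orders : int or sequence of int, default 4
        Polynomial degree per group (quartic default; the published shapes
        are cubic or quartic).
    bounds : CensoringBounds, optional
        Censoring bounds for the outcome distribution; inactive by default.
    """

    def __init__(self, data, n_groups, orders=4, bounds=None, sigma_min=0.5,
                 shared_sigma=True, bic_n="patients"):
        self._st = data if isinstance(data, _Stacked) else _Stacked(data)
        self.data = data
        self.n_groups = int(n_groups)
        self.orders = orders
        self.bounds = bounds or CensoringBounds()
        self.sigma_min = sigma_min
        self.shared_sigma = shared_sigma
        self.bic_n = bic_n
        max_order = int(np.max(orders)) if not np.isscalar(orders) else int(orders)
        counts = np.bincount(self._st.idx, minlength=self._st.n)
        if counts.min() < max_order + 1:
            raise ValueError("every patient needs at least order+1 observations")

    @classmethod
    def from_dataframe(cls, df, channel, n_groups, **kwargs):
        """Build from a long-format frame (patient_id, channel, time_h, value_mmhg)."""
        from .io import series_from_frame

        return cls(series_from_frame(df, channel=channel), n_groups, **kwargs)

    @property
    def channel(self) -> str:
        return self._st.channel

    def loglike(self, params: GBTMModel) -> float:
        return mixture_loglik(self._st, params)

    def fit(self, n_starts=10, max_iter=500, tol=1e-8, seed=0):
        params, posterior, details = fit_gbtm(
            self._st, self.n_groups, self.orders, bounds=self.bounds,
            sigma_min=self.sigma_min, shared_sigma=self.shared_sigma,
            n_starts=n_starts, max_iter=max_iter, tol=tol, seed=seed, bic_n=self.bic_n,
            return_details=True,
        )
        return GroupTrajectoryResults(self, params, posterior, details)


class GroupTrajectoryResults:
    """Fitted trajectory model: parameters, posterior classification, diagnostics."""

    def __init__(self, model: GroupTrajectoryModel, params: GBTMModel,
                 posterior: PosteriorMatrix, details: dict | None = None):
        self.model = model
        self.params = params
        self.posterior = posterior
        details = details or {}
        #: observed-data log-likelihood at each EM iteration of the best start
        self.loglik_history = details.get("loglik_history", [])
        self.n_iter = details.get("n_iter", None)

    # -- convenience accessors -------------------------------------------
    @property
    def shapes(self):
        return self.params.shapes

    @property
    def pi(self):
        return self.params.pi

    @property
    def sigma(self):
        return self.params.sigma

    @property
    def llf(self):
        return self.params.log_likelihood

    @property
    def aic(self):
        return self.params.aic

    @property
    def bic(self):
        return self.params.bic

    @property
    def assignments(self):
        return self.posterior.assignments

    def adequacy(self, min_share=0.05, min_appa=0.7) -> AdequacyReport:
        return adequacy(self.params, self.posterior, min_share, min_appa)

    def predict(self, t, group=None):
        """Group mean trajectory at times ``t`` (one group, or all as a matrix)."""
        if group is not None:
            return evaluate_trajectory(self.shapes[group - 1], t)
        return np.column_stack([evaluate_trajectory(s, t) for s in self.shapes])

    def coefficients_frame(self) -> pd.DataFrame:
        """Per-group polynomial coefficients, intercept first (published layout)."""
        rows = []
        for j, s in enumerate(self.shapes, start=1):
            row = {"group": j, "share": self.pi[j - 1]}
            for m, c in enumerate(s.coefficients):
                row[f"b{m}"] = c
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        rep = self.adequacy()
        return {
            "channel": self.model.channel,
            "n_groups": self.params.n_groups,
            "coefficients": [list(s.coefficients) for s in self.shapes],
            "pi": [round(float(p), 6) for p in self.pi],
            "sigma": round(float(self.sigma), 6),
            "log_likelihood": round(float(self.llf), 6),
            "n_free_params": self.params.n_free_params,
            "aic": round(float(self.aic), 6),
            "bic": round(float(self.bic), 6),
            "adequacy": {
                "group_shares": [round(float(x), 6) for x in rep.group_shares],
                "appa": [round(float(x), 6) for x in rep.appa],
                "passes": rep.passes,
            },
        }

    def summary(self) -> str:
        rep = self.adequacy()
        lines = [
            f"Group-based trajectory model ({self.model.channel}), "
            f"J={self.params.n_groups}, n={self.params.n_patients}",
            f"logL={self.llf:.3f}  k={self.params.n_free_params}  "
            f"AIC={self.aic:.3f}  BIC={self.bic:.3f}  sigma={self.sigma:.3f} mmHg",
            f"adequacy: min share {rep.group_shares.min():.3f} "
            f"(>= {rep.min_share}), min APPA {rep.appa.min():.3f} (> {rep.min_appa}) "
            f"-> {'PASS' if rep.passes else 'FAIL'}",
            "",
            f"{'group':>5} {'share':>7} {'APPA':>6}  coefficients (intercept first)",
        ]
        for j, s in enumerate(self.shapes, start=1):
            coefs = ", ".join(f"{c:.4g}" for c in s.coefficients)
            lines.append(
                f"{j:>5} {self.pi[j - 1]:>7.3f} {rep.appa[j - 1]:>6.3f}  [{coefs}]"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model selection over the number of groups


@dataclass
class SelectionResult:
    """Candidate fits over a range of group counts plus the BIC choice."""

    results: dict
    chosen: int
    trace: pd.DataFrame
    adequate: bool

    @property
    def result(self) -> GroupTrajectoryResults:
        return self.results[self.chosen]


def _prune_orders(st, res: GroupTrajectoryResults, config, z_crit=1.96):
    """Backward-drop each group's top polynomial term while its Wald |z| < z_crit."""
    current = res
    while True:
        # realign with the (relabelled) groups of the latest fit
        orders = [s.order for s in current.shapes]
        ses = _wls_coef_se(st, current.posterior.probs, orders, current.sigma)
        worst, worst_z = None, z_crit
        for j, (s, se) in enumerate(zip(current.shapes, ses)):
            if s.order == 0:
                continue
            z = abs(s.coefficients[-1]) / se[-1] if se[-1] > 0 else np.inf
            if z < worst_z:
                worst, worst_z = j, z
        if worst is None:
            return current
        orders[worst] -= 1
        model = GroupTrajectoryModel(
            st, current.params.n_groups, orders, bounds=current.params.bounds,
        )
        current = model.fit(**config)


def select_model(data, j_range=range(2, 7), orders=4, order_policy="full-quartic", *,
                 min_share=0.05, min_appa=0.7, bounds=None, sigma_min=0.5,
                 n_starts=10, max_iter=500, tol=1e-8, seed=0, bic_n="patients"):
    """Fit each candidate group count and choose by BIC among adequate fits.

    ``order_policy`` is ``"full-quartic"`` (every group keeps the full
    ``orders`` degree) or ``"prune"`` (after each fit, backward-drop each
    group's highest-degree term while its Wald |z| < 1.96 and refit).
    Returns a :class:`SelectionResult` whose trace records every candidate's
    log-likelihood, AIC, BIC and adequacy.  If no candidate passes adequacy
    the best-BIC fit is returned flagged inadequate.
    """
    st = data if isinstance(data, _Stacked) else _Stacked(data)
    j_range = list(j_range)
    if not j_range:
        raise ValueError("empty j_range")
    fit_kw = dict(n_starts=n_starts, max_iter=max_iter, tol=tol, seed=seed)
    results, rows = {}, []
    for J in j_range:
        model = GroupTrajectoryModel(st, J, orders, bounds=bounds, sigma_min=sigma_min,
                                     bic_n=bic_n)
        res = model.fit(**fit_kw)
        if order_policy == "prune":
            res = _prune_orders(st, res, fit_kw)
        elif order_policy != "full-quartic":
            raise ValueError(f"unknown order_policy {order_policy!r}")
        rep = res.adequacy(min_share, min_appa)
        results[J] = res
        rows.append({
            "n_groups": J,
            "orders": "/".join(str(s.order) for s in res.shapes),
            "log_likelihood": res.llf,
            "k": res.params.n_free_params,
            "aic": res.aic,
            "bic": res.bic,
            "min_share": float(rep.group_shares.min()),
            "min_appa": float(rep.appa.min()),
            "adequate": rep.passes,
        })
    trace = pd.DataFrame(rows)
    adequate_rows = trace[trace["adequate"]]
    pool = adequate_rows if len(adequate_rows) else trace
    chosen = int(pool.loc[pool["bic"].idxmin(), "n_groups"])
    return SelectionResult(results=results, chosen=chosen, trace=trace,
                           adequate=bool(len(adequate_rows)))
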