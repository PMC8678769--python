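"""Logistic-regression associations of BP exposures with binary stroke outcomes.

Implements the nested modelling strategy used for the trajectory-group and
BP-parameter analyses: model 1 is crude, model 2 adds demographics (age, sex),
model 3 adds every remaining covariate passing a univariate screen at p < .1.
Effects are reported as odds ratios with Wald 95% CIs; discrimination per
predictor as the ROC AUC with a Hanley-McNeil confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "ROCResult",
    "fit_logistic",
    "odds_ratio_ci",
    "covariate_screen",
    "trajectory_association",
    "roc_auc",
]

Z975 = norm.ppf(0.975)  # 1.959964
_SEPARATION_COEF = 15.0  # |logit coef| beyond this flags quasi-separation


@dataclass(frozen=True)
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    converged: bool
    llf: float
    names: tuple

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass(frozen=True)
class AssociationResult:
    exposure: str
    model_id: int
    or_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool


@dataclass(frozen=True)
class ROCResult:
    predictor: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float


def fit_logistic(y, X, max_iter=100, tol=1e-8) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS, observed-information cov).

    Quasi-separation (any |coefficient| > 15 on the logit scale) or
    non-convergence is flagged via ``converged=False`` rather than silently
    returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
        except Exception:
            res = model.fit(method="bfgs", maxiter=5 * max_iter, disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    if np.max(np.abs(res.params)) > _SEPARATION_COEF:
        converged = False
    names = tuple(X.columns) if hasattr(X, "columns") else tuple(
        f"x{i}" for i in range(X.shape[1]))
    return LogisticFit(np.asarray(res.params), np.asarray(res.cov_params()),
                       converged, float(res.llf), names)


def odds_ratio_ci(coef, se, level=0.95):
    """(OR, low, high) from a log-odds coefficient and its standard error."""
    if se < 0:
        raise ValueError("se must be non-negative")
    z = norm.ppf(0.5 + level / 2.0)
    return (float(np.exp(coef)), float(np.exp(coef - z * se)),
            float(np.exp(coef + z * se)))


def _wald_p(coef, se):
    if se == 0:
        return 0.0 if coef != 0 else 1.0
    return float(2.0 * norm.sf(abs(coef) / se))


def covariate_screen(covariates: pd.DataFrame, outcome, threshold=0.1) -> list:
    """Univariate-logistic screen: keep covariates with Wald p < threshold.

    Categorical (object / category / boolean) columns are dummy-coded and
    screened with a likelihood-ratio test for the whole block.  Constant
    columns are excluded with a warning.  Column order is preserved.
    """
    y = np.asarray(outcome, dtype=float)
    selected = []
    for col in covariates.columns:
        x = covariates[col]
        if x.nunique(dropna=False) <= 1:
            warnings.warn(f"covariate {col!r} is constant; excluded from screening")
            continue
        if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype) or x.dtype == bool:
            design = pd.get_dummies(x, drop_first=True, dtype=float)
        else:
            design = x.to_frame().astype(float)
        X = sm.add_constant(design.to_numpy(), has_constant="add")
        fit_full = fit_logistic(y, X)
        if design.shape[1] == 1:
            p = _wald_p(fit_full.params[1], fit_full.se()[1])
        else:  # LR test for a multi-level block
            fit_null = fit_logistic(y, np.ones((len(y), 1)))
            from scipy.stats import chi2
            lr = 2.0 * (fit_full.llf - fit_null.llf)
            p = float(chi2.sf(max(lr, 0.0), design.shape[1]))
        if p < threshold:
            selected.append(col)
    return selected


def _dummy_design(groups, reference):
    """Dummy-code group labels vs the reference level; columns in label order."""
    groups = pd.Series(groups).reset_index(drop=True)
    levels = sorted(groups.unique())
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from groups")
    cols = {}
    for lev in levels:
        if lev == reference:
            continue
        cols[f"group_{lev}"] = (groups == lev).astype(float)
    return pd.DataFrame(cols)


def trajectory_association(groups, outcome, covariates=None, reference=3,
                           models=(1, 2, 3), demographics=("age", "sex"),
                           screen_threshold=0.1) -> pd.DataFrame:
    """Group-vs-reference odds ratios for one outcome under nested models.

    Model 1 is unadjusted; model 2 adds the demographic covariates; model 3
    adds all remaining covariates passing :func:`covariate_screen`.  Returns
    one row per non-reference group per model (OR, 95% CI, Wald p,
    convergence flag).  Empty group levels after listwise deletion are
    dropped with a warning.
    """
    y = pd.Series(np.asarray(outcome, dtype=float)).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    dummies = _dummy_design(groups, reference)
    empty = [c for c in dummies.columns if dummies[c].sum() == 0]
    if empty:
        warnings.warn(f"empty group level(s) dropped: {empty}")
        dummies = dummies.drop(columns=empty)

    adjust_sets = {1: []}
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        demo = [c for c in demographics if c in cov.columns]
        adjust_sets[2] = demo
        others = cov.drop(columns=demo, errors="ignore")
        others = others.select_dtypes(exclude=["object"]) if len(others.columns) else others
        screened = covariate_screen(others, y, screen_threshold) if len(others.columns) else []
        adjust_sets[3] = demo + screened
    else:
        adjust_sets[2] = adjust_sets[3] = []

    rows = []
    for model_id in models:
        parts = [dummies]
        if adjust_sets[model_id]:
            parts.append(cov[adjust_sets[model_id]].astype(float))
        design = pd.concat(parts, axis=1)
        X = sm.add_constant(design.to_numpy(), has_constant="add")
        fit = fit_logistic(y.to_numpy(), X)
        ses = fit.se()
        for k, name in enumerate(dummies.columns, start=1):
            or_hat, lo, hi = odds_ratio_ci(fit.params[k], ses[k])
            rows.append(AssociationResult(
                exposure=name, model_id=model_id, or_hat=or_hat, ci_low=lo,
                ci_high=hi, p_value=_wald_p(fit.params[k], ses[k]),
                converged=fit.converged,
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def parameter_association(values, outcome, name, covariates=None,
                          models=(1,), demographics=("age", "sex"),
                          per_sd=False) -> pd.DataFrame:
    """Odds ratio for a continuous BP parameter (per mmHg, or per SD)."""
    x = np.asarray(values, dtype=float)
    if per_sd:
        x = x / np.std(x, ddof=1)
    y = np.asarray(outcome, dtype=float)
    rows = []
    for model_id in models:
        parts = [pd.Series(x, name=name)]
        if model_id >= 2 and covariates is not None:
            parts.append(covariates[list(demographics)].reset_index(drop=True).astype(float))
        design = pd.concat(parts, axis=1)
        X = sm.add_constant(design.to_numpy(), has_constant="add")
        fit = fit_logistic(y, X)
        or_hat, lo, hi = odds_ratio_ci(fit.params[1], fit.se()[1])
        rows.append(AssociationResult(name, model_id, or_hat, lo, hi,
                                      _wald_p(fit.params[1], fit.se()[1]), fit.converged))
    return pd.DataFrame([r.__dict__ for r in rows])


def roc_auc(scores, labels, predictor="score") -> ROCResult:
    """ROC AUC by the Mann-Whitney rank statistic (ties count 1/2).

    The confidence interval uses the Hanley-McNeil normal approximation;
    the p-value tests AUC = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes are required for an AUC")
    ranks = rankdata(scores)  # midranks: ties contribute 1/2
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, auc - Z975 * se)
    hi = min(1.0, auc + Z975 * se)
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = float(2.0 * norm.sf(abs(auc - 0.5) / se))
    return ROCResult(predictor, float(auc), lo, hi, p)
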