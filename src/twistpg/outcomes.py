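"""Outcome adapters: one collapsible difference scale per outcome type.

Every estimator recipe is a regression of the outcome on a small set of
derived regressors plus the measured covariates.  To keep the five estimates
combinable, each outcome type is mapped onto a *collapsible* difference
scale:

- continuous outcomes: mean differences from ordinary least squares;
- binary outcomes: risk differences, either as the average marginal effect
  (AME) of a logistic fit (delta-method SE) or from a linear probability
  model;
- time-to-event outcomes: additive hazard differences per year from a
  semiparametric additive hazards model with time-constant coefficients
  (Lin–Ying estimating equations, sandwich SEs).  The baseline hazard is
  profiled out, so no intercept is fitted.

Non-collapsible scales (odds ratios, hazard ratios) are deliberately not
offered: estimates on those scales drift when marginalised over independent
covariates and cannot be pooled across estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import PGDataset
from .errors import SeparationError, SingularDesignError, ValidationError

SCALES = {"continuous": "mean_difference", "binary": "risk_difference", "survival": "hazard_difference"}


@dataclass
class FitResult:
    """Coefficient of the target regressor on the outcome's difference scale."""

    beta: float
    se: float
    n: int
    scale: str


@dataclass
class SurvivalFit:
    """Constant hazard-difference coefficients (events per person-year) for all regressors."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    n: int
    n_events: int

    def coefficient(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def percent(self) -> "SurvivalFit":
        """Display transform to the percent-per-year scale (SEs scale identically)."""
        return SurvivalFit(self.names, self.beta * 100.0, self.se * 100.0, self.n, self.n_events)


def _design(data: PGDataset, regressors: Sequence[str], covariates: Sequence[str]) -> pd.DataFrame:
    cols = list(dict.fromkeys(list(regressors) + list(covariates)))
    X = data.df[cols].astype(float)
    # drop constant columns (e.g. T in a treated-only dataset); the intercept absorbs them
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def continuous_fit(
    data: PGDataset,
    target: str,
    regressors: Sequence[str],
    covariates: Sequence[str],
    robust: bool = False,
) -> FitResult:
    """OLS coefficient of ``target`` with intercept, extra regressors and covariates."""
    y = data.df["Y"].to_numpy(dtype=float)
    X = _design(data, [target] + list(regressors), covariates)
    if target not in X.columns:
        raise SingularDesignError(f"target regressor {target!r} has no variation")
    X = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, X).fit(cov_type="HC3" if robust else "nonrobust")
    return FitResult(
        beta=float(res.params[target]),
        se=float(res.bse[target]),
        n=int(res.nobs),
        scale=SCALES["continuous"],
    )


def risk_difference_fit(
    data: PGDataset,
    target: str,
    regressors: Sequence[str],
    covariates: Sequence[str],
    method: str = "ame",
    robust: bool = False,
) -> FitResult:
    """Risk difference for ``target``: logistic AME (default) or linear probability.

    The AME of a binary regressor is the mean, over all rows, of the fitted
    probability contrast between the regressor's two levels; its SE comes from
    the delta method.  With no covariates and a single binary regressor the
    logistic model is saturated and the AME equals the raw proportion
    difference.  Separated fits raise :class:`SeparationError` advising the
    linear-probability fallback (``method="lpm"``).
    """
    if method == "lpm":
        y = data.df["Y"].to_numpy(dtype=float)
        X = _design(data, [target] + list(regressors), covariates)
        if target not in X.columns:
            raise SingularDesignError(f"target regressor {target!r} has no variation")
        X = sm.add_constant(X, has_constant="add")
        res = sm.OLS(y, X).fit(cov_type="HC3" if robust else "nonrobust")
        return FitResult(float(res.params[target]), float(res.bse[target]), int(res.nobs),
                         SCALES["binary"])
    if method != "ame":
        raise ValidationError(f"unknown binary method {method!r}", code="unknown_method")

    y = data.df["Y"].to_numpy(dtype=float)
    X = _design(data, [target] + list(regressors), covariates)
    if target not in X.columns:
        raise SingularDesignError(f"target regressor {target!r} has no variation")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
            raise SeparationError(
                f"logistic fit failed ({exc}); consider method='lpm'"
            ) from exc
    fitted = res.predict(Xc)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        raise SeparationError(
            "fitted probabilities pinned at 0/1 (separation); use method='lpm'"
        )
    eff = res.get_margeff(at="overall", method="dydx", dummy=True)
    names = [c for c in Xc.columns if c != "const"]
    i = names.index(target)
    return FitResult(float(eff.margeff[i]), float(eff.margeff_se[i]), int(res.nobs),
                     SCALES["binary"])


def lin_ying_fit(time: np.ndarray, event: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Lin–Ying additive hazards estimator with sandwich covariance.

    Solves ``A beta = b`` where, with ``Zbar(t)`` the at-risk covariate mean,

    - ``A = sum_i  int_0^{X_i} (Z_i - Zbar(t)) Z_i' dt``
    - ``b = sum_{events j} (Z_j - Zbar(X_j))``

    and the covariance is ``A^{-1} B A^{-1}`` with
    ``B = sum_{events j} (Z_j - Zbar(X_j)) (Z_j - Zbar(X_j))'``.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order].astype(bool)
    Z = X[order]
    n, k = Z.shape

    # suffix statistics over the at-risk sets (rows j..n-1 share exit time >= t_j)
    S1 = np.cumsum(Z[::-1], axis=0)[::-1]                # (n, k) suffix sums
    ZZ = Z[:, :, None] * Z[:, None, :]                   # (n, k, k)
    S2 = np.cumsum(ZZ[::-1], axis=0)[::-1]               # suffix sums of outer products
    n_at_risk = np.arange(n, 0, -1, dtype=float)

    dt = np.diff(np.concatenate([[0.0], t]))             # interval ending at t_j
    outer_mean = S1[:, :, None] * S1[:, None, :] / n_at_risk[:, None, None]
    A = np.tensordot(dt, S2 - outer_mean, axes=(0, 0))

    # event contributions: at-risk set at an event time starts at the first
    # position of its tie group
    first_pos = np.searchsorted(t, t, side="left")
    zbar = S1[first_pos] / n_at_risk[first_pos, None]
    resid = (Z - zbar)[d]
    b = resid.sum(axis=0)
    B = resid.T @ resid

    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"additive hazards design singular: {exc}") from exc
    beta = Ainv @ b
    cov = Ainv @ B @ Ainv
    return beta, cov


def additive_hazards_fit(
    data: PGDataset,
    regressors: Sequence[str],
    covariates: Sequence[str] = (),
) -> SurvivalFit:
    """Fit the additive hazards model for the requested regressors + covariates.

    Returns per-year hazard differences; the same regressor sets as the
    continuous recipes apply, so all five estimators use this adapter
    identically for time-to-event outcomes.
    """
    if data.outcome_type != "survival":
        raise ValidationError("additive_hazards_fit requires a survival outcome",
                              code="wrong_outcome_type")
    X = _design(data, regressors, covariates)
    event = data.event
    if event.sum() < 1:
        raise SingularDesignError("no events observed")
    for col in regressors:
        if col in X.columns and set(np.unique(X[col])) <= {0.0, 1.0}:
            if event[(X[col] == 1).to_numpy()].sum() == 0 and X[col].sum() > 0:
                raise SingularDesignError(f"zero events in stratum {col} = 1")
    beta, cov = lin_ying_fit(data.time, event, X.to_numpy(dtype=float))
    return SurvivalFit(
        names=list(X.columns),
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        n=data.n,
        n_events=int(event.sum()),
    )


def survival_target_fit(
    data: PGDataset,
    target: str,
    regressors: Sequence[str],
    covariates: Sequence[str],
) -> FitResult:
    """Additive-hazards coefficient of ``target`` as a :class:`FitResult`."""
    fit = additive_hazards_fit(data, [target] + list(regressors), covariates)
    if target not in fit.names:
        raise SingularDesignError(f"target regressor {target!r} has no variation")
    beta, se = fit.coefficient(target)
    return FitResult(beta, se, fit.n, SCALES["survival"])
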