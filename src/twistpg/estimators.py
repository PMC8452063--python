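"""The five GMTE point estimators.

The genetically moderated treatment effect (GMTE) is the average causal
contrast between receiving the full, genotype-enabled effect of a treatment
(``T* = T G = 1``) and receiving its reduced or absent effect (``T* = 0``).
Each estimator is the coefficient of one derived regressor in an additive
model of the outcome:

=========  ===============================================  =========================
estimator  model (continuous-outcome form)                  sufficient assumptions
=========  ===============================================  =========================
GMTE(1)    coef of ``T*``    in ``Y ~ T + T* + Z``          PG3 and (PG1&PG2 or NUC)
GMTE(0)    coef of ``T*-``   in ``Y ~ T- + T*- + Z``        PG3 and (PG1&PG2 or NUC)
                                                            (targets ZERO: a
                                                            falsification estimate)
RGMTE      GMTE(1) - GMTE(0), or coef of ``T*`` in          PG1 or NUC
           ``Y ~ T + T* + T^* + Z``
MR         coef of ``T^*``   in ``Y ~ T^* + Z``             (PG1 or Hom) and
                                                            (PG2 or NUC) and PG3
CAT        coef of ``T_cat`` in ``Y ~ T_cat + Z``           (PG1 or PG3), NUC, Hom
=========  ===============================================  =========================

where PG1-PG3 are genotype independence of treatment, of confounders, and of
outcome given treatment and confounders; Hom is no treatment effect in the
``G = 0`` group; NUC is no unmeasured confounding.  Binary and survival
outcomes use the same regressor sets through :mod:`twistpg.outcomes`.

Standard errors are model-based (a heteroskedasticity-robust option exists
behind ``EstimandSpec.robust``); the MR second stage ignores first-stage
uncertainty, which is anti-conservative in small samples; p-values are
two-sided normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import PGDataset, build_derived
from .errors import (
    SingularDesignError,
    ValidationError,
    WeakInstrumentError,
)
from .outcomes import (
    SCALES,
    FitResult,
    continuous_fit,
    risk_difference_fit,
    survival_target_fit,
)

ESTIMATORS = ("CAT", "GMTE0", "GMTE1", "RGMTE", "MR")

ASSUMPTIONS = {
    "CAT": "{PG1 u PG3} n NUC n Hom",
    "GMTE0": "PG3 n {(PG1 n PG2) u NUC} (targets zero)",
    "GMTE1": "PG3 n {(PG1 n PG2) u NUC}",
    "RGMTE": "PG1 u NUC",
    "MR": "{PG1 u Hom} n {PG2 u NUC} n PG3",
}

#: regressor recipes: estimator -> (target, additional regressors)
RECIPES = {
    "GMTE1": ("T_star", ("T",)),
    "GMTE0": ("T_star_minus", ("T_minus",)),
    "RGMTE": ("T_star", ("T", "T_hat_star")),
    "MR": ("T_hat_star", ()),
    "CAT": ("T_cat", ()),
}


@dataclass
class EstimandSpec:
    """How to fit: adjustment set, outcome type and significance level."""

    covariates: Sequence[str] | None = None  # None -> all dataset covariates
    outcome_type: str | None = None          # None -> dataset outcome type
    alpha: float = 0.05
    robust: bool = False
    binary_method: str = "ame"               # "ame" or "lpm"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)", code="bad_alpha")

    def resolve(self, data: PGDataset) -> tuple[tuple[str, ...], str]:
        cov = tuple(self.covariates) if self.covariates is not None else data.covariates
        return cov, self.outcome_type or data.outcome_type


@dataclass
class Estimate:
    """One labelled GMTE estimate on a collapsible difference scale."""

    label: str
    beta: float
    se: float
    p: float
    n: int
    assumptions: str
    scale: str
    percent: bool = False
    method: str | None = field(default=None, compare=False)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se

    def as_percent(self) -> "Estimate":
        """Render a per-year hazard difference on the percent scale (x100)."""
        if self.scale != SCALES["survival"]:
            raise ValidationError("percent rendering applies to hazard differences only",
                                  code="not_hazard_scale")
        if self.percent:
            return self
        return Estimate(self.label, self.beta * 100.0, self.se * 100.0, self.p,
                        self.n, self.assumptions, self.scale, percent=True,
                        method=self.method)

    def to_dict(self) -> dict:
        return {
            "label": self.label, "beta": self.beta, "se": self.se, "p": self.p,
            "n": self.n, "assumptions": self.assumptions, "scale": self.scale,
            "percent": self.percent,
        }


def two_sided_p(beta: float, se: float) -> float:
    if se <= 0:
        raise ValidationError("standard error must be positive", code="bad_se")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _prepare(data: PGDataset) -> PGDataset:
    return data if data.has_derived else build_derived(data)


def _fit(data: PGDataset, target: str, extra: Sequence[str], spec: EstimandSpec) -> FitResult:
    cov, otype = spec.resolve(data)
    if otype == "continuous":
        return continuous_fit(data, target, extra, cov, robust=spec.robust)
    if otype == "binary":
        return risk_difference_fit(data, target, extra, cov,
                                   method=spec.binary_method, robust=spec.robust)
    if otype == "survival":
        return survival_target_fit(data, target, extra, cov)
    raise ValidationError(f"unknown outcome type {otype!r}")


def _make(label: str, fit: FitResult, method: str | None = None) -> Estimate:
    return Estimate(label, fit.beta, fit.se, two_sided_p(fit.beta, fit.se),
                    fit.n, ASSUMPTIONS[label], fit.scale, method=method)


def _require_stratum(data: PGDataset, treated: bool, estimator: str) -> None:
    T = data.T
    G = data.G
    mask = T == 1 if treated else T == 0
    word = "treated" if treated else "untreated"
    for g in (0, 1):
        count = int(((G == g) & mask).sum())
        if count == 0:
            raise SingularDesignError(
                f"{estimator}: genotype level G={g} absent among the {word}"
            )
        if count < 2:
            raise SingularDesignError(
                f"{estimator}: stratum (G={g}, {word}) has fewer than 2 rows"
            )


def gmte1(data: PGDataset, spec: EstimandSpec | None = None) -> Estimate:
    """Genotype contrast among the treated (coefficient of ``T*``).

    Accepts treated-only datasets, where the model reduces to the outcome on
    ``G`` plus covariates among the treated.
    """
    spec = spec or EstimandSpec()
    data = _prepare(data)
    _require_stratum(data, treated=True, estimator="GMTE1")
    target, extra = RECIPES["GMTE1"]
    if data.treated_only:
        extra = ()  # T is constant; the intercept absorbs it
    return _make("GMTE1", _fit(data, target, extra, spec))


def gmte0(data: PGDataset, spec: EstimandSpec | None = None) -> Estimate:
    """Genotype contrast among the untreated (coefficient of ``T*-``).

    Under the PG assumptions this targets zero; a significantly non-zero
    value falsifies them and estimates the shared bias of GMTE(1).
    """
    spec = spec or EstimandSpec()
    data = _prepare(data)
    if data.treated_only:
        raise SingularDesignError("GMTE0 requires untreated individuals")
    _require_stratum(data, treated=False, estimator="GMTE0")
    target, extra = RECIPES["GMTE0"]
    return _make("GMTE0", _fit(data, target, extra, spec))


def rgmte(data: PGDataset, spec: EstimandSpec | None = None,
          method: str = "regression") -> Estimate:
    """Robust GMTE: GMTE(1) minus GMTE(0).

    ``method="difference"`` subtracts the two estimates with
    ``SE = sqrt(se1^2 + se0^2)`` (the genetic contrasts come from disjoint
    treated/untreated strata); ``method="regression"`` takes the coefficient
    of ``T*`` in the model with ``T``, ``T*``, ``T^*`` and covariates.  The
    two are identical without covariates and agree to O(1/n) with pooled
    additive covariates.
    """
    spec = spec or EstimandSpec()
    data = _prepare(data)
    _require_stratum(data, treated=True, estimator="RGMTE")
    _require_stratum(data, treated=False, estimator="RGMTE")
    if method == "difference":
        e1 = gmte1(data, spec)
        e0 = gmte0(data, spec)
        beta = e1.beta - e0.beta
        se = float(np.hypot(e1.se, e0.se))
        return Estimate("RGMTE", beta, se, two_sided_p(beta, se), data.n,
                        ASSUMPTIONS["RGMTE"], e1.scale, method="difference")
    if method != "regression":
        raise ValidationError(f"unknown RGMTE method {method!r}", code="unknown_method")
    target, extra = RECIPES["RGMTE"]
    return _make("RGMTE", _fit(data, target, extra, spec), method="regression")


def mr(data: PGDataset, spec: EstimandSpec | None = None) -> Estimate:
    """Wald-type estimate using the genotype as an instrument for ``T*``.

    Implemented as the coefficient of the genotype-predicted moderator
    ``T^* = E[T*|G]`` (so the no-covariate case reduces to the ratio of the
    gene-outcome and gene-``T*`` associations).  Note ``E[T*|G=0] = 0`` by
    construction, so the denominator equals ``E[T|G=1]``.
    """
    spec = spec or EstimandSpec()
    data = _prepare(data)
    G = data.G
    if len(np.unique(G)) < 2:
        raise SingularDesignError("MR: genotype is constant; contrast undefined")
    denom = data.df["T_hat_star"].to_numpy()[G == 1].mean()
    if abs(denom) < 1e-10:
        raise WeakInstrumentError(
            "MR denominator E[T*|G=1] - E[T*|G=0] is numerically zero"
        )
    n_treated_carriers = int(data.df["T_star"].sum())
    if n_treated_carriers < 10:
        warnings.warn(
            f"MR: only {n_treated_carriers} treated carriers; the Wald ratio "
            "is imprecise and bias-prone at low allele frequency",
            UserWarning,
            stacklevel=2,
        )
    target, extra = RECIPES["MR"]
    return _make("MR", _fit(data, target, extra, spec))


def cat(data: PGDataset, spec: EstimandSpec | None = None) -> Estimate:
    """Corrected As-Treated: treated-untreated difference rescaled by E[G|T=1]."""
    spec = spec or EstimandSpec()
    data = _prepare(data)
    T = data.T
    if not (T == 0).any() or not (T == 1).any():
        raise SingularDesignError("CAT requires both treated and untreated rows")
    if data.G[T == 1].mean() <= 0:
        raise SingularDesignError("CAT: no carriers among the treated; rescaling undefined")
    target, extra = RECIPES["CAT"]
    return _make("CAT", _fit(data, target, extra, spec))


_DISPATCH = {"CAT": cat, "GMTE0": gmte0, "GMTE1": gmte1, "RGMTE": rgmte, "MR": mr}


def fit_single(data: PGDataset, label: str, spec: EstimandSpec | None = None) -> Estimate:
    if label not in _DISPATCH:
        raise ValidationError(f"unknown estimator {label!r}; choose from {ESTIMATORS}",
                              code="unknown_estimator")
    return _DISPATCH[label](data, spec)


def fit_all(data: PGDataset, spec: EstimandSpec | None = None) -> dict[str, Estimate]:
    """All five single estimates, keyed by label."""
    data = _prepare(data)
    return {label: fit_single(data, label, spec) for label in ESTIMATORS}
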