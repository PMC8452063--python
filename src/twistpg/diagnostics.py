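"""Estimator-specific confounder tests.

Each GMTE estimator can be biased by measured variables through its own
channel.  The test re-runs the estimator's continuous-outcome recipe with a
candidate confounder as the *outcome* (excluded from its own adjustment
set): a significantly non-zero coefficient signals a bias channel for the
real analysis unless that variable is adjusted for.  For the CAT estimator
the genotype itself is additionally testable (a genotype imbalance between
treated and untreated directly biases CAT).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import PGDataset, build_derived
from .errors import ValidationError
from .estimators import ESTIMATORS, EstimandSpec, fit_single

DEFAULT_ALPHA = 0.05


@dataclass
class ConfounderTestResult:
    estimator: str
    variable: str
    beta: float
    se: float
    p: float
    alpha: float
    flagged: bool  # True => potential bias; adjust for this variable

    @property
    def verdict(self) -> str:
        return ("potential bias - adjust for this variable"
                if self.flagged else "no detectable bias channel")

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator, "variable": self.variable,
            "beta": self.beta, "se": self.se, "p": self.p,
            "alpha": self.alpha, "flagged": self.flagged, "verdict": self.verdict,
        }


def confounder_test(
    data: PGDataset,
    estimator: str,
    variable: str,
    alpha: float = DEFAULT_ALPHA,
    bonferroni_m: int | None = None,
) -> ConfounderTestResult:
    """Run ``estimator``'s continuous recipe with ``variable`` as the outcome.

    The tested variable is removed from the adjustment set of its own test;
    the remaining covariates are retained.  Binary candidates are tested on
    the linear-probability scale (the recipe is linear regardless).
    ``bonferroni_m`` optionally divides ``alpha`` for multiplicity.
    """
    if estimator not in ESTIMATORS:
        raise ValidationError(f"unknown estimator {estimator!r}", code="unknown_estimator")
    if variable == "G":
        if estimator != "CAT":
            raise ValidationError(
                "G itself is only testable for the CAT estimator", code="bad_test_variable"
            )
        values = data.df["G"]
    else:
        if variable not in data.df.columns:
            raise ValidationError(f"variable {variable!r} not in dataset", code="missing_columns")
        values = pd.to_numeric(data.df[variable], errors="coerce")
        if values.isna().any():
            raise ValidationError(f"variable {variable!r} is not numeric", code="non_numeric")
    if values.nunique() < 2:
        raise ValidationError(f"variable {variable!r} is constant", code="constant_variable")

    remaining = tuple(c for c in data.covariates if c != variable)
    df = data.df.copy()
    df["Y"] = values.to_numpy(dtype=float)
    test_data = build_derived(
        PGDataset(df=df.drop(columns=["time", "event"], errors="ignore"),
                  outcome_type="continuous", covariates=remaining)
    )
    spec = EstimandSpec(covariates=remaining, outcome_type="continuous", alpha=alpha)
    est = fit_single(test_data, estimator, spec)
    level = alpha / bonferroni_m if bonferroni_m else alpha
    return ConfounderTestResult(
        estimator=estimator, variable=variable,
        beta=est.beta, se=est.se, p=est.p, alpha=level,
        flagged=bool(est.p < level),
    )


def confounder_scan(
    data: PGDataset,
    estimators: tuple[str, ...] = ESTIMATORS,
    variables: tuple[str, ...] | None = None,
    alpha: float = DEFAULT_ALPHA,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Variable x estimator grid of confounder-test betas and p-values."""
    variables = tuple(variables or data.covariates)
    m = len(variables) * len(estimators) if bonferroni else None
    rows = []
    for var in variables:
        for est in estimators:
            r = confounder_test(data, est, var, alpha=alpha, bonferroni_m=m)
            rows.append(r.to_dict())
    return pd.DataFrame(rows)
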