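"""Inverse-variance-weighted pooling with a heterogeneity gate.

Two (or three) approximately uncorrelated estimates of the same quantity are
pooled as ``sum(w_i b_i) / sum(w_i)`` with ``w_i = 1/se_i^2``.  The Cochran
heterogeneity statistic ``Q = sum(w_i (b_i - pooled)^2)`` is referred to a
chi-square law with ``k - 1`` degrees of freedom; a pooled estimate is
flagged for use only when ``Q``'s p-value is at least the pre-specified
significance level.

Only combinations of approximately uncorrelated estimates are enumerated:
the RGMTE and MR estimates are in general highly correlated with GMTE(1) and
are never pooled with it.  The sanctioned set is four singles (CAT, GMTE1,
RGMTE, MR), four pairs (CAT/GMTE1, CAT/RGMTE, CAT/MR, RGMTE/MR) and the
triple CAT/RGMTE/MR — nine results in total.  The CAT/MR correlation is
non-zero when the genotype predicts treatment, but is treated as negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CombinationError, ScaleMismatchError
from .estimators import Estimate, two_sided_p

#: the sanctioned multi-estimate combinations, in reporting order
SANCTIONED = (
    ("CAT", "GMTE1"),
    ("CAT", "RGMTE"),
    ("CAT", "MR"),
    ("RGMTE", "MR"),
    ("CAT", "RGMTE", "MR"),
)

SINGLES = ("CAT", "GMTE1", "RGMTE", "MR")


@dataclass
class CombinedEstimate:
    """IVW pooling of 2-3 component estimates with its heterogeneity gate."""

    labels: tuple[str, ...]
    beta: float
    se: float
    p: float
    q: float
    q_df: int
    q_p: float
    passed: bool
    alpha: float
    scale: str | None = None
    percent: bool = False

    @property
    def label(self) -> str:
        return "/".join(self.labels)

    def to_dict(self) -> dict:
        return {
            "label": self.label, "beta": self.beta, "se": self.se, "p": self.p,
            "Q": self.q, "Q_df": self.q_df, "Q_p": self.q_p, "combine": self.passed,
            "alpha": self.alpha, "scale": self.scale, "percent": self.percent,
        }


@dataclass
class UnavailableResult:
    """Placeholder for a result whose inputs were missing (never silently skipped)."""

    label: str
    reason: str
    available: bool = False

    def to_dict(self) -> dict:
        return {"label": self.label, "available": False, "reason": self.reason}


def _components(components: Iterable) -> tuple[list[str], np.ndarray, np.ndarray, str | None, bool]:
    labels, betas, ses = [], [], []
    scales, percents = set(), set()
    for comp in components:
        if isinstance(comp, Estimate):
            labels.append(comp.label)
            betas.append(comp.beta)
            ses.append(comp.se)
            scales.add(comp.scale)
            percents.add(comp.percent)
        else:
            label, beta, se = comp
            labels.append(str(label))
            betas.append(float(beta))
            ses.append(float(se))
    if len(scales) > 1 or len(percents) > 1:
        raise ScaleMismatchError(
            f"cannot pool estimates on different scales: {sorted(scales)} percent={sorted(percents)}"
        )
    scale = scales.pop() if scales else None
    percent = percents.pop() if percents else False
    return labels, np.asarray(betas, float), np.asarray(ses, float), scale, percent


def ivw_combine(components: Sequence, alpha: float = 0.05) -> CombinedEstimate:
    """Pool 2-3 estimates by inverse-variance weighting; gate on Cochran's Q.

    ``components`` may be :class:`Estimate` objects (scale-checked) or bare
    ``(label, beta, se)`` tuples (assumed to share a scale), so printed
    summary tables can be pooled without individual-level data.
    """
    labels, betas, ses, scale, percent = _components(components)
    k = len(labels)
    if k not in (2, 3):
        raise CombinationError(f"IVW combination takes 2 or 3 components, got {k}")
    if np.any(ses <= 0):
        raise CombinationError("all component standard errors must be positive")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (betas - pooled) ** 2))
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, q_df))
    return CombinedEstimate(
        labels=tuple(labels), beta=pooled, se=se, p=two_sided_p(pooled, se),
        q=q, q_df=q_df, q_p=q_p, passed=bool(q_p >= alpha), alpha=alpha,
        scale=scale, percent=percent,
    )


def enumerate_twist(estimates: dict, alpha: float = 0.05) -> dict:
    """The nine single/paired/triple results, keyed ``"CAT"`` ... ``"CAT/RGMTE/MR"``.

    ``estimates`` maps labels to :class:`Estimate` (or ``(label, beta, se)``
    tuples); any of the four singles may be absent, in which case that single
    and every combination needing it are reported as unavailable.
    """
    results: dict[str, object] = {}
    present: dict[str, object] = {}
    for label in SINGLES:
        est = estimates.get(label)
        if est is None:
            results[label] = UnavailableResult(label, "estimate not supplied")
        else:
            results[label] = est
            present[label] = est
    for combo in SANCTIONED:
        key = "/".join(combo)
        missing = [l for l in combo if l not in present]
        if missing:
            results[key] = UnavailableResult(key, f"missing component(s): {', '.join(missing)}")
        else:
            results[key] = ivw_combine([present[l] for l in combo], alpha=alpha)
    return results
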