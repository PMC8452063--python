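"""Dataset contract and derived-regressor construction.

A pharmacogenetic analysis dataset holds, per participant, a binary genotype
indicator ``G`` (1 = treatment-enabling / loss-of-function-carrier group, as
declared by the user), a binary treatment indicator ``T``, an outcome (a
continuous value, a 0/1 event, or a time+event pair) and named covariates
``Z``.  All five GMTE estimators are expressed as regressions on derived
columns of this table:

==============  =====================================================
``T_star``      ``T * G`` — the treatment-moderator regressor
``T_minus``     ``1 - T``
``T_star_minus``  ``(1 - T) * G``
``T_hat_star``  within-genotype-level sample mean of ``T_star``
                (the genotype-predicted moderator, the MR first stage)
``T_cat``       ``mean(G | T = 1) * T`` (the Corrected-As-Treated regressor)
==============  =====================================================
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

OUTCOME_TYPES = ("continuous", "binary", "survival")

DERIVED_COLUMNS = ("T_star", "T_minus", "T_star_minus", "T_hat_star", "T_cat")


@dataclass
class PGDataset:
    """Validated participant-level table with derived GMTE regressors.

    Parameters
    ----------
    df
        One row per participant.  Must contain columns ``G`` and ``T`` plus
        the outcome column(s) and covariates.  Continuous/binary outcomes live
        in ``Y``; survival outcomes in ``time``/``event``.
    outcome_type
        One of ``continuous``, ``binary``, ``survival``.
    covariates
        Names of the measured-confounder columns carried into every fitted
        model (additively).
    truth
        Optional simulator-internal ground truth (e.g. the unmeasured
        confounder ``U`` and the true GMTE).  Never visible to estimators.
    """

    df: pd.DataFrame
    outcome_type: str = "continuous"
    covariates: tuple[str, ...] = ()
    treated_only: bool = False
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        _validate(self)

    # -- column accessors -------------------------------------------------
    @property
    def G(self) -> np.ndarray:
        return self.df["G"].to_numpy(dtype=float)

    @property
    def T(self) -> np.ndarray:
        return self.df["T"].to_numpy(dtype=float)

    @property
    def Y(self) -> np.ndarray:
        if self.outcome_type == "survival":
            raise ValidationError(
                "survival datasets expose 'time'/'event', not Y", code="no_scalar_outcome"
            )
        return self.df["Y"].to_numpy(dtype=float)

    @property
    def time(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def has_derived(self) -> bool:
        return all(c in self.df.columns for c in DERIVED_COLUMNS)

    def Z(self) -> pd.DataFrame:
        return self.df[list(self.covariates)]

    def subset(self, mask: np.ndarray) -> "PGDataset":
        """Row subset sharing outcome type and covariates (derived columns kept as-is)."""
        return replace(self, df=self.df.loc[mask].reset_index(drop=True))

    def metadata(self) -> dict:
        """JSON-serialisable description of the dataset (no participant data)."""
        return {
            "n": self.n,
            "outcome_type": self.outcome_type,
            "covariates": list(self.covariates),
            "treated_only": self.treated_only,
            "n_treated": int(self.df["T"].sum()),
            "n_carriers": int(self.df["G"].sum()),
            "derived": self.has_derived,
        }

    def metadata_json(self) -> str:
        return json.dumps(self.metadata(), sort_keys=True)


def _check_binary(x: pd.Series, name: str) -> None:
    vals = pd.unique(x.dropna())
    if not np.isin(vals, [0, 1]).all():
        raise ValidationError(
            f"column {name!r} must be binary 0/1; found values {sorted(vals)[:6]}",
            code="non_binary",
        )


def _validate(data: PGDataset) -> None:
    df = data.df
    if data.outcome_type not in OUTCOME_TYPES:
        raise ValidationError(
            f"outcome_type must be one of {OUTCOME_TYPES}, got {data.outcome_type!r}"
        )
    required = ["G", "T"]
    if data.outcome_type == "survival":
        required += ["time", "event"]
    else:
        required += ["Y"]
    missing = [c for c in required + list(data.covariates) if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}", code="missing_columns")
    if len(df) == 0:
        raise ValidationError("dataset is empty", code="empty_dataset")
    if df[required + list(data.covariates)].isna().any().any():
        raise ValidationError(
            "missing values present; drop or impute before constructing PGDataset",
            code="missing_values",
        )
    _check_binary(df["G"], "G")
    _check_binary(df["T"], "T")
    if data.outcome_type == "binary":
        _check_binary(df["Y"], "Y")
    if data.outcome_type == "survival":
        if (df["time"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("survival times must be non-negative", code="negative_time")
        _check_binary(df["event"], "event")
    g_levels = set(pd.unique(df["G"]))
    t_levels = set(pd.unique(df["T"]))
    if g_levels < {0, 1}:
        raise ValidationError(
            "both genotype levels must be present", code="missing_genotype_level"
        )
    all_treated = t_levels == {1}
    if t_levels < {0, 1} and not all_treated:
        raise ValidationError("no treated individuals in dataset", code="missing_treatment_level")
    # treated-only tables are legal but only the GMTE(1) estimator may use them
    object.__setattr__(data, "treated_only", bool(all_treated))


def build_derived(data: PGDataset) -> PGDataset:
    """Populate the derived regressors.  Idempotent.

    ``T_hat_star`` is the within-genotype-level sample mean of ``T_star``;
    since ``T_star = 0`` identically when ``G = 0``, it equals
    ``mean(T | G = 1) * G``.  ``T_cat`` rescales ``T`` by the carrier
    proportion among the treated and is undefined without treated rows.
    """
    df = data.df.copy()
    G = df["G"].to_numpy(dtype=float)
    T = df["T"].to_numpy(dtype=float)
    t_star = T * G
    df["T_star"] = t_star
    df["T_minus"] = 1.0 - T
    df["T_star_minus"] = (1.0 - T) * G
    t_hat = np.zeros_like(G)
    carriers = G == 1
    t_hat[carriers] = t_star[carriers].mean()
    df["T_hat_star"] = t_hat
    treated = T == 1
    if not treated.any():
        raise ValidationError(
            "T_cat undefined: no treated rows", code="no_treated_rows"
        )
    df["T_cat"] = G[treated].mean() * T
    return replace(data, df=df)


def read_dataset(
    path,
    column_map: Mapping[str, str],
    outcome_type: str = "continuous",
    covariates: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> PGDataset:
    """Read a delimited text file into a validated :class:`PGDataset`.

    ``column_map`` maps the canonical names (``G``, ``T``, and either ``Y`` or
    ``time``/``event``) to the file's column names.  ``covariates`` are file
    column names carried through unchanged.  Comma- and tab-delimited dialects
    are auto-detected unless ``delimiter`` is given; a header row is required.
    Rows with missing values in any mapped column are dropped (count logged).
    """
    covariates = list(covariates or [])
    if outcome_type == "survival":
        needed = ["G", "T", "time", "event"]
        if not {"time", "event"} <= set(column_map):
            raise ValidationError(
                "survival outcome requires 'time' and 'event' in column_map",
                code="missing_survival_columns",
            )
    else:
        needed = ["G", "T", "Y"]
    for key in needed:
        if key not in column_map:
            raise ValidationError(f"column_map missing entry for {key!r}", code="missing_columns")

    if delimiter is None:
        raw = pd.read_csv(path, sep=None, engine="python")
    else:
        raw = pd.read_csv(path, sep=delimiter)
    absent = [v for v in list(column_map.values()) + covariates if v not in raw.columns]
    if absent:
        raise ValidationError(f"mapped columns not in file: {absent}", code="missing_columns")

    df = raw[[column_map[k] for k in needed] + covariates].copy()
    df.columns = needed + covariates
    for col in ("G", "T"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    before = len(df)
    df = df.dropna().reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("read_dataset: dropped %d/%d rows with missing mapped values", dropped, before)
    if len(df) == 0:
        raise ValidationError("no complete rows after filtering", code="empty_dataset")
    data = PGDataset(df=df, outcome_type=outcome_type, covariates=tuple(covariates))
    return build_derived(data)


def write_dataset(data: PGDataset, path, delimiter: str = ",") -> None:
    """Write the full table (including derived columns) as delimited text."""
    data.df.to_csv(path, sep=delimiter, index=False)
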