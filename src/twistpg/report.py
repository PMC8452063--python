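"""Reporting: avoided-event translation, forest plots, end-to-end pipeline.

A per-year hazard difference on the percent scale, multiplied by the
person-years actually observed in the group of interest, translates a GMTE
estimate into an expected number of events that could be avoided (or
incurred) if every treated patient experienced the genotype-enabled effect.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .combine import UnavailableResult, enumerate_twist
from .dataset import read_dataset
from .diagnostics import confounder_scan
from .errors import ScaleMismatchError, StageError, TwistError, ValidationError
from .estimators import EstimandSpec, Estimate, fit_all

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class AvoidedEvents:
    """Event-count translation of a percent-per-year hazard difference."""

    beta_percent: float
    se: float
    person_years: float
    count: int              # signed, positive = excess events attributable
    magnitude: int          # |count|, the prose-style "events avoided"
    ci: tuple[int, int]     # signed 95% interval, rounded

    def to_dict(self) -> dict:
        return {
            "beta_percent_per_year": self.beta_percent, "se": self.se,
            "person_years": self.person_years, "count": self.count,
            "magnitude": self.magnitude, "ci": list(self.ci),
        }


def avoided_events(beta_percent: float, se: float, person_years: float) -> AvoidedEvents:
    """Expected events over ``person_years`` for a %-per-year hazard difference.

    ``count = round(beta/100 * person_years)`` with rounding half away from
    zero applied only at the final integer step; the interval applies the
    same transform to ``beta -/+ 1.96 se``.
    """
    if person_years <= 0:
        raise ValidationError("person_years must be positive", code="bad_person_years")
    if se < 0:
        raise ValidationError("se must be non-negative", code="bad_se")
    scale = person_years / 100.0
    count = _round_half_away(beta_percent * scale)
    lo = _round_half_away((beta_percent - Z975 * se) * scale)
    hi = _round_half_away((beta_percent + Z975 * se) * scale)
    return AvoidedEvents(
        beta_percent=beta_percent, se=se, person_years=person_years,
        count=count, magnitude=abs(count), ci=(lo, hi),
    )


def avoided_events_from_estimate(est: Estimate, person_years: float) -> AvoidedEvents:
    """Same, but enforcing the percent-hazard-scale contract on the input."""
    if est.scale != "hazard_difference" or not est.percent:
        raise ScaleMismatchError(
            "avoided-events translation requires a hazard difference on the percent scale"
        )
    return avoided_events(est.beta, est.se, person_years)


def forest_plot(results: dict, out_path, gmte0: Estimate | None = None,
                title: str | None = None) -> Path:
    """Forest plot of the nine results (plus the GMTE(0) falsification bar).

    Singles and combinations that pass the heterogeneity gate are drawn as
    blue squares; failing combinations black; the GMTE(0) estimate, which
    targets zero rather than the GMTE, is a red bar.  Layout is
    deterministic given the inputs.
    """
    rows = [(k, v) for k, v in results.items() if not isinstance(v, UnavailableResult)]
    if gmte0 is not None:
        rows.append(("GMTE0", gmte0))
    if not rows:
        raise ValidationError("no available results to plot", code="empty_results")

    fig, ax = plt.subplots(figsize=(6.4, 0.45 * len(rows) + 1.2))
    ys = range(len(rows), 0, -1)
    for y, (key, res) in zip(ys, rows):
        passed = getattr(res, "passed", True)  # singles always "pass"
        color = "red" if key == "GMTE0" else ("tab:blue" if passed else "black")
        half = Z975 * res.se
        ax.errorbar(res.beta, y, xerr=[[half], [half]], fmt="s", color=color,
                    ecolor=color, capsize=3, markersize=5)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(ys))
    ax.set_yticklabels([k for k, _ in rows])
    ax.set_xlabel("GMTE estimate (difference scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, metadata=_stable_metadata(out_path.suffix))
    plt.close(fig)
    return out_path


def _stable_metadata(suffix: str) -> dict | None:
    # strip timestamps so identical inputs give identical bytes
    if suffix == ".png":
        return {"Software": "twistpg"}
    if suffix == ".svg":
        return {"Date": None}
    return None


BUNDLE_KEYS = ("meta", "singles", "gmte0", "combined", "diagnostics")


def validate_bundle(bundle: dict) -> None:
    missing = [k for k in BUNDLE_KEYS if k not in bundle]
    if missing:
        raise ValidationError(f"results bundle missing sections {missing}", code="bad_bundle")


def run_pipeline(config: dict | str, out_dir=None) -> dict:
    """Execute read -> derive -> estimators -> diagnostics -> combination -> outputs.

    ``config`` is a dict (or path to a JSON file) with keys:

    - ``data``: path to a delimited text file; or ``summary``: list of
      ``{label, beta, se}`` records for combination-only use;
    - ``columns``: mapping for G/T/Y (or time/event); ``covariates``;
    - ``outcome_type``; ``alpha`` (default 0.05); ``percent`` (render hazard
      differences as % per year); ``person_years`` (optional avoided-events
      translation); ``plot`` (optional output image name).

    Returns the results bundle (also written to ``out_dir`` when given);
    errors are re-raised tagged with the failing stage.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    alpha = float(config.get("alpha", 0.05))
    bundle: dict = {"meta": {"alpha": alpha}, "singles": {}, "gmte0": None,
                    "combined": {}, "diagnostics": None}

    if "summary" in config:
        try:
            supplied = {r["label"]: (r["label"], float(r["beta"]), float(r["se"]))
                        for r in config["summary"]}
            gmte0_row = supplied.pop("GMTE0", None)
            results = enumerate_twist(supplied, alpha=alpha)
        except TwistError as exc:
            raise StageError("combine", str(exc)) from exc
        bundle["meta"]["mode"] = "summary"
        for key, res in results.items():
            rec = (res.to_dict() if hasattr(res, "to_dict")
                   else {"label": res[0], "beta": res[1], "se": res[2]})
            (bundle["combined"] if "/" in key else bundle["singles"])[key] = rec
        if gmte0_row is not None:
            bundle["gmte0"] = {"label": "GMTE0", "beta": gmte0_row[1], "se": gmte0_row[2]}
        validate_bundle(bundle)
        return _write_bundle(bundle, out_dir)

    try:
        data = read_dataset(
            config["data"], config["columns"],
            outcome_type=config.get("outcome_type", "continuous"),
            covariates=config.get("covariates", ()),
        )
    except (TwistError, KeyError, OSError) as exc:
        raise StageError("read", str(exc)) from exc
    bundle["meta"].update(data.metadata())
    logger.info("pipeline: dataset %s", data.metadata_json())

    spec = EstimandSpec(alpha=alpha)
    try:
        singles = fit_all(data, spec)
    except TwistError as exc:
        raise StageError("fit", str(exc)) from exc
    if config.get("percent") and data.outcome_type == "survival":
        singles = {k: v.as_percent() for k, v in singles.items()}
    for label, est in singles.items():
        logger.info("pipeline: fitted %s on n=%d rows", label, est.n)

    try:
        bundle["diagnostics"] = confounder_scan(data, alpha=alpha).to_dict(orient="records")
    except TwistError as exc:
        raise StageError("diagnose", str(exc)) from exc

    try:
        results = enumerate_twist(singles, alpha=alpha)
    except TwistError as exc:
        raise StageError("combine", str(exc)) from exc
    bundle["gmte0"] = singles["GMTE0"].to_dict()
    for key, res in results.items():
        rec = res.to_dict() if hasattr(res, "to_dict") else res
        (bundle["combined"] if "/" in key else bundle["singles"])[key] = rec

    if config.get("person_years"):
        py = float(config["person_years"])
        events = {}
        for key, res in results.items():
            if isinstance(res, UnavailableResult):
                continue
            if getattr(res, "scale", None) == "hazard_difference" and getattr(res, "percent", False):
                events[key] = avoided_events(res.beta, res.se, py).to_dict()
        bundle["avoided_events"] = events

    if out_dir is not None and config.get("plot"):
        try:
            forest_plot(results, Path(out_dir) / config["plot"], gmte0=singles["GMTE0"])
        except TwistError as exc:
            raise StageError("plot", str(exc)) from exc

    validate_bundle(bundle)
    return _write_bundle(bundle, out_dir)


def _write_bundle(bundle: dict, out_dir) -> dict:
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        rows = []
        for section in ("singles", "combined"):
            for key, rec in bundle[section].items():
                if rec.get("available", True):
                    rows.append({"result": key, **{k: v for k, v in rec.items()
                                                   if not isinstance(v, (list, dict))}})
        import pandas as pd

        pd.DataFrame(rows).to_csv(out_dir / "results.csv", index=False)
    return bundle
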