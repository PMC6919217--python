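"""Full per-cohort analysis: filter, summarise, estimate, stratify, smooth.

``run_analysis`` is the single entry point the CLI drives: it applies the
inclusion criteria once, computes the overall descriptive summary and
conditional-survival curve, repeats both for the age strata (each stratum
truncated independently at the minimum-at-risk threshold), smooths every
curve for presentation, and bundles the lot with the exclusion accounting
and an echo of the parameters used.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import pandas as pd

from .cohort import (CohortSummary, ExclusionReport, apply_inclusion_criteria,
                     summarize_cohort)
from .estimator import (SurvivalCurve, estimate_conditional_survival,
                        stratify_by_age)
from .exceptions import EmptyCurveError
from .smoothing import SmoothCurve, smooth_curve

__all__ = ["AnalysisSettings", "AnalysisResult", "run_analysis",
           "compare_strata", "save_result"]


@dataclasses.dataclass(frozen=True)
class AnalysisSettings:
    """Tunable parameters of the pipeline with the study defaults."""

    min_at_risk: int = 50
    conf: float = 0.95
    age_cutoff: float = 75.0
    span: float = 0.5
    loess_degree: int = 2

    def validate(self) -> None:
        if self.min_at_risk < 1:
            raise ValueError("min_at_risk must be >= 1")
        if not 0.0 < self.conf < 1.0:
            raise ValueError("conf must be in (0, 1)")
        if self.age_cutoff < 0:
            raise ValueError("age_cutoff must be non-negative")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if self.loess_degree not in (0, 1, 2):
            raise ValueError("loess_degree must be 0, 1 or 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class AnalysisResult:
    """Everything one analysis produces, ready for serialization."""

    summary_overall: CohortSummary
    summary_young: CohortSummary | None
    summary_old: CohortSummary | None
    curve_overall: SurvivalCurve
    curve_young: SurvivalCurve
    curve_old: SurvivalCurve
    smooth_overall: SmoothCurve
    smooth_young: SmoothCurve | None
    smooth_old: SmoothCurve | None
    exclusions: ExclusionReport
    config_echo: dict


def _empty_summary(label: str) -> CohortSummary:
    nan = float("nan")
    return CohortSummary(n=0, median_age=nan, iqr_age=(nan, nan), pct_male=nan,
                         median_los=nan, iqr_los=(nan, nan), pct_survived=nan,
                         label=label)


def _stratum_curve(df: pd.DataFrame, settings: AnalysisSettings,
                   label: str) -> SurvivalCurve:
    try:
        return estimate_conditional_survival(
            df, min_at_risk=settings.min_at_risk, conf=settings.conf,
            label=label)
    except EmptyCurveError:
        warnings.warn(
            f"stratum '{label}' has {len(df)} record(s), fewer than "
            f"min_at_risk={settings.min_at_risk}; its curve is empty",
            UserWarning, stacklevel=3)
        return SurvivalCurve.empty_curve(
            min_at_risk=settings.min_at_risk, conf=settings.conf, label=label)


def _smooth_or_none(curve: SurvivalCurve, settings: AnalysisSettings):
    if curve.empty:
        return None
    return smooth_curve(curve, span=settings.span, degree=settings.loess_degree)


def run_analysis(raw: pd.DataFrame,
                 settings: AnalysisSettings | None = None,
                 label: str | None = None) -> AnalysisResult:
    """Run the full deterministic pipeline on a raw admission table."""
    settings = settings or AnalysisSettings()
    settings.validate()
    if label is None:
        label = raw.attrs.get("label", "cohort") or "cohort"

    cohort, report = apply_inclusion_criteria(raw)
    cohort.attrs["label"] = label

    summary_overall = summarize_cohort(cohort, label=label)
    curve_overall = estimate_conditional_survival(
        cohort, min_at_risk=settings.min_at_risk, conf=settings.conf,
        label=label)

    young, old = stratify_by_age(cohort, cutoff=settings.age_cutoff)
    lab_y = f"{label}:under{settings.age_cutoff:g}"
    lab_o = f"{label}:over{settings.age_cutoff:g}"
    summary_young = summarize_cohort(young, label=lab_y) if len(young) else _empty_summary(lab_y)
    summary_old = summarize_cohort(old, label=lab_o) if len(old) else _empty_summary(lab_o)
    curve_young = _stratum_curve(young, settings, lab_y)
    curve_old = _stratum_curve(old, settings, lab_o)

    return AnalysisResult(
        summary_overall=summary_overall,
        summary_young=summary_young,
        summary_old=summary_old,
        curve_overall=curve_overall,
        curve_young=curve_young,
        curve_old=curve_old,
        smooth_overall=smooth_curve(curve_overall, span=settings.span,
                                    degree=settings.loess_degree),
        smooth_young=_smooth_or_none(curve_young, settings),
        smooth_old=_smooth_or_none(curve_old, settings),
        exclusions=report,
        config_echo={"settings": settings.to_dict(), "label": label,
                     "n_raw": report.n_raw, "n_included": report.n_included},
    )


def compare_strata(result: AnalysisResult) -> pd.DataFrame:
    """Day-wise contrast of the young and old curves.

    Inner-joins on days present in both stratum curves and reports
    ``difference = cs_young - cs_old``.  If either stratum is empty the
    comparison is empty, with a warning.
    """
    cols = ["day", "cs_young", "cs_old", "difference"]
    if result.curve_young.empty or result.curve_old.empty:
        warnings.warn("one or both age strata have empty curves; "
                      "comparison is empty", UserWarning, stacklevel=2)
        return pd.DataFrame(columns=cols)
    y = result.curve_young.to_frame()[["day", "cs"]].rename(columns={"cs": "cs_young"})
    o = result.curve_old.to_frame()[["day", "cs"]].rename(columns={"cs": "cs_old"})
    merged = y.merge(o, on="day", how="inner")
    merged["difference"] = merged["cs_young"] - merged["cs_old"]
    return merged[cols]


def save_result(result: AnalysisResult, outdir: str | Path) -> Path:
    """Serialize an :class:`AnalysisResult` as a directory of artifacts.

    Layout: ``summaries.json``, ``exclusions.json``, ``config_echo.json``,
    ``curves/{overall,young,old}.csv`` (raw statistics, 6-decimal
    proportions) and ``smooth/*.csv`` (presentation values plus a JSON
    sidecar recording span/degree/family).
    """
    outdir = Path(outdir)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)
    (outdir / "smooth").mkdir(parents=True, exist_ok=True)

    summaries = {
        "overall": result.summary_overall.to_dict(),
        "young": result.summary_young.to_dict() if result.summary_young else None,
        "old": result.summary_old.to_dict() if result.summary_old else None,
    }
    (outdir / "summaries.json").write_text(json.dumps(summaries, indent=2) + "\n")
    result.exclusions.to_json(outdir / "exclusions.json")
    (outdir / "config_echo.json").write_text(
        json.dumps(result.config_echo, indent=2, sort_keys=True) + "\n")

    for name, curve in (("overall", result.curve_overall),
                        ("young", result.curve_young),
                        ("old", result.curve_old)):
        curve.to_csv(outdir / "curves" / f"{name}.csv")

    sidecar = {}
    for name, sm in (("overall", result.smooth_overall),
                     ("young", result.smooth_young),
                     ("old", result.smooth_old)):
        if sm is None:
            continue
        sm.to_frame().to_csv(outdir / "smooth" / f"{name}.csv", index=False,
                             float_format="%.6f")
        sidecar[name] = sm.metadata
    (outdir / "smooth" / "metadata.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return outdir
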