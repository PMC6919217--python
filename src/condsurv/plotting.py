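"""Figures: conditional survival against day of ICU admission.

Two panels mirror the standard presentation: an overall panel (solid
smoothed line, dashed 95% CI band) and an age-stratified panel (dot-dash
line for the under-75 stratum with dotted CIs, solid line for the 75-and-
over stratum with dashed CIs).  Lines show the LOESS-smoothed curves by
default; the raw per-day estimates stay available in the exported CSVs, and
``smooth=False`` plots them directly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless by design; figures are written, not shown
import matplotlib.pyplot as plt

from .analysis import AnalysisResult
from .estimator import SurvivalCurve
from .exceptions import NoCurveError
from .smoothing import SmoothCurve

__all__ = ["plot_curves"]


def _series(curve: SurvivalCurve, sm: SmoothCurve | None, smooth: bool):
    if smooth and sm is not None:
        lo = sm.ci_lower_smooth if sm.ci_lower_smooth is not None else curve.ci_lower
        hi = sm.ci_upper_smooth if sm.ci_upper_smooth is not None else curve.ci_upper
        return sm.x, sm.y_smooth, lo, hi
    return curve.days, curve.cs, curve.ci_lower, curve.ci_upper


def _draw(ax, curve, sm, smooth, line_style, ci_style, color, label):
    x, y, lo, hi = _series(curve, sm, smooth)
    if len(x) == 1:
        warnings.warn(f"curve '{label}' has a single point; no line drawn",
                      UserWarning, stacklevel=3)
        ax.plot(x, y, marker="o", linestyle="none", color=color, label=label)
        return
    ax.plot(x, y, linestyle=line_style, color=color, label=label)
    ax.plot(x, lo, linestyle=ci_style, color=color, linewidth=0.9)
    ax.plot(x, hi, linestyle=ci_style, color=color, linewidth=0.9)


def plot_curves(result: AnalysisResult, outdir: str | Path,
                smooth: bool = True, formats: tuple[str, ...] = ("svg", "png"),
                dpi: int = 200) -> list[Path]:
    """Write the overall and age-stratified panels; returns the file paths.

    Raises
    ------
    NoCurveError
        if every curve in the result is empty.
    """
    if (result.curve_overall.empty and result.curve_young.empty
            and result.curve_old.empty):
        raise NoCurveError("all curves are empty; nothing to plot")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if not result.curve_overall.empty:
        fig, ax = plt.subplots(figsize=(6, 4.2))
        _draw(ax, result.curve_overall, result.smooth_overall, smooth,
              "solid", "dashed", "black", result.curve_overall.label or "all")
        ax.set_xlabel("Day of ICU admission")
        ax.set_ylabel("Survival to hospital discharge")
        ax.set_ylim(0.0, 1.0)
        ax.set_title("Conditional survival")
        fig.tight_layout()
        for fmt in formats:
            p = outdir / f"conditional_survival_overall.{fmt}"
            fig.savefig(p, dpi=dpi)
            written.append(p)
        plt.close(fig)

    if not (result.curve_young.empty and result.curve_old.empty):
        fig, ax = plt.subplots(figsize=(6, 4.2))
        if not result.curve_young.empty:
            _draw(ax, result.curve_young, result.smooth_young, smooth,
                  "dashdot", "dotted", "tab:blue", "age < cutoff")
        if not result.curve_old.empty:
            _draw(ax, result.curve_old, result.smooth_old, smooth,
                  "solid", "dashed", "tab:red", "age >= cutoff")
        ax.set_xlabel("Day of ICU admission")
        ax.set_ylabel("Survival to hospital discharge")
        ax.set_ylim(0.0, 1.0)
        ax.set_title("Conditional survival by age stratum")
        ax.legend(loc="lower left", frameon=False)
        fig.tight_layout()
        for fmt in formats:
            p = outdir / f"conditional_survival_by_age.{fmt}"
            fig.savefig(p, dpi=dpi)
            written.append(p)
        plt.close(fig)

    return written
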