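"""Locally weighted polynomial smoothing (LOESS) for presentation curves.

For each target point, the ``q = ceil(span * N)`` nearest observations by
distance on the x axis are weighted with the tricube kernel
``w = (1 - (dist / dist_max)^3)^3`` (``dist_max`` the largest distance in
the neighborhood) and a weighted least-squares polynomial of the requested
degree is fitted; the smoothed value is that polynomial evaluated at the
target.  A single gaussian-family pass is used — no bisquare robustness
iterations — and that choice is recorded in the curve metadata.

Smoothing is presentation-only: exported conditional-survival statistics
always remain the unsmoothed per-day proportions.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .estimator import SurvivalCurve
from .exceptions import UnderdeterminedFitError

__all__ = ["SmoothCurve", "LoessSmoother", "loess_fit", "smooth_curve"]


@dataclasses.dataclass
class SmoothCurve:
    """Raw and smoothed values on a common grid of days."""

    x: np.ndarray
    y_raw: np.ndarray
    y_smooth: np.ndarray
    span: float
    degree: int
    ci_lower_smooth: np.ndarray | None = None
    ci_upper_smooth: np.ndarray | None = None
    label: str = ""
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y_raw) == len(self.y_smooth)):
            raise ValueError("x, y_raw and y_smooth must have equal length")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"day": self.x, "cs_raw": self.y_raw,
                           "cs_smooth": self.y_smooth})
        if self.ci_lower_smooth is not None:
            df["ci_lower_smooth"] = self.ci_lower_smooth
            df["ci_upper_smooth"] = self.ci_upper_smooth
        return df


def _tricube(dist: np.ndarray, dist_max: float) -> np.ndarray:
    u = np.clip(dist / dist_max, 0.0, 1.0)
    return (1.0 - u ** 3) ** 3


class LoessSmoother(BaseEstimator, RegressorMixin):
    """Local polynomial regression smoother.

    Parameters
    ----------
    span : float, default 0.5
        Fraction of all points in each local neighborhood, in (0, 1].
    degree : int, default 2
        Local polynomial degree (0, 1 or 2).

    Attributes
    ----------
    x_, y_ : ndarray
        Training abscissae (strictly increasing) and responses.
    fitted_values_ : ndarray
        The smooth evaluated at the training abscissae.

    Notes
    -----
    Distance ties at the neighborhood boundary are broken by including the
    lower x first; since the tricube weight vanishes at ``dist_max``, tie
    handling cannot change the fitted values.
    """

    def __init__(self, span: float = 0.5, degree: int = 2):
        self.span = span
        self.degree = degree

    def _validate(self, x: np.ndarray) -> int:
        if not 0.0 < self.span <= 1.0:
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (0, 1, 2):
            raise ValueError(f"degree must be 0, 1 or 2, got {self.degree}")
        n = len(x)
        q = math.ceil(self.span * n)
        if n < self.degree + 1 or q < self.degree + 1:
            raise UnderdeterminedFitError(
                f"neighborhood of {q} point(s) cannot determine a degree-"
                f"{self.degree} polynomial (need >= {self.degree + 1})")
        return q

    def fit(self, X, y) -> "LoessSmoother":
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if len(x) >= 2 and not np.all(np.diff(x) > 0):
            raise ValueError("x must be strictly increasing")
        self._validate(x)
        self.x_ = x
        self.y_ = y
        self.fitted_values_ = self.predict(x)
        return self

    def _local_fit(self, x0: float, q: int) -> float:
        dist = np.abs(self.x_ - x0)
        # stable sort on (distance, x): ties include the lower x first
        order = np.lexsort((self.x_, dist))[:q]
        dmax = dist[order[-1]]
        if dmax == 0.0:
            return float(np.mean(self.y_[order]))
        w = _tricube(dist[order], dmax)
        pos = w > 0
        # the tricube weight vanishes at dist_max, so a minimal neighborhood
        # can carry fewer than degree+1 effective points; degrade the local
        # degree rather than fail (the fit is still well defined)
        deg = min(self.degree, int(pos.sum()) - 1)
        if deg < 0:
            raise UnderdeterminedFitError(
                f"no point carries weight at x={x0}")
        # centre at x0 for conditioning; the fitted value is the constant term
        xc = self.x_[order][pos] - x0
        coeffs = np.polynomial.polynomial.polyfit(
            xc, self.y_[order][pos], deg=deg, w=np.sqrt(w[pos]))
        return float(coeffs[0])

    def predict(self, X) -> np.ndarray:
        xq = np.asarray(X, dtype=float).ravel()
        q = self._validate(self.x_)
        lo, hi = self.x_[0], self.x_[-1]
        if np.any(xq < lo) or np.any(xq > hi):
            raise ValueError(
                "query points outside the observed range; extrapolation is "
                "not supported")
        return np.array([self._local_fit(float(x0), q) for x0 in xq])


def loess_fit(x: Sequence[float], y: Sequence[float], span: float = 0.5,
              degree: int = 2, label: str = "") -> SmoothCurve:
    """Fit a LOESS smooth and return raw plus smoothed values."""
    sm = LoessSmoother(span=span, degree=degree).fit(x, y)
    return SmoothCurve(
        x=sm.x_, y_raw=sm.y_, y_smooth=sm.fitted_values_, span=span,
        degree=degree, label=label,
        metadata={"family": "gaussian", "robustness_iterations": 0,
                  "span": span, "degree": degree},
    )


def smooth_curve(curve: SurvivalCurve, span: float = 0.5, degree: int = 2,
                 smooth_ci: bool = True) -> SmoothCurve:
    """Smooth a conditional-survival curve for plotting.

    Curves with fewer than four points are returned unsmoothed with a
    warning.  CI bounds, when smoothed, use the same settings and are for
    plotting only — they are never exported as statistics.
    """
    x = curve.days.astype(float)
    if len(curve) < 4:
        warnings.warn(
            f"curve '{curve.label}' has {len(curve)} point(s); returned "
            "unsmoothed", UserWarning, stacklevel=2)
        return SmoothCurve(
            x=x, y_raw=curve.cs.copy(), y_smooth=curve.cs.copy(), span=span,
            degree=degree,
            ci_lower_smooth=curve.ci_lower.copy() if smooth_ci else None,
            ci_upper_smooth=curve.ci_upper.copy() if smooth_ci else None,
            label=curve.label,
            metadata={"family": "gaussian", "robustness_iterations": 0,
                      "span": span, "degree": degree, "smoothed": False},
        )
    sm = LoessSmoother(span=span, degree=degree).fit(x, curve.cs)
    out = SmoothCurve(
        x=x, y_raw=curve.cs.copy(), y_smooth=sm.fitted_values_, span=span,
        degree=degree, label=curve.label,
        metadata={"family": "gaussian", "robustness_iterations": 0,
                  "span": span, "degree": degree, "smoothed": True},
    )
    if smooth_ci:
        out.ci_lower_smooth = LoessSmoother(span=span, degree=degree).fit(
            x, curve.ci_lower).fitted_values_
        out.ci_upper_smooth = LoessSmoother(span=span, degree=degree).fit(
            x, curve.ci_upper).fitted_values_
    return out
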