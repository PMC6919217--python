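"""Per-day conditional survival with Agresti-Coull intervals.

Conditional survival at integer day ``d`` is the proportion of admissions
surviving to *hospital* discharge among those whose ICU length of stay is at
least ``d`` days (the day-``d`` at-risk set).  Day 0 therefore includes every
admission and equals the overall hospital survival proportion.  Because
discharge status is known for every admission there is no censoring, so the
statistic is a plain binomial proportion per day and needs no Kaplan-Meier
machinery.

The curve is reported from day 0 up to (and excluding) the first day on
which fewer than ``min_at_risk`` admissions remain at risk — the same
truncation rule the source analyses use (default 50) to bound confidence
interval width.  Intervals use the Agresti-Coull adjustment: with
``z`` the exact standard-normal quantile at ``(1 + conf) / 2``,

    n~ = n + z**2
    p~ = (x + z**2 / 2) / n~
    bounds = p~ -+ z * sqrt(p~ (1 - p~) / n~), clipped to [0, 1].

The reported point estimate remains the raw proportion ``x / n``; only the
interval is centred at ``p~``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import EmptyCurveError, UndefinedIntervalError

__all__ = [
    "BinomialInterval",
    "SurvivalCurve",
    "ConditionalSurvival",
    "agresti_coull_interval",
    "at_risk_counts",
    "estimate_conditional_survival",
    "stratify_by_age",
]


@dataclasses.dataclass(frozen=True)
class BinomialInterval:
    """An Agresti-Coull confidence interval for a binomial proportion."""

    x: int
    n: int
    conf: float
    p_tilde: float
    lower: float
    upper: float


def agresti_coull_interval(x: int, n: int, conf: float = 0.95) -> BinomialInterval:
    """Agresti-Coull interval for ``x`` successes in ``n`` trials.

    Uses the exact normal quantile (not the z = 2 shortcut).  Bounds are
    clipped to [0, 1].

    Raises
    ------
    UndefinedIntervalError
        if ``n == 0``.
    """
    if n < 1:
        raise UndefinedIntervalError("binomial interval undefined for n = 0 trials")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {conf}")
    z = float(stats.norm.ppf((1.0 + conf) / 2.0))
    n_tilde = n + z * z
    p_tilde = (x + z * z / 2.0) / n_tilde
    half = z * np.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return BinomialInterval(
        x=int(x), n=int(n), conf=conf, p_tilde=float(p_tilde),
        lower=float(max(0.0, p_tilde - half)),
        upper=float(min(1.0, p_tilde + half)),
    )


def _los_array(cohort) -> np.ndarray:
    if isinstance(cohort, pd.DataFrame):
        return cohort["icu_los_days"].to_numpy(dtype=float)
    return np.asarray(cohort, dtype=float)


def at_risk_counts(cohort, max_day: int | None = None) -> list[tuple[int, int]]:
    """Number of admissions at risk on each integer day.

    An admission is at risk on day ``d`` iff its ICU length of stay is at
    least ``d`` days, so day 0 counts every admission.  Enumeration stops at
    the first day with zero at risk (exclusive) or at ``max_day`` (inclusive).
    """
    los = _los_array(cohort)
    out: list[tuple[int, int]] = []
    d = 0
    while True:
        n = int((los >= d).sum())
        out.append((d, n))
        if n == 0 or (max_day is not None and d >= max_day):
            break
        d += 1
    return out


@dataclasses.dataclass
class SurvivalCurve:
    """A fitted conditional-survival curve: one row per reported day."""

    days: np.ndarray
    n_at_risk: np.ndarray
    n_survivors: np.ndarray
    cs: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    min_at_risk: int = 50
    conf: float = 0.95
    label: str = ""

    def __len__(self) -> int:
        return len(self.days)

    @property
    def empty(self) -> bool:
        return len(self.days) == 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "day": self.days.astype(int),
            "n_at_risk": self.n_at_risk.astype(int),
            "n_survivors": self.n_survivors.astype(int),
            "cs": self.cs,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        })
        df["label"] = self.label
        return df

    def to_csv(self, path: str | Path) -> None:
        """Export with proportions at 6 decimals."""
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def empty_curve(cls, min_at_risk: int = 50, conf: float = 0.95,
                    label: str = "") -> "SurvivalCurve":
        z = np.empty(0)
        return cls(days=z.astype(int), n_at_risk=z.astype(int),
                   n_survivors=z.astype(int), cs=z.copy(), ci_lower=z.copy(),
                   ci_upper=z.copy(), min_at_risk=min_at_risk, conf=conf,
                   label=label)


class ConditionalSurvival(BaseEstimator):
    """Estimator for the day-indexed conditional-survival curve.

    Parameters
    ----------
    min_at_risk : int, default 50
        Truncation threshold: the curve stops at the first day on which
        fewer than this many admissions remain at risk.
    conf : float, default 0.95
        Confidence level of the Agresti-Coull intervals.

    Attributes
    ----------
    curve_ : SurvivalCurve
        The fitted curve (days, at-risk counts, proportions, CI bounds).
    days_, cs_, ci_lower_, ci_upper_, n_at_risk_, n_survivors_ : ndarray
        Column views of ``curve_``.

    Examples
    --------
    >>> import pandas as pd
    >>> df = pd.DataFrame({"icu_los_days": [1, 2, 3, 5],
    ...                    "survived_to_discharge": [True, True, False, True]})
    >>> est = ConditionalSurvival(min_at_risk=1).fit(df)
    >>> float(est.cs_[0])
    0.75
    """

    def __init__(self, min_at_risk: int = 50, conf: float = 0.95):
        self.min_at_risk = min_at_risk
        self.conf = conf

    def fit(self, X, y=None, label: str | None = None) -> "ConditionalSurvival":
        """Fit the curve.

        ``X`` is either a cohort DataFrame carrying ``icu_los_days`` and
        ``survived_to_discharge`` columns, or a 1-d array of lengths of
        stay with ``y`` the boolean survival outcomes.
        """
        if self.min_at_risk < 1:
            raise ValueError("min_at_risk must be >= 1")
        if not 0.0 < self.conf < 1.0:
            raise ValueError("conf must be in (0, 1)")
        if isinstance(X, pd.DataFrame):
            los = X["icu_los_days"].to_numpy(dtype=float)
            surv = X["survived_to_discharge"].to_numpy(dtype=bool)
            if label is None:
                label = X.attrs.get("label", "")
        else:
            los = np.asarray(X, dtype=float).ravel()
            if y is None:
                raise ValueError("y (survival outcomes) required with array input")
            surv = np.asarray(y, dtype=bool).ravel()
            if label is None:
                label = ""
        if los.shape != surv.shape:
            raise ValueError("length-of-stay and outcome arrays differ in length")
        if len(los) < self.min_at_risk:
            raise EmptyCurveError(
                f"cohort of {len(los)} records is smaller than min_at_risk="
                f"{self.min_at_risk}; lower the threshold to report any day")

        days, nar, nsurv, cs, lo, up = [], [], [], [], [], []
        d = 0
        while True:
            at_risk = los >= d
            n = int(at_risk.sum())
            if n < self.min_at_risk:
                break
            x = int(surv[at_risk].sum())
            ci = agresti_coull_interval(x, n, self.conf)
            days.append(d)
            nar.append(n)
            nsurv.append(x)
            cs.append(x / n)
            lo.append(ci.lower)
            up.append(ci.upper)
            d += 1

        self.curve_ = SurvivalCurve(
            days=np.array(days, dtype=int),
            n_at_risk=np.array(nar, dtype=int),
            n_survivors=np.array(nsurv, dtype=int),
            cs=np.array(cs, dtype=float),
            ci_lower=np.array(lo, dtype=float),
            ci_upper=np.array(up, dtype=float),
            min_at_risk=self.min_at_risk,
            conf=self.conf,
            label=label,
        )
        self.days_ = self.curve_.days
        self.n_at_risk_ = self.curve_.n_at_risk
        self.n_survivors_ = self.curve_.n_survivors
        self.cs_ = self.curve_.cs
        self.ci_lower_ = self.curve_.ci_lower
        self.ci_upper_ = self.curve_.ci_upper
        return self


def estimate_conditional_survival(cohort, min_at_risk: int = 50,
                                  conf: float = 0.95,
                                  label: str | None = None) -> SurvivalCurve:
    """Functional wrapper around :class:`ConditionalSurvival`."""
    return ConditionalSurvival(min_at_risk=min_at_risk, conf=conf).fit(
        cohort, label=label).curve_


def stratify_by_age(cohort: pd.DataFrame, cutoff: float = 75.0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort at an age cutoff (inclusive on the older side).

    Returns ``(young, old)`` with ``young`` = age < cutoff and
    ``old`` = age >= cutoff; the partition is exhaustive and disjoint.
    """
    age = cohort["age_years"].to_numpy(dtype=float)
    young = cohort[age < cutoff].reset_index(drop=True).copy()
    old = cohort[age >= cutoff].reset_index(drop=True).copy()
    base = cohort.attrs.get("label", "")
    young.attrs["label"] = f"{base}:under{cutoff:g}" if base else f"under{cutoff:g}"
    old.attrs["label"] = f"{base}:over{cutoff:g}" if base else f"over{cutoff:g}"
    return young, old
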