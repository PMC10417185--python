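"""Survival-curve and life-table calibration.

This module converts the survival information a decision model is built
from — digitized Kaplan–Meier traces, published hazard ratios, and
abridged (5-year-band) life tables — into the monthly transition
probability schedules the cohort engine consumes.

Conventions
-----------
* Time is measured in months; model cycles are half-open intervals
  ``[t, t+1)``.
* A survival curve ``S`` is resampled onto the monthly grid by linear
  interpolation of ``log S`` (exact for exponential survival), and the
  monthly event probability for cycle ``t`` is the discrete hazard
  ``p[t] = 1 - S(t+1) / S(t)``.
* Hazard ratios act on the discrete survival ratio,
  ``p' = 1 - (1 - p)**hr``, the proportional-hazards transform for
  grouped survival data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationError",
    "SurvivalCurve",
    "HazardAdjustment",
    "LifeTable",
    "curve_to_monthly_probs",
    "apply_hazard_ratio",
    "life_table_to_monthly",
]


class CalibrationError(ValueError):
    """Invalid survival curve, hazard ratio, or life table input."""


@dataclass(frozen=True)
class HazardAdjustment:
    """A proportional-hazards adjustment between survival strata.

    The default 1.61 is the published hazard ratio for survival after
    recurrence in patients whose adjuvant treatment was single-agent
    fluoropyrimidine or none, relative to doublet (oxaliplatin-based)
    adjuvant treatment.
    """

    hazard_ratio: float = 1.61

    def __post_init__(self) -> None:
        if not (self.hazard_ratio > 0 and np.isfinite(self.hazard_ratio)):
            raise CalibrationError(
                f"hazard_ratio must be a positive finite number, got {self.hazard_ratio!r}"
            )


@dataclass(frozen=True)
class SurvivalCurve:
    """An ordered survival curve ``(t_i, S(t_i))`` on a monthly time axis.

    Parameters
    ----------
    times
        Strictly increasing times in months; the first point must be
        ``t = 0`` with survival 1.
    survival
        Non-increasing survival fractions in ``[0, 1]``.
    stratum_label
        Free-text label, e.g. the post-recurrence stratum
        (``"doublet"`` vs ``"single_or_none"``).
    """

    times: np.ndarray
    survival: np.ndarray
    stratum_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        if times.ndim != 1 or times.shape != surv.shape or times.size < 2:
            raise CalibrationError("curve needs matching 1-d times/survival with >= 2 points")
        if np.any(np.diff(times) <= 0):
            raise CalibrationError(f"curve times must be strictly increasing ({self.stratum_label!r})")
        if times[0] != 0 or surv[0] != 1.0:
            raise CalibrationError("curve must start at (t=0, S=1)")
        if np.any(surv < 0) or np.any(surv > 1):
            raise CalibrationError("survival values must lie in [0, 1]")
        if np.any(np.diff(surv) > 1e-12):
            raise CalibrationError(f"survival must be non-increasing ({self.stratum_label!r})")

    @property
    def max_time(self) -> float:
        return float(self.times[-1])

    def at(self, time: float | np.ndarray) -> float | np.ndarray:
        """Survival at ``time`` by log-linear interpolation (no extrapolation)."""
        t = np.asarray(time, dtype=float)
        if np.any(t < 0) or np.any(t > self.max_time + 1e-9):
            raise CalibrationError(
                f"time {time} outside curve support [0, {self.max_time}]"
            )
        with np.errstate(divide="ignore"):
            logs = np.log(self.survival)
        out = np.exp(np.interp(t, self.times, logs))
        # exact zeros stay zero (log-interp against -inf)
        return float(out) if np.isscalar(time) else out

    def resample_monthly(self, n_months: int | None = None) -> np.ndarray:
        """Survival at integer months ``0..n`` (default: floor of last time)."""
        if n_months is None:
            n_months = int(np.floor(self.max_time))
        return np.asarray(self.at(np.arange(n_months + 1, dtype=float)))


def curve_to_monthly_probs(curve: SurvivalCurve, n_months: int | None = None) -> np.ndarray:
    """Discrete monthly event probabilities implied by a survival curve.

    ``p[t] = 1 - S(t+1)/S(t)`` for each month ``t`` with ``S(t) > 0``;
    if the curve reaches zero the sequence terminates with probability 1
    at that month.  The curve is first resampled onto the monthly grid by
    log-linear interpolation.
    """
    s = curve.resample_monthly(n_months)
    probs = []
    for t in range(len(s) - 1):
        if s[t] <= 0.0:
            break
        p = 1.0 - s[t + 1] / s[t]
        if s[t + 1] <= 0.0:
            probs.append(1.0)
            break
        probs.append(min(max(p, 0.0), 1.0))
    return np.asarray(probs, dtype=float)


def apply_hazard_ratio(
    probs: np.ndarray, adj: HazardAdjustment | float
) -> np.ndarray:
    """Scale a monthly probability sequence by a hazard ratio.

    Uses the grouped-data proportional-hazards transform
    ``p' = 1 - (1 - p)**hr``, which composes multiplicatively in the
    hazard ratio and preserves ``[0, 1]``.
    """
    hr = adj.hazard_ratio if isinstance(adj, HazardAdjustment) else float(adj)
    if not (hr > 0 and np.isfinite(hr)):
        raise CalibrationError(f"hazard ratio must be positive and finite, got {hr!r}")
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise CalibrationError("probabilities outside [0, 1]")
    if hr == 1.0:
        return p.copy()
    return 1.0 - (1.0 - p) ** hr


@dataclass(frozen=True)
class LifeTable:
    """Abridged life table with contiguous age bands.

    Rows are ``[age_lower, age_upper)`` bands with the annual probability
    of death for a person whose attained age falls in the band.
    """

    age_lower: np.ndarray
    age_upper: np.ndarray
    annual_death_prob: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_lower, dtype=float)
        hi = np.asarray(self.age_upper, dtype=float)
        q = np.asarray(self.annual_death_prob, dtype=float)
        object.__setattr__(self, "age_lower", lo)
        object.__setattr__(self, "age_upper", hi)
        object.__setattr__(self, "annual_death_prob", q)
        if not (lo.shape == hi.shape == q.shape) or lo.ndim != 1 or lo.size == 0:
            raise CalibrationError("life table needs matching 1-d columns")
        if np.any(hi <= lo):
            raise CalibrationError("age_upper must exceed age_lower in every band")
        if np.any(lo[1:] != hi[:-1]):
            raise CalibrationError("life table age bands must be contiguous")
        if np.any(q < 0) or np.any(q > 1):
            raise CalibrationError("annual death probabilities must lie in [0, 1]")
        if np.any(np.diff(q) < 0):
            log.warning("life table annual death probabilities are not monotone in age")

    def annual_q(self, age: float) -> float:
        """Annual death probability for the band containing ``age``."""
        if age < self.age_lower[0] or age >= self.age_upper[-1]:
            raise CalibrationError(
                f"age {age} outside life table coverage "
                f"[{self.age_lower[0]}, {self.age_upper[-1]})"
            )
        idx = int(np.searchsorted(self.age_lower, age, side="right") - 1)
        return float(self.annual_death_prob[idx])


def life_table_to_monthly(
    table: LifeTable, start_age: float, horizon: int
) -> np.ndarray:
    """Monthly background death probabilities indexed by cycle.

    For each cycle the attained age is ``start_age + cycle/12``; the
    band's annual probability ``q`` is converted to a monthly one as
    ``1 - (1 - q)**(1/12)``, so twelve cycles inside one band compound
    back to ``q`` exactly.
    """
    cycles = np.arange(horizon, dtype=float)
    ages = start_age + cycles / 12.0
    if ages[0] < table.age_lower[0] or ages[-1] >= table.age_upper[-1]:
        raise CalibrationError(
            f"ages [{ages[0]}, {ages[-1]}] not covered by life table "
            f"[{table.age_lower[0]}, {table.age_upper[-1]})"
        )
    idx = np.searchsorted(table.age_lower, ages, side="right") - 1
    annual_q = table.annual_death_prob[idx]
    return 1.0 - (1.0 - annual_q) ** (1.0 / 12.0)
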