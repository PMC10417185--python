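"""Discrete-time Markov cohort engine.

Simulates a cohort of post-resection colon cancer patients over monthly
cycles through the states DISEASE_FREE, RECURRENCE (split into a
curative-intent hepatectomy pathway and first-/second-line palliative
chemotherapy pathways, each a tunnel indexed by months since
recurrence), DEAD_CC (death from colon cancer) and DEAD_OTHER
(background death).

Within-cycle competing-risk convention
--------------------------------------
From DISEASE_FREE, background death is applied first, then recurrence to
the survivors, so ``P(recurrence this cycle) = (1 - p_death_other) *
p_recur``.  In the recurrence tunnels, background death is likewise
applied before cancer death.  This ordering is used consistently here
and in the micro-simulation test oracle, and it makes the disease-free
survival round trip against the calibration curve exact.

Half-cycle correction
---------------------
State-time for cycle ``t`` is credited trapezoidally as the mean of the
occupancies at the cycle's two boundaries.  One-time transition events
(recurrence entry, line entry, deaths) are counted as within-cycle
flows and are not half-cycle corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STATE_COLUMNS",
    "EngineError",
    "ModelSettings",
    "RecurrencePathway",
    "TransitionScheduleSet",
    "CohortTrace",
    "run_cohort",
    "overall_survival_years",
    "validate_dfs",
]

#: Aggregate state columns of the cohort trace, in order.
STATE_COLUMNS = (
    "DISEASE_FREE",
    "REC_HEPATECTOMY",
    "REC_FIRST_LINE",
    "REC_SECOND_LINE",
    "DEAD_CC",
    "DEAD_OTHER",
)

DISEASE_FREE, REC_HEP, REC_1L, REC_2L, DEAD_CC, DEAD_OTHER = range(6)

#: Per-cycle event flow keys recorded by the engine.
FLOW_KEYS = (
    "recurrence",
    "hepatectomy",
    "first_line",
    "second_line",
    "dead_cc",
    "dead_other",
)


class EngineError(ValueError):
    """Invalid engine settings or transition schedules."""


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings.

    The horizon is ``min(300, 12 * (max_age - start_age))`` cycles of one
    month: the model runs for 25 years or until the cohort reaches the
    maximum age, whichever comes first.
    """

    start_age: int = 60
    max_age: int = 85
    annual_discount_rate: float = 0.05
    cycle_length_months: int = 1

    def __post_init__(self) -> None:
        if not (40 <= self.start_age <= 80):
            raise EngineError(f"start_age must be in [40, 80], got {self.start_age}")
        if self.max_age <= self.start_age:
            raise EngineError("max_age must exceed start_age")
        if not (0.0 <= self.annual_discount_rate <= 0.10):
            raise EngineError(
                f"annual_discount_rate must be in [0, 0.10], got {self.annual_discount_rate}"
            )
        if self.cycle_length_months != 1:
            raise EngineError("cycle length is fixed at 1 month")

    @property
    def horizon(self) -> int:
        """Number of monthly cycles simulated."""
        return min(300, 12 * (self.max_age - self.start_age))


@dataclass(frozen=True)
class RecurrencePathway:
    """How newly recurrent patients are allocated to treatment pathways.

    One third of recurrences are liver-only, and one third of liver-only
    recurrences undergo curative-intent hepatectomy; everyone else
    enters first-line palliative chemotherapy and may move to a second
    (final) line after ``first_line_duration_months``.
    """

    frac_liver_only: float = 1.0 / 3.0
    frac_hepatectomy_given_liver_only: float = 1.0 / 3.0
    max_treatment_lines: int = 2
    first_line_duration_months: int = 8

    def __post_init__(self) -> None:
        for name in ("frac_liver_only", "frac_hepatectomy_given_liver_only"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise EngineError(f"{name} must be in [0, 1], got {v}")
        if self.max_treatment_lines != 2:
            raise EngineError("the treatment pathway supports exactly two chemotherapy lines")
        if self.first_line_duration_months < 1:
            raise EngineError("first_line_duration_months must be >= 1")

    @property
    def frac_hepatectomy(self) -> float:
        """Joint fraction of recurrences managed by hepatectomy."""
        return self.frac_liver_only * self.frac_hepatectomy_given_liver_only


def _check_probs(name: str, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise EngineError(f"{name} must be a 1-d sequence")
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise EngineError(f"{name} contains probabilities outside [0, 1]")
    return p


@dataclass(frozen=True)
class TransitionScheduleSet:
    """Monthly transition probabilities for one strategy.

    ``p_recur`` is indexed by cycle since model start and is treated as
    zero beyond its defined support (the recurrence risk is assumed
    exhausted once the source curve plateaus).  ``p_death_cc`` is
    indexed by months since recurrence and ``p_death_other`` by cycle
    (attained age); both must cover the horizon.
    """

    p_recur: np.ndarray
    p_death_cc: np.ndarray
    p_death_other: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_recur", _check_probs("p_recur", self.p_recur))
        object.__setattr__(self, "p_death_cc", _check_probs("p_death_cc", self.p_death_cc))
        object.__setattr__(
            self, "p_death_other", _check_probs("p_death_other", self.p_death_other)
        )

    def require_horizon(self, horizon: int) -> None:
        """Raise a named error if a death schedule cannot cover ``horizon``."""
        for name in ("p_death_cc", "p_death_other"):
            seq = getattr(self, name)
            if seq.size < horizon:
                raise EngineError(
                    f"schedule {name} is shorter than the horizon: "
                    f"{seq.size} < {horizon} (deficit {horizon - seq.size} cycles)"
                )

    def recur_at(self, horizon: int) -> np.ndarray:
        """Recurrence schedule zero-extended to ``horizon`` cycles."""
        out = np.zeros(horizon, dtype=float)
        n = min(horizon, self.p_recur.size)
        out[:n] = self.p_recur[:n]
        return out


@dataclass
class CohortTrace:
    """Engine output: state occupancy, half-cycle state-time and flows.

    Attributes
    ----------
    occupancy
        ``(horizon + 1, 6)`` state-occupancy fractions at cycle
        boundaries, columns per :data:`STATE_COLUMNS`.
    half_cycle_occupancy
        ``(horizon, 6)`` trapezoidal state-time per cycle.
    event_flows
        Per-cycle fractions newly experiencing each event
        (keys per :data:`FLOW_KEYS`).
    df_background_survival
        ``(horizon + 1,)`` cumulative probability of surviving
        background mortality along the disease-free path,
        ``prod(1 - p_death_other)``; this is the denominator that
        removes model-added background mortality when comparing model
        disease-free survival against a trial calibration curve.
    """

    occupancy: np.ndarray
    half_cycle_occupancy: np.ndarray
    event_flows: dict[str, np.ndarray]
    df_background_survival: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def state(self, name: str, half_cycle: bool = False) -> np.ndarray:
        col = STATE_COLUMNS.index(name)
        return (self.half_cycle_occupancy if half_cycle else self.occupancy)[:, col]

    def alive(self, half_cycle: bool = False) -> np.ndarray:
        """Fraction alive (disease-free + recurrence) per row."""
        arr = self.half_cycle_occupancy if half_cycle else self.occupancy
        return arr[:, : DEAD_CC].sum(axis=1)

    def recurrent(self, half_cycle: bool = True) -> np.ndarray:
        arr = self.half_cycle_occupancy if half_cycle else self.occupancy
        return arr[:, REC_HEP : DEAD_CC].sum(axis=1)

    def validate(self, atol: float = 1e-9) -> None:
        occ = self.occupancy
        if np.any(occ < -atol) or np.any(occ > 1 + atol):
            raise EngineError("occupancy outside [0, 1]")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > atol:
            raise EngineError("occupancy rows do not sum to 1")
        for col in (DEAD_CC, DEAD_OTHER):
            if np.any(np.diff(occ[:, col]) < -atol):
                raise EngineError("absorbing state occupancy decreased")


def run_cohort(
    settings: ModelSettings,
    schedules: TransitionScheduleSet,
    pathway: RecurrencePathway | None = None,
) -> CohortTrace:
    """Run the cohort simulation for one strategy.

    The whole cohort starts disease-free.  Each cycle, background death
    is applied first; surviving disease-free patients may recur and are
    split across pathways at entry (hepatectomy vs first line);
    recurrence tunnels advance by one month per cycle so the
    post-recurrence death schedule is indexed by months since
    recurrence; first-line patients surviving
    ``pathway.first_line_duration_months`` months move to second line.
    """
    pathway = pathway or RecurrencePathway()
    horizon = settings.horizon
    schedules.require_horizon(horizon)

    p_recur = schedules.recur_at(horizon)
    p_do = schedules.p_death_other
    p_dcc = schedules.p_death_cc[: horizon + 1]
    if p_dcc.size < horizon + 1:  # tunnel index can reach horizon - 1
        p_dcc = np.concatenate([p_dcc, np.full(horizon + 1 - p_dcc.size, p_dcc[-1])])

    f_hep = pathway.frac_hepatectomy
    line_switch = pathway.first_line_duration_months

    occ = np.zeros((horizon + 1, 6))
    occ[0, DISEASE_FREE] = 1.0
    flows = {k: np.zeros(horizon) for k in FLOW_KEYS}
    bg_surv = np.ones(horizon + 1)

    df = 1.0
    # tunnels indexed by months since recurrence (0..horizon)
    tun = {REC_HEP: np.zeros(horizon + 1), REC_1L: np.zeros(horizon + 1), REC_2L: np.zeros(horizon + 1)}
    dead_cc = 0.0
    dead_other = 0.0

    for t in range(horizon):
        pdo = p_do[t]
        # disease-free: background death first, then recurrence
        df_deaths = df * pdo
        df_surv = df - df_deaths
        new_rec = df_surv * p_recur[t]
        df_next = df_surv - new_rec
        bg_surv[t + 1] = bg_surv[t] * (1.0 - pdo)

        cyc_dead_other = df_deaths
        cyc_dead_cc = 0.0
        tun_next = {}
        for key, arr in tun.items():
            do_deaths = arr * pdo
            after_do = arr - do_deaths
            cc_deaths = after_do * p_dcc[: arr.size]
            survivors = after_do - cc_deaths
            cyc_dead_other += do_deaths.sum()
            cyc_dead_cc += cc_deaths.sum()
            nxt = np.zeros_like(arr)
            nxt[1:] = survivors[:-1]  # tunnel advances one month
            tun_next[key] = nxt

        # pathway allocation at recurrence entry
        tun_next[REC_HEP][0] += new_rec * f_hep
        tun_next[REC_1L][0] += new_rec * (1.0 - f_hep)

        # first line -> second line after the fixed first-line duration
        moved = tun_next[REC_1L][line_switch] if line_switch <= horizon else 0.0
        if moved:
            tun_next[REC_2L][line_switch] += moved
            tun_next[REC_1L][line_switch] = 0.0

        dead_cc += cyc_dead_cc
        dead_other += cyc_dead_other
        df = df_next
        tun = tun_next

        flows["recurrence"][t] = new_rec
        flows["hepatectomy"][t] = new_rec * f_hep
        flows["first_line"][t] = new_rec * (1.0 - f_hep)
        flows["second_line"][t] = moved
        flows["dead_cc"][t] = cyc_dead_cc
        flows["dead_other"][t] = cyc_dead_other

        occ[t + 1, DISEASE_FREE] = df
        occ[t + 1, REC_HEP] = tun[REC_HEP].sum()
        occ[t + 1, REC_1L] = tun[REC_1L].sum()
        occ[t + 1, REC_2L] = tun[REC_2L].sum()
        occ[t + 1, DEAD_CC] = dead_cc
        occ[t + 1, DEAD_OTHER] = dead_other

    half = 0.5 * (occ[:-1] + occ[1:])
    trace = CohortTrace(
        occupancy=occ,
        half_cycle_occupancy=half,
        event_flows=flows,
        df_background_survival=bg_surv,
    )
    trace.validate()
    return trace


def overall_survival_years(trace: CohortTrace) -> float:
    """Undiscounted, disability-unadjusted life years per patient.

    Half-cycle-corrected time spent alive (disease-free or recurrent),
    divided by 12.
    """
    return float(trace.alive(half_cycle=True).sum() / 12.0)


def validate_dfs(trace: CohortTrace, calibration_curve) -> float:
    """Relative error of model 5-year disease-free survival vs its source curve.

    Model DFS at 60 months is the DISEASE_FREE occupancy divided by the
    cumulative background survival along the disease-free path, which
    removes the background mortality the model adds on top of the trial
    curve.  Returns ``|model - curve| / curve`` at month 60.  Raises if
    either the trace horizon or the curve does not reach 60 months.
    """
    month = 60
    if trace.horizon < month:
        raise EngineError(f"trace horizon {trace.horizon} does not reach {month} months")
    if calibration_curve.max_time < month:
        raise EngineError(
            f"calibration curve ends at {calibration_curve.max_time} months; "
            f"no {month}-month value (extrapolation refused)"
        )
    curve_dfs = float(calibration_curve.at(month))
    if curve_dfs <= 0:
        raise EngineError("calibration curve survival is zero at 60 months")
    model_dfs = trace.occupancy[month, DISEASE_FREE] / trace.df_background_survival[month]
    return abs(model_dfs - curve_dfs) / curve_dfs
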