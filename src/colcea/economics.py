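"""Costs, DALYs, net monetary benefit and the cost-effectiveness frontier.

Costs are accounted in 2021 South African rand (ZAR) and converted to
2021 international dollars (I$) with the purchasing-power-parity factor
7.097 ZAR/I$.  Effectiveness is measured in DALYs averted relative to a
comparator strategy (no adjuvant chemotherapy by default).  Costs and
disability are discounted at 5% per year with exact monthly compounding,
``(1 + r) ** (-cycle / 12)``; overall survival is reported undiscounted.

DALY convention
---------------
YLD accrues discounted state-time in the recurrence states at the
annual metastatic-recurrence disability weight, plus adverse-event
disability during and after adjuvant treatment.  YLL accrues
colon-cancer-death state-time at weight 1 up to the model horizon;
background (non-cancer) death accrues nothing.  This within-horizon
weight-1 convention — not the GBD standard-life-expectancy formula —
changes DALY magnitudes and is deliberate: DALYs here count the burden
attributable to colon cancer inside the modelled lifetime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .engine import CohortTrace, ModelSettings, DISEASE_FREE

log = logging.getLogger(__name__)

__all__ = [
    "EconomicsError",
    "EconSettings",
    "SharedCosts",
    "DisabilityWeights",
    "SurveillanceSchedule",
    "Dominance",
    "CEAResult",
    "convert_currency",
    "discount_factors",
    "discounted_costs",
    "compute_dalys",
    "net_monetary_benefit",
    "frontier",
]

PPP_ZAR_PER_INTL_DOLLAR = 7.097

AE_NAMES = (
    "peripheral_neuropathy",
    "diarrhea",
    "febrile_neutropenia",
    "nausea_vomiting",
    "mucositis",
    "hand_foot_syndrome",
)


class EconomicsError(ValueError):
    pass


def convert_currency(zar: float, ppp_factor: float = PPP_ZAR_PER_INTL_DOLLAR,
                     display: bool = False) -> float:
    """Convert 2021 ZAR to 2021 international dollars.

    ``display=True`` rounds half-up to the nearest integer dollar (the
    table convention); internally values stay unrounded.
    """
    if zar < 0:
        raise EconomicsError(f"negative cost {zar!r}")
    value = zar / ppp_factor
    return float(math.floor(value + 0.5)) if display else value


@dataclass(frozen=True)
class EconSettings:
    """Willingness-to-pay and currency settings.

    The base willingness-to-pay of I$13,764 per DALY averted is the 2021
    South African GDP per capita.
    """

    wtp_per_daly: float = 13_764.0
    ppp_factor: float = PPP_ZAR_PER_INTL_DOLLAR
    comparator: str = "no_adjuvant"

    def __post_init__(self) -> None:
        if self.wtp_per_daly <= 0 or self.ppp_factor <= 0:
            raise EconomicsError("wtp_per_daly and ppp_factor must be positive")


@dataclass
class SharedCosts:
    """Costs common to all strategies, in 2021 ZAR.

    Indirect (societal-perspective) costs are per person-day;
    surveillance CT counts one person-day (patient only) while
    colonoscopy and treatment visits count two (patient plus caregiver).
    """

    hepatectomy_zar: float = 58_329.0
    bloodwork_zar: float = 43.0
    ct_scan_zar: float = 2_260.0
    colonoscopy_zar: float = 2_233.0
    ae_event_zar: dict[str, float] = field(default_factory=lambda: {
        "peripheral_neuropathy": 51.0,
        "diarrhea": 7_485.0,
        "febrile_neutropenia": 17_425.0,
        "nausea_vomiting": 7_877.0,
        "mucositis": 7_924.0,
        "hand_foot_syndrome": 7_928.0,
    })
    residual_neuropathy_annual_zar: float = 206.0
    residual_neuropathy_months: int = 36
    transport_per_day_zar: float = 41.0
    lost_wages_per_day_zar: float = 138.0

    def __post_init__(self) -> None:
        numeric = [self.hepatectomy_zar, self.bloodwork_zar, self.ct_scan_zar,
                   self.colonoscopy_zar, self.residual_neuropathy_annual_zar,
                   self.transport_per_day_zar, self.lost_wages_per_day_zar,
                   *self.ae_event_zar.values()]
        if any(v < 0 for v in numeric):
            raise EconomicsError("costs must be non-negative")

    @property
    def indirect_per_person_day_zar(self) -> float:
        return self.transport_per_day_zar + self.lost_wages_per_day_zar


@dataclass
class DisabilityWeights:
    """Annual disability weights for health states and adverse events."""

    disease_free: float = 0.0
    recurrence: float = 0.451
    cc_death: float = 1.0
    ae: dict[str, float] = field(default_factory=lambda: {
        "peripheral_neuropathy": 0.133,
        "diarrhea": 0.247,
        "febrile_neutropenia": 0.133,
        "nausea_vomiting": 0.114,
        "mucositis": 0.051,
        "hand_foot_syndrome": 0.133,
    })
    residual_neuropathy: float = 0.133

    def __post_init__(self) -> None:
        vals = [self.disease_free, self.recurrence, self.cc_death,
                self.residual_neuropathy, *self.ae.values()]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise EconomicsError("disability weights must lie in [0, 1]")


@dataclass
class SurveillanceSchedule:
    """Post-resection surveillance calendar: item -> visit months.

    The default reflects a standard 5-year surveillance program:
    blood work every 3 months in years 1-2 and every 6 months in years
    3-5, annual CT for 5 years, colonoscopy at years 1 and 4.
    """

    visits: dict[str, tuple[int, ...]] = field(default_factory=lambda: {
        "bloodwork": tuple(range(3, 25, 3)) + tuple(range(30, 61, 6)),
        "ct_scan": (12, 24, 36, 48, 60),
        "colonoscopy": (12, 48),
    })


def discount_factors(horizon: int, annual_rate: float) -> np.ndarray:
    """Per-cycle discount factors ``(1 + r) ** (-t / 12)`` for ``t = 0..horizon-1``."""
    t = np.arange(horizon, dtype=float)
    return (1.0 + annual_rate) ** (-t / 12.0)


def _treatment_months(strategy) -> int:
    return int(strategy.adjuvant_months)


def discounted_costs(trace: CohortTrace, strategy, costs: SharedCosts,
                     surveillance: SurveillanceSchedule,
                     settings: ModelSettings,
                     ppp_factor: float = PPP_ZAR_PER_INTL_DOLLAR) -> float:
    """Total discounted societal cost of one strategy, in I$ per patient.

    One-time costs attach to event flows (metastatic course at line
    entry, hepatectomy at entry, adverse events at incidence during the
    adjuvant months); the adjuvant course is spread uniformly over its
    treatment months; surveillance items follow the visit calendar for
    disease-free patients; the residual-neuropathy annuity runs monthly
    for three years after treatment ends; indirect costs apply per
    visit-day.  Every component is multiplied by the per-cycle discount
    factor and summed.
    """
    horizon = trace.horizon
    disc = discount_factors(horizon, settings.annual_discount_rate)
    flows = trace.event_flows
    df_half = trace.state("DISEASE_FREE", half_cycle=True)
    indirect = costs.indirect_per_person_day_zar

    total = 0.0  # ZAR

    # adjuvant course spread over treatment months, paid by patients on treatment
    months = _treatment_months(strategy)
    if months > 0:
        per_month = strategy.adjuvant_cost_zar / months
        on_tx = df_half[:months]
        total += float((per_month * on_tx * disc[:months]).sum())
        # one treatment visit-day per month, patient + caregiver
        total += float((2 * indirect * on_tx * disc[:months]).sum())
        # adverse events during treatment, spread uniformly over the course
        for name, incidence in strategy.ae_incidence.items():
            if name not in costs.ae_event_zar:
                raise EconomicsError(f"no cost row for adverse event {name!r}")
            events = on_tx * (incidence / months)
            total += float((costs.ae_event_zar[name] * events * disc[:months]).sum())
        # residual neuropathy annuity, 3 years after the course ends
        carriers = strategy.residual_neuropathy_incidence * trace.occupancy[months, DISEASE_FREE]
        end = min(months + costs.residual_neuropathy_months, horizon)
        monthly = costs.residual_neuropathy_annual_zar / 12.0
        total += float(carriers * monthly * disc[months:end].sum())

    # metastatic treatment courses at line entry (one-time, with visit-days)
    fl_cost = strategy.first_line_cost_zar + 2 * indirect * strategy.first_line_visit_days
    sl_cost = strategy.second_line_cost_zar + 2 * indirect * strategy.second_line_visit_days
    total += float((flows["first_line"] * fl_cost * disc).sum())
    total += float((flows["second_line"] * sl_cost * disc).sum())
    total += float((flows["hepatectomy"] * costs.hepatectomy_zar * disc).sum())

    # surveillance while disease-free
    item_costs = {
        "bloodwork": (costs.bloodwork_zar, 0),
        "ct_scan": (costs.ct_scan_zar, 1),       # patient only
        "colonoscopy": (costs.colonoscopy_zar, 2),  # patient + caregiver
    }
    for item, visit_months in surveillance.visits.items():
        if item not in item_costs:
            raise EconomicsError(f"no cost row for surveillance item {item!r}")
        unit, person_days = item_costs[item]
        for m in visit_months:
            if m < horizon:
                total += (unit + person_days * indirect) * df_half[m] * disc[m]

    return total / ppp_factor


def compute_dalys(trace: CohortTrace, strategy, weights: DisabilityWeights,
                  settings: ModelSettings) -> tuple[float, float, float]:
    """Discounted (YLL, YLD, DALY) for one strategy, per patient.

    YLL: colon-cancer-death state-time at weight 1, accrued within the
    horizon.  YLD: recurrence state-time at the metastatic weight, plus
    adverse-event disability (one month per event) during adjuvant
    treatment and the residual-neuropathy weight for three years after.
    No age weighting is applied.
    """
    horizon = trace.horizon
    disc = discount_factors(horizon, settings.annual_discount_rate)

    yll = float((trace.state("DEAD_CC", half_cycle=True) * weights.cc_death / 12.0 * disc).sum())

    yld = float((trace.recurrent() * weights.recurrence / 12.0 * disc).sum())
    months = _treatment_months(strategy)
    if months > 0:
        df_half = trace.state("DISEASE_FREE", half_cycle=True)
        on_tx = df_half[:months]
        for name, incidence in strategy.ae_incidence.items():
            w = weights.ae[name]
            events = on_tx * (incidence / months)
            yld += float((events * w / 12.0 * disc[:months]).sum())  # one month per event
        carriers = strategy.residual_neuropathy_incidence * trace.occupancy[months, DISEASE_FREE]
        end = min(months + 36, horizon)
        yld += float(carriers * weights.residual_neuropathy / 12.0 * disc[months:end].sum())

    return yll, yld, yll + yld


def net_monetary_benefit(cost: float, dalys_averted: float, wtp: float) -> float:
    """``NMB = WTP * effectiveness - cost`` (I$)."""
    return wtp * dalys_averted - cost


class Dominance(str, Enum):
    REFERENCE = "REFERENCE"
    UNDOMINATED = "UNDOMINATED"
    DOMINATED = "DOMINATED"
    EXTENDED_DOMINATED = "EXTENDED_DOMINATED"


@dataclass
class CEAResult:
    """Per-strategy cost-effectiveness summary (one Table-style row)."""

    strategy: str
    total_cost: float          # I$, discounted
    dalys_averted: float       # vs comparator, discounted
    nmb: float                 # I$
    dominance: Dominance
    icer: float | None = None  # I$/DALY averted vs next-less-costly retained strategy
    os_years: float | None = None
    dalys: float | None = None
    total_cost_zar: float | None = None
    recommended: bool = False


def frontier(results: list[tuple[str, float, float]], wtp: float,
             recompute_after_extended: bool = False) -> list[CEAResult]:
    """Classify strategies on the cost-effectiveness frontier.

    Strategies are sorted by ascending cost (ties broken toward higher
    effectiveness, logged).  Strictly dominated strategies (costlier and
    no more effective than another) are marked and excluded; sequential
    ICERs are computed between each remaining strategy and the
    next-less-costly remaining one; a strategy whose sequential ICER
    exceeds that of the next-costlier remaining strategy is marked
    extended-dominated.  By default the reported ICERs are the ones
    computed *before* extended-dominance removal (the convention of the
    source cost-effectiveness tables); pass
    ``recompute_after_extended=True`` for the textbook convention that
    re-computes ICERs on the final frontier.

    The recommended strategy is the costliest retained one whose ICER is
    at or below the willingness-to-pay (the cheapest, reference,
    strategy if none qualifies); this always coincides with maximising
    net monetary benefit.
    """
    if not results:
        raise EconomicsError("frontier needs at least one strategy")
    entries = sorted(results, key=lambda r: (r[1], -r[2]))
    for a, b in zip(entries, entries[1:]):
        if a[1] == b[1]:
            log.info("tied costs for %s and %s; tie broken by effectiveness", a[0], b[0])

    out = {name: CEAResult(strategy=name, total_cost=cost, dalys_averted=eff,
                           nmb=net_monetary_benefit(cost, eff, wtp),
                           dominance=Dominance.UNDOMINATED)
           for name, cost, eff in entries}

    # strict dominance: costlier and no more effective than some other strategy
    # (cost ties: the less effective one loses; exact duplicates keep first)
    seen: set[tuple[float, float]] = set()
    for name, cost, eff in entries:
        if (cost, eff) in seen:
            out[name].dominance = Dominance.DOMINATED
            continue
        seen.add((cost, eff))
        for oname, ocost, oeff in entries:
            if oname == name:
                continue
            if (cost > ocost and eff <= oeff) or (cost == ocost and eff < oeff):
                out[name].dominance = Dominance.DOMINATED
                break

    retained = [e for e in entries if out[e[0]].dominance is not Dominance.DOMINATED]
    out[retained[0][0]].dominance = Dominance.REFERENCE
    icers: list[float | None] = [None]
    for (pn, pc, pe), (name, cost, eff) in zip(retained, retained[1:]):
        if eff <= pe:  # cannot happen after strict-dominance filtering
            raise EconomicsError("retained strategies must have increasing effectiveness")
        icers.append((cost - pc) / (eff - pe))

    for i in range(1, len(retained) - 1):
        if icers[i] is not None and icers[i + 1] is not None and icers[i] > icers[i + 1]:
            out[retained[i][0]].dominance = Dominance.EXTENDED_DOMINATED

    if recompute_after_extended:
        final = [e for e in retained
                 if out[e[0]].dominance in (Dominance.REFERENCE, Dominance.UNDOMINATED)]
        icer_map = {final[0][0]: None}
        for (pn, pc, pe), (name, cost, eff) in zip(final, final[1:]):
            icer_map[name] = (cost - pc) / (eff - pe)
        for name, cost, eff in retained:
            out[name].icer = icer_map.get(name)
    else:
        for (name, _, _), icer in zip(retained, icers):
            if out[name].dominance is not Dominance.DOMINATED:
                out[name].icer = icer

    # recommendation: costliest retained strategy whose ICER <= WTP
    best = retained[0][0]
    for name, cost, eff in retained[1:]:
        r = out[name]
        if r.dominance in (Dominance.UNDOMINATED,) and r.icer is not None and r.icer <= wtp:
            best = name
    out[best].recommended = True

    ordered = [out[name] for name, _, _ in entries]
    nmb_best = max(ordered, key=lambda r: r.nmb)
    if nmb_best.strategy != best:
        log.warning("frontier recommendation %s disagrees with NMB maximiser %s",
                    best, nmb_best.strategy)
    return ordered
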