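"""Deterministic, probabilistic, subgroup and scenario sensitivity analyses.

One-way deterministic analyses re-run the model at the bounds of a
parameter's plausible range and report the spread of the comparison
ICER (tornado layout); a bisection finds the multiplier of a base value
at which the ICER crosses the willingness-to-pay.  The probabilistic
analysis draws all parameters jointly per iteration — beta for
probabilities and weights (method of moments, sd = 10% of base), gamma
for costs (sd = 25% of base), classical PERT (shape 4) for disability
weights with printed min/mode/max — runs every strategy
deterministically on each draw, and summarises the NMB-optimal strategy
per willingness-to-pay grid point (cost-effectiveness acceptability
curve).

Time-varying probability schedules are perturbed by a single scalar
hazard multiplier per draw (a beta draw around the schedule's mean
monthly probability, rescaled), keeping each curve's shape coherent
rather than drawing each cycle independently.  Willingness-to-pay and
the discount rate are excluded from the probabilistic draws and handled
via the WTP grid and the deterministic sweeps respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig
from .economics import net_monetary_benefit
from .report import run_base_case

log = logging.getLogger(__name__)

__all__ = [
    "SensitivityError", "DistFamily", "DistributionSpec", "TornadoSpec",
    "PSAConfig", "PSAResult", "sample_parameter", "default_psa_distributions",
    "pair_icer", "one_way_dsa", "tornado", "bisect_crossing",
    "threshold_multiplier", "run_psa",
    "subgroup_model", "scenario_xeliri", "default_tornado_specs",
]


class SensitivityError(ValueError):
    pass


class DistFamily(str, Enum):
    BETA = "BETA"
    GAMMA = "GAMMA"
    PERT = "PERT"
    FIXED = "FIXED"


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling description for one model parameter.

    ``sd_fraction`` applies to BETA (0.10) and GAMMA (0.25);
    PERT uses ``(minimum, maximum)`` with the base value as the mode.
    """

    parameter_path: str
    family: DistFamily
    base_value: float
    sd_fraction: float | None = None
    minimum: float | None = None
    maximum: float | None = None

    def __post_init__(self) -> None:
        if self.family is DistFamily.BETA:
            if not (0.0 <= self.base_value <= 1.0):
                raise SensitivityError(
                    f"{self.parameter_path}: BETA requires a base in [0, 1]"
                )
            sd = (self.sd_fraction or 0.0) * self.base_value
            if sd > 0 and sd * sd >= self.base_value * (1.0 - self.base_value):
                raise SensitivityError(
                    f"{self.parameter_path}: sd {sd:.4g} too large for a beta "
                    f"with mean {self.base_value:.4g}"
                )
        elif self.family is DistFamily.GAMMA:
            if self.base_value < 0:
                raise SensitivityError(f"{self.parameter_path}: GAMMA requires base >= 0")
        elif self.family is DistFamily.PERT:
            if self.minimum is None or self.maximum is None:
                raise SensitivityError(f"{self.parameter_path}: PERT needs min and max")
            if not (self.minimum <= self.base_value <= self.maximum):
                raise SensitivityError(
                    f"{self.parameter_path}: PERT needs min <= mode <= max"
                )


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value for a parameter according to its distribution spec."""
    base = spec.base_value
    if spec.family is DistFamily.FIXED or (spec.family is not DistFamily.PERT
                                           and (spec.sd_fraction or 0.0) == 0.0):
        return base
    if spec.family is DistFamily.BETA:
        if base in (0.0, 1.0):
            return base
        sd = spec.sd_fraction * base
        nu = base * (1.0 - base) / sd**2 - 1.0
        a, b = base * nu, (1.0 - base) * nu
        return float(rng.beta(a, b))
    if spec.family is DistFamily.GAMMA:
        if base == 0.0:
            return 0.0
        sd = spec.sd_fraction * base
        shape = (base / sd) ** 2
        scale = sd**2 / base
        return float(rng.gamma(shape, scale))
    if spec.family is DistFamily.PERT:
        lo, hi, mode = spec.minimum, spec.maximum, base
        if hi == lo:
            return lo
        a = 1.0 + 4.0 * (mode - lo) / (hi - lo)
        b = 1.0 + 4.0 * (hi - mode) / (hi - lo)
        return float(lo + (hi - lo) * rng.beta(a, b))
    raise SensitivityError(f"unknown family {spec.family!r}")


def pert_mean(minimum: float, mode: float, maximum: float) -> float:
    """Classical PERT mean ``(min + 4*mode + max) / 6``."""
    return (minimum + 4.0 * mode + maximum) / 6.0


#: Printed PERT ranges for the annual disability weights.
DISABILITY_PERT_RANGES = {
    "weights.recurrence": (0.307, 0.600),
    "weights.ae.peripheral_neuropathy": (0.089, 0.187),
    "weights.ae.diarrhea": (0.164, 0.348),
    "weights.ae.febrile_neutropenia": (0.088, 0.190),
    "weights.ae.nausea_vomiting": (0.078, 0.159),
    "weights.ae.mucositis": (0.032, 0.074),
    "weights.ae.hand_foot_syndrome": (0.078, 0.159),
}


def default_psa_distributions(config: ModelConfig) -> list[DistributionSpec]:
    """The analysis' standard joint-draw set.

    Probabilities (recurrence, cancer death, background death, adverse
    events) get beta draws with sd 10% of base; costs get gamma draws
    with sd 25% of base; disability weights get PERT draws over their
    printed ranges.  Schedule draws use the schedule's mean monthly
    probability as the beta base and enter the model as hazard
    multipliers.
    """
    specs: list[DistributionSpec] = []
    for name, sched in config.recurrence_schedules.items():
        specs.append(DistributionSpec(f"recurrence_hazard.{name}", DistFamily.BETA,
                                      float(np.mean(sched[sched > 0])), 0.10))
    for stratum, sched in config.death_cc_schedules.items():
        specs.append(DistributionSpec(f"death_cc_hazard.{stratum}", DistFamily.BETA,
                                      float(np.mean(sched)), 0.10))
    specs.append(DistributionSpec("background_hazard", DistFamily.BETA,
                                  float(np.mean(config.life_table.annual_death_prob)), 0.10))
    for name, strat in config.strategies.items():
        if strat.adjuvant_months > 0:
            specs.append(DistributionSpec(f"strategies.{name}.adjuvant_cost_zar",
                                          DistFamily.GAMMA, strat.adjuvant_cost_zar, 0.25))
            for ae, inc in strat.ae_incidence.items():
                specs.append(DistributionSpec(f"strategies.{name}.ae_incidence.{ae}",
                                              DistFamily.BETA, inc, 0.10))
        specs.append(DistributionSpec(f"strategies.{name}.first_line_cost_zar",
                                      DistFamily.GAMMA, strat.first_line_cost_zar, 0.25))
        specs.append(DistributionSpec(f"strategies.{name}.second_line_cost_zar",
                                      DistFamily.GAMMA, strat.second_line_cost_zar, 0.25))
    for path, (lo, hi) in DISABILITY_PERT_RANGES.items():
        specs.append(DistributionSpec(path, DistFamily.PERT, config.get_param(path),
                                      minimum=lo, maximum=hi))
    return specs


# ---------------------------------------------------------------------------
# Deterministic one-way analysis


def pair_icer(config: ModelConfig, comparison: tuple[str, str]) -> float:
    """ICER of ``comparison[0]`` (costlier/more effective) vs ``comparison[1]``."""
    report = run_base_case(config)
    a, b = (report.result(name) for name in comparison)
    d_eff = a.dalys_averted - b.dalys_averted
    if d_eff == 0:
        return float("inf") if a.total_cost > b.total_cost else float("-inf")
    return (a.total_cost - b.total_cost) / d_eff


@dataclass(frozen=True)
class TornadoSpec:
    """One-way range for a parameter: multipliers or absolute bounds."""

    parameter_path: str
    low: float
    high: float
    relative: bool = True  # bounds are multipliers of the base value

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise SensitivityError(f"{self.parameter_path}: low must be < high")

    def bounds(self, base: float) -> tuple[float, float]:
        return (self.low * base, self.high * base) if self.relative else (self.low, self.high)


def one_way_dsa(config: ModelConfig, spec: TornadoSpec,
                comparison: tuple[str, str]) -> tuple[float, float]:
    """Comparison ICER at the low and high bound of one parameter."""
    base = config.get_param(spec.parameter_path)
    lo, hi = spec.bounds(base)
    icer_low = pair_icer(config.with_params({spec.parameter_path: lo}), comparison)
    icer_high = pair_icer(config.with_params({spec.parameter_path: hi}), comparison)
    return icer_low, icer_high


def default_tornado_specs(config: ModelConfig,
                          comparison: tuple[str, str]) -> list[TornadoSpec]:
    """Standard tornado set: costs -50%/+100%, probabilities +/-25%,
    discount rate 0-0.10."""
    a, b = comparison
    specs = [
        TornadoSpec(f"strategies.{a}.adjuvant_cost_zar", 0.5, 2.0),
        TornadoSpec(f"strategies.{b}.adjuvant_cost_zar", 0.5, 2.0),
        TornadoSpec(f"strategies.{a}.first_line_cost_zar", 0.5, 2.0),
        TornadoSpec("recurrence_hazard.all", 0.75, 1.25),
        TornadoSpec("death_cc_hazard.all", 0.75, 1.25),
        TornadoSpec("settings.annual_discount_rate", 0.0, 0.10, relative=False),
    ]
    return specs


def tornado(config: ModelConfig, specs: list[TornadoSpec],
            comparison: tuple[str, str]) -> pd.DataFrame:
    """One-way analysis over many parameters, sorted by ICER spread."""
    rows = []
    for spec in specs:
        lo, hi = one_way_dsa(config, spec, comparison)
        rows.append({"parameter": spec.parameter_path, "icer_low": lo,
                     "icer_high": hi, "spread": abs(hi - lo)})
    return (pd.DataFrame(rows)
            .sort_values("spread", ascending=False, kind="stable")
            .reset_index(drop=True))


def bisect_crossing(gap, lo: float, hi: float, rel_tol: float = 1e-4) -> float | None:
    """Root of ``gap`` in ``[lo, hi]`` by bisection, ``None`` if no sign change."""
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if np.sign(g_lo) == np.sign(g_hi):
        return None
    while (hi - lo) > rel_tol * max(abs(hi), 1.0):
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        if g_mid == 0.0:
            return mid
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def threshold_multiplier(config: ModelConfig, parameter_path: str,
                         comparison: tuple[str, str], wtp: float,
                         bracket: tuple[float, float] = (0.25, 2.5),
                         rel_tol: float = 1e-4) -> float | None:
    """Multiplier of a parameter's base value at which the ICER equals WTP.

    Bisection to relative tolerance 1e-4; returns ``None`` when the ICER
    does not cross the willingness-to-pay inside the bracket (reported,
    not raised).
    """
    base = config.get_param(parameter_path)

    def gap(mult: float) -> float:
        cfg = config.with_params({parameter_path: base * mult})
        return pair_icer(cfg, comparison) - wtp

    result = bisect_crossing(gap, bracket[0], bracket[1], rel_tol)
    if result is None:
        log.info("no ICER/WTP crossing for %s in [%g, %g]",
                 parameter_path, bracket[0], bracket[1])
    return result


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis

#: Willingness-to-pay grid from one half to three times GDP per capita.
DEFAULT_WTP_GRID = tuple(np.linspace(6_882.0, 41_292.0, 21))


@dataclass(frozen=True)
class PSAConfig:
    n_iterations: int = 5_000
    rng_seed: int = 0
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise SensitivityError("n_iterations must be >= 1")
        if list(self.wtp_grid) != sorted(self.wtp_grid):
            raise SensitivityError("wtp_grid must be sorted")


@dataclass
class PSAResult:
    iterations: pd.DataFrame          # iteration, strategy, cost, dalys, dalys_averted
    ceac: pd.DataFrame                # wtp, strategy, probability_optimal
    optimal_share_at_base_wtp: dict[str, float]
    n_rejected: int
    metadata: dict


def run_psa(config: ModelConfig, distributions: list[DistributionSpec],
            psa: PSAConfig) -> PSAResult:
    """Joint-draw probabilistic sensitivity analysis.

    One joint parameter draw per iteration is applied to all strategies
    (shared parameters are sampled once and shared across arms), the
    model runs deterministically, and the NMB-maximal strategy is
    recorded at every willingness-to-pay grid point.  Reproducible under
    a fixed seed via per-iteration child RNG streams.
    """
    strategies = list(config.strategies)
    comparator = config.econ.comparator
    base_wtp = config.econ.wtp_per_daly
    seeds = np.random.SeedSequence(psa.rng_seed).spawn(psa.n_iterations)

    # multiplier paths: convert the sampled probability back to a hazard
    # multiplier around its base so schedules stay coherent
    mult_heads = ("recurrence_hazard", "death_cc_hazard", "background_hazard")

    rows = []
    n_rejected = 0
    wtps = np.asarray(psa.wtp_grid)
    optimal_counts = {w: {s: 0 for s in strategies} for w in psa.wtp_grid}
    base_wtp_counts = {s: 0 for s in strategies}
    n_ok = 0

    for it, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        updates: dict[str, float] = {}
        for spec in distributions:
            value = sample_parameter(spec, rng)
            if spec.parameter_path.split(".", 1)[0] in mult_heads:
                value = value / spec.base_value if spec.base_value else 1.0
            updates[spec.parameter_path] = value
        try:
            cfg = config.with_params(updates)
            report = run_base_case(cfg)
        except ValueError as exc:
            n_rejected += 1
            log.warning("PSA iteration %d rejected: %s", it, exc)
            continue
        n_ok += 1
        costs = np.array([report.result(s).total_cost for s in strategies])
        effs = np.array([report.result(s).dalys_averted for s in strategies])
        for s, c, e in zip(strategies, costs, effs):
            rows.append({"iteration": it, "strategy": s, "cost_intl": c,
                         "dalys": report.result(s).dalys, "dalys_averted": e})
        for w in psa.wtp_grid:
            best = strategies[int(np.argmax(w * effs - costs))]
            optimal_counts[w][best] += 1
        best_base = strategies[int(np.argmax(base_wtp * effs - costs))]
        base_wtp_counts[best_base] += 1

    if n_ok == 0:
        raise SensitivityError("all PSA iterations were rejected")

    ceac_rows = [{"wtp": w, "strategy": s,
                  "probability_optimal": optimal_counts[w][s] / n_ok}
                 for w in psa.wtp_grid for s in strategies]
    metadata = {"seed": psa.rng_seed, "n_iterations": psa.n_iterations,
                "n_rejected": n_rejected, "config_hash": config.content_hash(),
                "base_wtp": base_wtp}
    return PSAResult(
        iterations=pd.DataFrame(rows),
        ceac=pd.DataFrame(ceac_rows),
        optimal_share_at_base_wtp={s: base_wtp_counts[s] / n_ok for s in strategies},
        n_rejected=n_rejected,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Subgroup and scenario re-parameterisations


def subgroup_model(base_config: ModelConfig,
                   subgroup: str,
                   recurrence_multipliers: dict[str, float]) -> ModelConfig:
    """Config with recurrence hazards scaled per strategy for a subgroup.

    Multipliers act through the proportional-hazards transform on each
    strategy's monthly recurrence schedule; everything else is shared
    with the base configuration.
    """
    for name, m in recurrence_multipliers.items():
        if m <= 0:
            raise SensitivityError(f"multiplier for {name!r} must be positive")
        if name != "all" and name not in base_config.strategies:
            raise SensitivityError(f"unknown strategy {name!r} in subgroup {subgroup!r}")
    updates = {f"recurrence_hazard.{name}": m for name, m in recurrence_multipliers.items()}
    return base_config.with_params(updates)


def scenario_xeliri(base_config: ModelConfig,
                    xeliri_cost_zar: float | None = None) -> ModelConfig:
    """All-capecitabine metastatic scenario.

    Every metastatic line using FOLFIRI is swapped to XELIRI
    (capecitabine + irinotecan) at the XELIRI course cost; survival
    schedules are unchanged (the regimens are treated as equivalent in
    effectiveness).  Raises if a swap is needed but no XELIRI cost is
    known; returns an identical config when no line uses FOLFIRI.
    """
    from .synthetic import XELIRI_COST_ZAR

    cost = xeliri_cost_zar if xeliri_cost_zar is not None else XELIRI_COST_ZAR
    updates: dict[str, float] = {}
    new = base_config.with_params({})
    for name, strat in new.strategies.items():
        if strat.first_line_regimen == "FOLFIRI":
            strat.first_line_regimen = "XELIRI"
            strat.first_line_cost_zar = cost
        if strat.second_line_regimen == "FOLFIRI":
            strat.second_line_regimen = "XELIRI"
            strat.second_line_cost_zar = cost
    return new
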