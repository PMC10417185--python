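"""Base-case orchestration and report generation.

Ties the calibration, engine and economics layers together: run every
strategy of a configuration, assemble the per-strategy
cost-effectiveness rows (cost, OS, DALYs averted, ICER, dominance, NMB),
and write CSV/JSON reports plus a deterministic run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .config import ModelConfig
from .economics import (
    CEAResult,
    Dominance,
    compute_dalys,
    convert_currency,
    discounted_costs,
    frontier,
    net_monetary_benefit,
)
from .engine import CohortTrace, overall_survival_years, run_cohort, validate_dfs

log = logging.getLogger(__name__)

__all__ = ["StrategyOutcome", "BaseCaseReport", "run_strategy", "run_base_case",
           "frontier_from_values", "RunManifest"]


@dataclass
class StrategyOutcome:
    """Raw model outputs for one strategy before frontier classification."""

    name: str
    trace: CohortTrace
    cost_intl: float
    cost_zar: float
    os_years: float
    yll: float
    yld: float
    dalys: float


def run_strategy(config: ModelConfig, name: str) -> StrategyOutcome:
    """Calibrate schedules, run the cohort engine, and cost one strategy."""
    spec = config.strategies[name]
    schedules = config.build_schedules(name)
    trace = run_cohort(config.settings, schedules, config.pathway)
    cost = discounted_costs(trace, spec, config.costs, config.surveillance,
                            config.settings, ppp_factor=config.econ.ppp_factor)
    yll, yld, daly = compute_dalys(trace, spec, config.weights, config.settings)
    return StrategyOutcome(
        name=name, trace=trace, cost_intl=cost,
        cost_zar=cost * config.econ.ppp_factor,
        os_years=overall_survival_years(trace), yll=yll, yld=yld, dalys=daly,
    )


@dataclass
class BaseCaseReport:
    stage: str
    wtp: float
    results: list[CEAResult]
    outcomes: dict[str, StrategyOutcome] = field(default_factory=dict)

    @property
    def recommended(self) -> str:
        return next(r.strategy for r in self.results if r.recommended)

    def result(self, name: str) -> CEAResult:
        return next(r for r in self.results if r.strategy == name)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "strategy": r.strategy,
                "total_cost_intl": r.total_cost,
                "total_cost_zar": r.total_cost_zar,
                "os_years": r.os_years,
                "dalys": r.dalys,
                "dalys_averted": r.dalys_averted,
                "icer": r.icer,
                "dominance": r.dominance.value,
                "nmb_intl": r.nmb,
                "recommended": r.recommended,
            })
        return pd.DataFrame(rows)

    def to_display_dataframe(self) -> pd.DataFrame:
        """Rounded for display: costs/NMB/ICER to nearest I$, DALYs to 2 dp."""
        df = self.to_dataframe()
        for col in ("total_cost_intl", "total_cost_zar", "nmb_intl", "icer"):
            df[col] = pd.to_numeric(df[col], errors="coerce").round(0)
        for col in ("dalys", "dalys_averted", "os_years"):
            df[col] = pd.to_numeric(df[col], errors="coerce").round(2)
        return df


def run_base_case(config: ModelConfig) -> BaseCaseReport:
    """Run all strategies of a configuration and classify the frontier."""
    outcomes = {name: run_strategy(config, name) for name in config.strategies}
    comparator = config.econ.comparator
    base_daly = outcomes[comparator].dalys
    triples = [(name, o.cost_intl, base_daly - o.dalys) for name, o in outcomes.items()]
    results = frontier(triples, wtp=config.econ.wtp_per_daly)
    for r in results:
        o = outcomes[r.strategy]
        r.os_years = o.os_years
        r.dalys = o.dalys
        r.total_cost_zar = o.cost_zar
    return BaseCaseReport(stage=config.stage, wtp=config.econ.wtp_per_daly,
                          results=results, outcomes=outcomes)


def frontier_from_values(values: dict[str, tuple[float, float]], wtp: float,
                         stage: str = "from_values") -> BaseCaseReport:
    """Frontier classification directly on (cost, DALYs-averted) pairs,
    bypassing the engine — used with published table values."""
    triples = [(name, cost, eff) for name, (cost, eff) in values.items()]
    results = frontier(triples, wtp=wtp)
    return BaseCaseReport(stage=stage, wtp=wtp, results=results)


def validate_all_dfs(config: ModelConfig,
                     report: BaseCaseReport | None = None) -> dict[str, float]:
    """Relative 5-year DFS error of every strategy vs its calibration curve."""
    report = report or run_base_case(config)
    return {name: validate_dfs(report.outcomes[name].trace, config.dfs_curves[name])
            for name in config.strategies}


@dataclass
class RunManifest:
    """Deterministic record of a run: config hash, seed, outputs.

    No wall-clock fields: re-running a command with an identical
    configuration and seed must produce byte-identical outputs.
    """

    command: str
    config_hash: str
    seed: int | None
    version: str = _version
    outputs: list[str] = field(default_factory=list)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        payload = {"command": self.command, "config_hash": self.config_hash,
                   "seed": self.seed, "version": self.version,
                   "outputs": sorted(self.outputs)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def write_report(report: BaseCaseReport, out_dir: str | Path,
                 basename: str = "base_case") -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = out / f"{basename}.csv"
    report.to_dataframe().to_csv(csv_path, index=False, float_format="%.6f",
                                 lineterminator="\n")
    written.append(csv_path)
    json_path = out / f"{basename}.json"
    payload = {
        "stage": report.stage,
        "wtp_per_daly": report.wtp,
        "recommended": report.recommended,
        "strategies": {
            r.strategy: {
                "total_cost_intl": r.total_cost,
                "total_cost_zar": r.total_cost_zar,
                "os_years": r.os_years,
                "dalys": r.dalys,
                "dalys_averted": r.dalys_averted,
                "icer": r.icer,
                "dominance": r.dominance.value,
                "nmb_intl": r.nmb,
            } for r in report.results
        },
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(json_path)
    return written
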