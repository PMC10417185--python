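"""Model configuration: the in-memory container and its on-disk dialect.

A :class:`ModelConfig` bundles everything one stage's analysis needs:
simulation settings, the four strategy specifications, monthly
recurrence schedules (with the survival curves they came from),
post-recurrence death schedules per stratum, the background life table,
cost and disability-weight tables, and the surveillance calendar.

On disk a configuration is a directory with a ``config.yaml`` that
references CSV tables by relative path:

* survival curves: ``time_months,survival``
* life table: ``age_lower,age_upper,annual_death_probability``
* shared costs: ``item,zar``
* disability weights: ``item,annual_weight``
* surveillance calendar: ``item,month``

All indices are 0-based and cycles are half-open ``[t, t+1)`` months.
Writing is deterministic (sorted keys, fixed float format) so identical
configurations produce byte-identical files.

Deterministic sensitivity analyses address parameters with dotted paths
(see :meth:`ModelConfig.with_params`), e.g.
``strategies.capox_6mo.adjuvant_cost_zar`` or the hazard-scale
multipliers ``recurrence_hazard.capox_3mo`` / ``death_cc_hazard.all`` /
``background_hazard.all``.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    LifeTable,
    SurvivalCurve,
    apply_hazard_ratio,
    curve_to_monthly_probs,
    life_table_to_monthly,
)
from .economics import (
    DisabilityWeights,
    EconSettings,
    SharedCosts,
    SurveillanceSchedule,
    AE_NAMES,
)
from .engine import ModelSettings, RecurrencePathway, TransitionScheduleSet

log = logging.getLogger(__name__)

__all__ = ["ConfigError", "StrategySpec", "ModelConfig", "load_config", "write_config"]

STAGES = ("high_risk_stage_ii", "stage_iii")
STRATEGY_ORDER = ("no_adjuvant", "cape_6mo", "capox_3mo", "capox_6mo")


class ConfigError(ValueError):
    pass


@dataclass
class StrategySpec:
    """One adjuvant strategy: regimen identity, duration, costs, AE profile."""

    name: str
    label: str
    adjuvant_regimen: str | None
    adjuvant_months: int
    adjuvant_cost_zar: float
    first_line_regimen: str
    first_line_cost_zar: float
    second_line_regimen: str
    second_line_cost_zar: float
    post_recurrence_stratum: str
    ae_incidence: dict[str, float] = field(default_factory=dict)
    residual_neuropathy_incidence: float = 0.0
    first_line_visit_days: int = 8
    second_line_visit_days: int = 8

    def __post_init__(self) -> None:
        if self.adjuvant_months < 0:
            raise ConfigError("adjuvant_months must be >= 0")
        for v in (self.adjuvant_cost_zar, self.first_line_cost_zar, self.second_line_cost_zar):
            if v < 0:
                raise ConfigError(f"negative cost in strategy {self.name!r}")
        for ae, inc in self.ae_incidence.items():
            if ae not in AE_NAMES:
                raise ConfigError(f"unknown adverse event {ae!r} in strategy {self.name!r}")
            if not 0.0 <= inc <= 1.0:
                raise ConfigError(f"AE incidence for {ae!r} outside [0, 1]")
        if not 0.0 <= self.residual_neuropathy_incidence <= 1.0:
            raise ConfigError("residual_neuropathy_incidence outside [0, 1]")


@dataclass
class ModelConfig:
    """Complete, runnable configuration for one disease stage."""

    stage: str
    settings: ModelSettings
    econ: EconSettings
    pathway: RecurrencePathway
    strategies: dict[str, StrategySpec]
    dfs_curves: dict[str, SurvivalCurve]
    recurrence_schedules: dict[str, np.ndarray]
    death_cc_schedules: dict[str, np.ndarray]   # keyed by post-recurrence stratum
    life_table: LifeTable
    costs: SharedCosts
    weights: DisabilityWeights
    surveillance: SurveillanceSchedule
    # hazard-scale multipliers used by sensitivity analyses (base 1.0)
    recurrence_hazard: dict[str, float] = field(default_factory=dict)
    death_cc_hazard: dict[str, float] = field(default_factory=dict)
    background_hazard: float = 1.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.econ.comparator not in self.strategies:
            raise ConfigError(f"comparator {self.econ.comparator!r} not among strategies")
        for name, spec in self.strategies.items():
            if name not in self.recurrence_schedules:
                raise ConfigError(f"no recurrence schedule for strategy {name!r}")
            if spec.post_recurrence_stratum not in self.death_cc_schedules:
                raise ConfigError(
                    f"no post-recurrence death schedule for stratum "
                    f"{spec.post_recurrence_stratum!r} (strategy {name!r})"
                )

    # -- schedule assembly -------------------------------------------------

    def build_schedules(self, strategy_name: str) -> TransitionScheduleSet:
        """Assemble the engine's transition schedules for one strategy,
        applying any hazard-scale multipliers."""
        spec = self.strategies[strategy_name]
        horizon = self.settings.horizon

        p_recur = self.recurrence_schedules[strategy_name]
        m = (self.recurrence_hazard.get(strategy_name, 1.0)
             * self.recurrence_hazard.get("all", 1.0))
        if m != 1.0:
            p_recur = apply_hazard_ratio(p_recur, m)

        p_dcc = self.death_cc_schedules[spec.post_recurrence_stratum]
        mc = (self.death_cc_hazard.get(spec.post_recurrence_stratum, 1.0)
              * self.death_cc_hazard.get("all", 1.0))
        if mc != 1.0:
            p_dcc = apply_hazard_ratio(p_dcc, mc)

        p_do = life_table_to_monthly(self.life_table, self.settings.start_age, horizon)
        if self.background_hazard != 1.0:
            p_do = apply_hazard_ratio(p_do, self.background_hazard)

        return TransitionScheduleSet(p_recur=p_recur, p_death_cc=p_dcc, p_death_other=p_do)

    # -- parameter paths ---------------------------------------------------

    def get_param(self, path: str) -> float:
        obj, attr = self._resolve(path)
        if isinstance(obj, dict):
            return obj.get(attr, 1.0) if self._is_multiplier(path) else obj[attr]
        return getattr(obj, attr)

    def with_params(self, updates: dict[str, float]) -> "ModelConfig":
        """A deep copy of this config with dotted-path parameters replaced."""
        new = copy.deepcopy(self)
        for path, value in updates.items():
            obj, attr = new._resolve(path)
            if isinstance(obj, dict):
                obj[attr] = value
            elif hasattr(obj, "__dataclass_fields__") and getattr(type(obj), "__dataclass_params__").frozen:
                object.__setattr__(obj, attr, value)
            else:
                setattr(obj, attr, value)
        # frozen dataclass invariant checks don't rerun; re-validate settings
        ModelSettings(start_age=new.settings.start_age, max_age=new.settings.max_age,
                      annual_discount_rate=new.settings.annual_discount_rate)
        return new

    @staticmethod
    def _is_multiplier(path: str) -> bool:
        return path.split(".", 1)[0] in ("recurrence_hazard", "death_cc_hazard")

    def _resolve(self, path: str):
        parts = path.split(".")
        try:
            head = parts[0]
            if head == "settings" and len(parts) == 2:
                return self.settings, parts[1]
            if head == "econ" and len(parts) == 2:
                return self.econ, parts[1]
            if head == "pathway" and len(parts) == 2:
                return self.pathway, parts[1]
            if head == "background_hazard" and len(parts) == 1:
                return self, "background_hazard"
            if head in ("recurrence_hazard", "death_cc_hazard") and len(parts) == 2:
                return getattr(self, head), parts[1]
            if head == "strategies" and len(parts) >= 3:
                spec = self.strategies[parts[1]]
                if parts[2] == "ae_incidence" and len(parts) == 4:
                    return spec.ae_incidence, parts[3]
                if len(parts) == 3 and hasattr(spec, parts[2]):
                    return spec, parts[2]
            if head == "costs" and len(parts) >= 2:
                if parts[1] == "ae_event_zar" and len(parts) == 3:
                    return self.costs.ae_event_zar, parts[2]
                if len(parts) == 2 and hasattr(self.costs, parts[1]):
                    return self.costs, parts[1]
            if head == "weights" and len(parts) >= 2:
                if parts[1] == "ae" and len(parts) == 3:
                    return self.weights.ae, parts[2]
                if len(parts) == 2 and hasattr(self.weights, parts[1]):
                    return self.weights, parts[1]
        except KeyError as exc:
            raise ConfigError(f"cannot resolve parameter path {path!r}: {exc}") from exc
        raise ConfigError(f"cannot resolve parameter path {path!r}")

    # -- hashing -----------------------------------------------------------

    def content_hash(self) -> str:
        """Stable SHA-256 over the full configuration content."""
        payload = {
            "stage": self.stage,
            "settings": asdict(self.settings),
            "econ": asdict(self.econ),
            "pathway": asdict(self.pathway),
            "strategies": {k: asdict(v) for k, v in sorted(self.strategies.items())},
            "recurrence_schedules": {k: np.round(v, 15).tolist()
                                     for k, v in sorted(self.recurrence_schedules.items())},
            "death_cc_schedules": {k: np.round(v, 15).tolist()
                                   for k, v in sorted(self.death_cc_schedules.items())},
            "life_table": [self.life_table.age_lower.tolist(),
                           self.life_table.age_upper.tolist(),
                           self.life_table.annual_death_prob.tolist()],
            "costs": asdict(self.costs),
            "weights": asdict(self.weights),
            "surveillance": {k: list(v) for k, v in sorted(self.surveillance.visits.items())},
            "multipliers": [sorted(self.recurrence_hazard.items()),
                            sorted(self.death_cc_hazard.items()),
                            self.background_hazard],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# CSV / YAML IO

_FLOAT_FMT = "%.12g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_curve_csv(curve: SurvivalCurve, path: Path) -> None:
    _write_csv(pd.DataFrame({"time_months": curve.times, "survival": curve.survival}), path)


def read_curve_csv(path: Path, stratum_label: str = "") -> SurvivalCurve:
    df = pd.read_csv(path)
    try:
        return SurvivalCurve(times=df["time_months"].to_numpy(),
                             survival=df["survival"].to_numpy(),
                             stratum_label=stratum_label or path.stem)
    except Exception as exc:
        raise ConfigError(f"{path}: invalid survival curve: {exc}") from exc


def write_life_table_csv(table: LifeTable, path: Path) -> None:
    _write_csv(pd.DataFrame({"age_lower": table.age_lower, "age_upper": table.age_upper,
                             "annual_death_probability": table.annual_death_prob}), path)


def read_life_table_csv(path: Path) -> LifeTable:
    df = pd.read_csv(path)
    try:
        return LifeTable(age_lower=df["age_lower"].to_numpy(),
                         age_upper=df["age_upper"].to_numpy(),
                         annual_death_prob=df["annual_death_probability"].to_numpy())
    except Exception as exc:
        raise ConfigError(f"{path}: invalid life table: {exc}") from exc


def _strategy_to_yaml(spec: StrategySpec) -> dict:
    d = asdict(spec)
    d.pop("name")
    return d


def write_config(config: ModelConfig, out_dir: str | Path) -> list[Path]:
    """Materialise a configuration directory; returns the files written."""
    out = Path(out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, curve in sorted(config.dfs_curves.items()):
        p = out / "curves" / f"dfs_{name}.csv"
        write_curve_csv(curve, p)
        written.append(p)
    for stratum, probs in sorted(config.death_cc_schedules.items()):
        # store as a survival curve so the loader re-derives probabilities
        surv = np.concatenate([[1.0], np.cumprod(1.0 - probs)])
        curve = SurvivalCurve(times=np.arange(probs.size + 1, dtype=float),
                              survival=surv, stratum_label=stratum)
        p = out / "curves" / f"post_recurrence_{stratum}.csv"
        write_curve_csv(curve, p)
        written.append(p)

    p = out / "life_table.csv"
    write_life_table_csv(config.life_table, p)
    written.append(p)

    cost_rows = [("hepatectomy", config.costs.hepatectomy_zar),
                 ("bloodwork", config.costs.bloodwork_zar),
                 ("ct_scan", config.costs.ct_scan_zar),
                 ("colonoscopy", config.costs.colonoscopy_zar),
                 ("residual_neuropathy_annual", config.costs.residual_neuropathy_annual_zar),
                 ("transport_per_day", config.costs.transport_per_day_zar),
                 ("lost_wages_per_day", config.costs.lost_wages_per_day_zar)]
    cost_rows += [(f"ae_{k}", v) for k, v in sorted(config.costs.ae_event_zar.items())]
    p = out / "shared_costs.csv"
    _write_csv(pd.DataFrame(cost_rows, columns=["item", "zar"]), p)
    written.append(p)

    weight_rows = [("disease_free", config.weights.disease_free),
                   ("recurrence", config.weights.recurrence),
                   ("cc_death", config.weights.cc_death),
                   ("residual_neuropathy", config.weights.residual_neuropathy)]
    weight_rows += [(f"ae_{k}", v) for k, v in sorted(config.weights.ae.items())]
    p = out / "disability_weights.csv"
    _write_csv(pd.DataFrame(weight_rows, columns=["item", "annual_weight"]), p)
    written.append(p)

    surv_rows = [(item, m) for item, months in sorted(config.surveillance.visits.items())
                 for m in months]
    p = out / "surveillance.csv"
    _write_csv(pd.DataFrame(surv_rows, columns=["item", "month"]), p)
    written.append(p)

    doc = {
        "stage": config.stage,
        "settings": asdict(config.settings),
        "econ": asdict(config.econ),
        "pathway": asdict(config.pathway),
        "strategies": {k: _strategy_to_yaml(v) for k, v in sorted(config.strategies.items())},
        "files": {
            "life_table": "life_table.csv",
            "shared_costs": "shared_costs.csv",
            "disability_weights": "disability_weights.csv",
            "surveillance": "surveillance.csv",
            "dfs_curves": {k: f"curves/dfs_{k}.csv" for k in sorted(config.dfs_curves)},
            "post_recurrence_curves": {k: f"curves/post_recurrence_{k}.csv"
                                       for k in sorted(config.death_cc_schedules)},
        },
    }
    p = out / "config.yaml"
    p.write_text(yaml.safe_dump(doc, sort_keys=True))
    written.append(p)
    return written


def load_config(config_dir: str | Path) -> ModelConfig:
    """Load and validate a configuration directory.

    All probabilities are validated at load time; per-file diagnostics
    are logged, and the first failure aborts with the offending file.
    """
    root = Path(config_dir)
    doc_path = root / "config.yaml"
    if not doc_path.exists():
        raise ConfigError(f"no config.yaml in {root}")
    doc = yaml.safe_load(doc_path.read_text())

    settings = ModelSettings(**doc["settings"])
    econ = EconSettings(**doc["econ"])
    pathway = RecurrencePathway(**doc["pathway"])

    strategies = {}
    for name, spec in doc["strategies"].items():
        strategies[name] = StrategySpec(name=name, **spec)

    files = doc["files"]
    life_table = read_life_table_csv(root / files["life_table"])
    log.info("loaded life table: %d bands covering ages [%g, %g)",
             life_table.age_lower.size, life_table.age_lower[0], life_table.age_upper[-1])

    costs_df = pd.read_csv(root / files["shared_costs"]).set_index("item")["zar"]
    ae_costs = {k[3:]: float(v) for k, v in costs_df.items() if k.startswith("ae_")}
    costs = SharedCosts(
        hepatectomy_zar=float(costs_df["hepatectomy"]),
        bloodwork_zar=float(costs_df["bloodwork"]),
        ct_scan_zar=float(costs_df["ct_scan"]),
        colonoscopy_zar=float(costs_df["colonoscopy"]),
        residual_neuropathy_annual_zar=float(costs_df["residual_neuropathy_annual"]),
        transport_per_day_zar=float(costs_df["transport_per_day"]),
        lost_wages_per_day_zar=float(costs_df["lost_wages_per_day"]),
        ae_event_zar=ae_costs,
    )

    w_df = pd.read_csv(root / files["disability_weights"]).set_index("item")["annual_weight"]
    weights = DisabilityWeights(
        disease_free=float(w_df["disease_free"]),
        recurrence=float(w_df["recurrence"]),
        cc_death=float(w_df["cc_death"]),
        residual_neuropathy=float(w_df["residual_neuropathy"]),
        ae={k[3:]: float(v) for k, v in w_df.items() if k.startswith("ae_")},
    )

    s_df = pd.read_csv(root / files["surveillance"])
    visits: dict[str, tuple[int, ...]] = {}
    for item, grp in s_df.groupby("item"):
        visits[str(item)] = tuple(int(m) for m in sorted(grp["month"]))
    surveillance = SurveillanceSchedule(visits=visits)

    dfs_curves = {}
    recurrence_schedules = {}
    for name, rel in files["dfs_curves"].items():
        curve = read_curve_csv(root / rel, stratum_label=name)
        dfs_curves[name] = curve
        recurrence_schedules[name] = curve_to_monthly_probs(curve)
        log.info("loaded DFS curve %s: %d points to %g months", name,
                 curve.times.size, curve.max_time)

    death_cc_schedules = {}
    for stratum, rel in files["post_recurrence_curves"].items():
        curve = read_curve_csv(root / rel, stratum_label=stratum)
        death_cc_schedules[stratum] = curve_to_monthly_probs(curve)

    return ModelConfig(
        stage=doc["stage"], settings=settings, econ=econ, pathway=pathway,
        strategies=strategies, dfs_curves=dfs_curves,
        recurrence_schedules=recurrence_schedules,
        death_cc_schedules=death_cc_schedules, life_table=life_table,
        costs=costs, weights=weights, surveillance=surveillance,
    )
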