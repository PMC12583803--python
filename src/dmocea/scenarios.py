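"""Deterministic scenario analyses around the base case.

Each scenario moves exactly one lever of the model configuration:
treatment-effect persistence (20/10/5 years before natural history
resumes), the long-term continuation fraction (25% or 75% after year 5),
costing treatment and monitoring as separate visits, and the
minimum/maximum monitoring-and-treatment schedule bounds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .cohort import run_cohort
from .economics import rank_by_nmb
from .parameters import ModelConfig, ParameterRegistry
from .psa import run_psa
from .strategies import build_default_strategies
from .transitions import LifeTable

__all__ = ["SCENARIO_NAMES", "make_scenario", "run_scenarios",
           "ScenarioReport"]

#: scenario label -> (config field, value)
_LEVERS = {
    "base": None,
    "cease_20y": ("effect_persistence_years", 20.0),
    "cease_10y": ("effect_persistence_years", 10.0),
    "cease_5y": ("effect_persistence_years", 5.0),
    "continue_25pct": ("continuation_after_y5", 0.25),
    "continue_75pct": ("continuation_after_y5", 0.75),
    "separate_visit": ("separate_monitoring_visit", True),
    "monitoring_min": ("schedule_delta", -2.0),
    "monitoring_max": ("schedule_delta", 2.0),
}

SCENARIO_NAMES = tuple(_LEVERS)


def make_scenario(name: str, base: ModelConfig) -> ModelConfig:
    """Return a config differing from ``base`` only in the scenario lever."""
    if name not in _LEVERS:
        raise ValueError(f"unknown scenario {name!r}; valid names: "
                         f"{', '.join(SCENARIO_NAMES)}")
    lever = _LEVERS[name]
    if lever is None:
        return dataclasses.replace(base)
    fld, value = lever
    return dataclasses.replace(base, **{fld: value})


@dataclasses.dataclass
class ScenarioReport:
    """Per-scenario cost/QALY/NMB table and top-three strategies."""

    frame: pd.DataFrame            # rows: (scenario, strategy)
    top_three: dict[str, list[str]]
    threshold: float

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "top_three": self.top_three,
            "results": self.frame.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def run_scenarios(registry: ParameterRegistry, strategies=None,
                  config: ModelConfig | None = None,
                  life_table: LifeTable | None = None,
                  names: tuple[str, ...] = SCENARIO_NAMES,
                  psa_draws: int = 0, seed: int = 0) -> ScenarioReport:
    """Run the scenario suite.

    Deterministic by default; set ``psa_draws`` > 0 to report probabilistic
    means instead (slower). NMB and the top-three ranking use the first
    willingness-to-pay threshold (GBP 20,000 per QALY).
    """
    config = config or ModelConfig()
    base_strategies = build_default_strategies(registry)
    strat_names = list(strategies) if strategies else list(base_strategies)
    lam = config.wtp_thresholds[0]
    rows = []
    top_three: dict[str, list[str]] = {}
    for scen in names:
        cfg = make_scenario(scen, config)
        pairs: dict[str, tuple[float, float]] = {}
        if psa_draws > 0:
            psa = run_psa(registry, strat_names, n_draws=psa_draws,
                          seed=seed, config=cfg, life_table=life_table)
            mean_cost = psa.costs.mean(axis=0)
            mean_q = psa.qalys.mean(axis=0)
            for j, name in enumerate(strat_names):
                pairs[name] = (float(mean_cost[j]), float(mean_q[j]))
        else:
            for name in strat_names:
                res = run_cohort(name, registry, cfg, life_table,
                                 keep_trace=False)
                pairs[name] = (res.cost, res.qalys)
        ranking = rank_by_nmb(pairs, lam)
        top_three[scen] = list(ranking.index[:3])
        for name in strat_names:
            cost, q = pairs[name]
            rows.append({"scenario": scen, "strategy": name,
                         "cost": cost, "qalys": q,
                         "nmb": q * lam - cost,
                         "rank": int(ranking.loc[name, "rank"])})
    frame = pd.DataFrame(rows)
    return ScenarioReport(frame=frame, top_three=top_three, threshold=lam)
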