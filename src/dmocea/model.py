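"""Model/Results interface over the cohort engine.

`CostUtilityModel` bundles the parameter registry, the eleven strategy
definitions, a life table and the run configuration; ``fit()`` evaluates
the deterministic lifetime projection for every strategy and returns a
`CostUtilityResults` carrying per-strategy costs, QALYs, ICERs versus no
treatment, net monetary benefits and rankings, with a ``summary()`` table.
Probabilistic and scenario analyses hang off the same object via
``fit_psa()`` and ``fit_scenarios()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import StrategyResult, run_cohort
from .economics import compute_icer, compute_nmb, rank_by_nmb
from .parameters import (ModelConfig, ParameterRegistry,
                         build_default_registry, validate_registry)
from .psa import PSAResult, run_psa
from .scenarios import SCENARIO_NAMES, ScenarioReport, run_scenarios
from .strategies import build_default_strategies
from .transitions import LifeTable
from .synthetic import synth_life_table

__all__ = ["CostUtilityModel", "CostUtilityResults"]


class CostUtilityModel:
    """Lifetime cost-utility model of DMO treatment strategies.

    Parameters
    ----------
    registry
        Parameter registry; defaults to the bundled point estimates.
    strategies
        Mapping of strategy name -> definition; defaults to the eleven
        modelled strategies built from the registry.
    life_table
        Age/sex life table; defaults to the synthetic Gompertz-Makeham
        stand-in.
    config
        Run configuration (ages, cycle length, discounting, levers).
    """

    def __init__(self, registry: ParameterRegistry | None = None,
                 strategies=None, life_table: LifeTable | None = None,
                 config: ModelConfig | None = None):
        self.registry = registry if registry is not None else build_default_registry()
        self.strategies = (strategies if strategies is not None
                           else build_default_strategies(self.registry))
        self.life_table = life_table if life_table is not None else synth_life_table()
        self.config = config or ModelConfig()

    @classmethod
    def from_defaults(cls, **config_overrides) -> "CostUtilityModel":
        return cls(config=ModelConfig(**config_overrides))

    def validate(self):
        """Registry invariant check (violations reported, not raised)."""
        return validate_registry(self.registry)

    def fit(self, keep_traces: bool = False) -> "CostUtilityResults":
        """Deterministic evaluation of every strategy."""
        results = {
            name: run_cohort(name, self.registry, self.config,
                             self.life_table, keep_trace=keep_traces)
            for name in self.strategies
        }
        return CostUtilityResults(model=self, strategy_results=results)

    def fit_psa(self, n_draws: int = 1000, seed: int = 0) -> PSAResult:
        """Probabilistic sensitivity analysis."""
        return run_psa(self.registry, list(self.strategies), n_draws=n_draws,
                       seed=seed, config=self.config,
                       life_table=self.life_table)

    def fit_scenarios(self, names=SCENARIO_NAMES, psa_draws: int = 0,
                      seed: int = 0) -> ScenarioReport:
        """Deterministic (or probabilistic) scenario suite."""
        return run_scenarios(self.registry, list(self.strategies),
                             self.config, self.life_table, names=names,
                             psa_draws=psa_draws, seed=seed)


@dataclass
class CostUtilityResults:
    """Deterministic results for all strategies, with economics attached."""

    model: CostUtilityModel
    strategy_results: dict[str, StrategyResult]
    reference: str = "no_treatment"
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        """Table-shaped results: cost, QALYs, ICER vs reference, NMB, rank."""
        if self._frame is None:
            ref = self.strategy_results[self.reference]
            thresholds = self.model.config.wtp_thresholds
            pairs = {n: (r.cost, r.qalys)
                     for n, r in self.strategy_results.items()}
            ranking = rank_by_nmb(pairs, thresholds[0])
            rows = []
            for name, res in self.strategy_results.items():
                ice = compute_icer(res.cost, res.qalys, ref.cost, ref.qalys)
                row = {
                    "strategy": name,
                    "display_name": res.display_name,
                    "cost": res.cost,
                    "qalys": res.qalys,
                    "icer_vs_no_treatment": ice.icer,
                    "icer_flag": ice.flag,
                }
                for lam in thresholds:
                    row[f"nmb_{int(lam)}"] = compute_nmb(res.qalys, res.cost,
                                                         lam)
                row["rank"] = int(ranking.loc[name, "rank"])
                rows.append(row)
            df = pd.DataFrame(rows).set_index("strategy")
            self._frame = df.sort_values("rank")
        return self._frame

    def icer(self, strategy: str) -> float | None:
        ref = self.strategy_results[self.reference]
        res = self.strategy_results[strategy]
        return compute_icer(res.cost, res.qalys, ref.cost, ref.qalys).icer

    def summary(self, threshold: float | None = None) -> str:
        """Human-readable results table (GBP rounded to whole pounds)."""
        lam = threshold or self.model.config.wtp_thresholds[0]
        df = self.frame.copy()
        out = pd.DataFrame({
            "Strategy": df["display_name"],
            "Cost (GBP)": df["cost"].round(0).astype(int),
            "QALYs": df["qalys"].round(3),
            "ICER vs no treatment": [
                "-" if not pd.notna(v) else f"{v:,.0f}"
                for v in df["icer_vs_no_treatment"]],
            f"NMB at {int(lam):,}": df[f"nmb_{int(lam)}"].round(0).astype(int),
            "Rank": df["rank"],
        })
        title = ("Deterministic lifetime cost-utility results "
                 f"(discount {self.model.config.discount_rate:.1%}, "
                 f"horizon age {self.model.config.horizon_age:.0f})")
        return title + "\n" + "=" * len(title) + "\n" + out.to_string(index=False)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.model.config.to_dict(),
            "results": {n: r.to_dict()
                        for n, r in self.strategy_results.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))
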