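"""Probabilistic sensitivity analysis.

Every registry parameter is sampled from its declared distribution; one
coherent draw is applied to all strategies (common random parameters, so
incremental comparisons within a draw share the same world), the cohort
model is re-run, and costs/QALYs/NMB are summarised over draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ModelInputs, run_cohort
from .parameters import (DistributionSpec, ModelConfig, ParameterRegistry,
                         ParameterSpec)
from .strategies import build_default_strategies
from .transitions import LifeTable

__all__ = ["sample_parameter", "sample_dirichlet_group", "draw_registry",
           "run_psa", "PSAResult", "ParameterDraw"]


def sample_parameter(spec: ParameterSpec | DistributionSpec,
                     rng: np.random.Generator) -> float:
    """Draw one value from a scalar parameter's distribution.

    Dirichlet members must be sampled jointly with their group via
    :func:`sample_dirichlet_group`.
    """
    dist = spec.distribution if isinstance(spec, ParameterSpec) else spec
    p = dist.params
    if dist.kind == "fixed":
        return float(p["value"])
    if dist.kind == "beta":
        return float(rng.beta(float(p["alpha"]), float(p["beta"])))
    if dist.kind == "gamma":
        return float(rng.gamma(float(p["shape"]), float(p["scale"])))
    if dist.kind == "normal":
        return float(rng.normal(float(p["mu"]), float(p["sigma"])))
    if dist.kind == "lognormal":
        return float(rng.lognormal(float(p["mu"]), float(p["sigma"])))
    if dist.kind == "dirichlet":
        raise ValueError("dirichlet members are sampled jointly; "
                         "use sample_dirichlet_group")
    raise ValueError(f"unknown distribution kind {dist.kind!r}")


def sample_dirichlet_group(specs: list[ParameterSpec],
                           rng: np.random.Generator) -> np.ndarray:
    """Jointly sample one Dirichlet block; returns values summing to 1."""
    alphas = np.array([float(s.distribution.params["alpha"]) for s in specs])
    return rng.dirichlet(alphas)


@dataclass
class ParameterDraw:
    """One complete sampled registry."""

    values: dict[str, float]
    draw_index: int = 0
    seed: int | None = None

    def registry(self, base: ParameterRegistry) -> ParameterRegistry:
        """Materialise the draw as a registry (distributions preserved)."""
        reg = base.copy()
        for pid, v in self.values.items():
            reg.replace(pid, point_estimate=float(v))
        return reg


def draw_registry(registry: ParameterRegistry, rng: np.random.Generator,
                  draw_index: int = 0) -> ParameterDraw:
    """Sample every parameter once, respecting Dirichlet blocks.

    Derived quantities are kept coherent: the weighted anti-VEGF
    administration cost is recomputed from its sampled components.
    """
    values: dict[str, float] = {}
    group_members = registry.groups()
    grouped = {m for members in group_members.values() for m in members}
    for pid, spec in registry.items():
        if pid in grouped:
            continue
        values[pid] = sample_parameter(spec, rng)
    for group, members in group_members.items():
        sampled = sample_dirichlet_group([registry[m] for m in members], rng)
        for m, v in zip(members, sampled):
            values[m] = float(v)
    values["cost_admin_anti_vegf_visit"] = (
        values["cost_oct"] + 0.95 * values["cost_admin_outpatient"]
        + 0.05 * values["cost_admin_daycase"])
    return ParameterDraw(values=values, draw_index=draw_index)


@dataclass
class PSAResult:
    """Monte-Carlo summaries over PSA draws."""

    strategies: list[str]
    costs: np.ndarray              # (n_draws, n_strategies)
    qalys: np.ndarray
    thresholds: tuple[float, ...]
    n_draws: int
    seed: int
    display_names: dict[str, str] = field(default_factory=dict)

    def nmb(self, threshold: float) -> np.ndarray:
        return self.qalys * threshold - self.costs

    def summary_frame(self, ci: float = 0.95) -> pd.DataFrame:
        lo, hi = 50 * (1 - ci), 50 * (1 + ci)
        rows = {}
        rows["mean_cost"] = self.costs.mean(axis=0)
        rows["mean_qalys"] = self.qalys.mean(axis=0)
        for lam in self.thresholds:
            nmb = self.nmb(lam)
            tag = f"{int(lam)}"
            rows[f"nmb_{tag}"] = nmb.mean(axis=0)
            rows[f"nmb_{tag}_lo"] = np.percentile(nmb, lo, axis=0)
            rows[f"nmb_{tag}_hi"] = np.percentile(nmb, hi, axis=0)
        return pd.DataFrame(rows, index=self.strategies)

    def rank_frequencies(self, threshold: float | None = None) -> pd.DataFrame:
        """Row-normalised frequency of each NMB rank per strategy."""
        lam = threshold if threshold is not None else self.thresholds[0]
        nmb = self.nmb(lam)
        order = np.argsort(-nmb, axis=1, kind="stable")
        ranks = np.empty_like(order)
        n = len(self.strategies)
        ranks[np.arange(nmb.shape[0])[:, None], order] = np.arange(n)
        freq = np.zeros((n, n))
        for r in range(n):
            freq[:, r] = (ranks == r).mean(axis=0)
        return pd.DataFrame(freq, index=self.strategies,
                            columns=[f"rank_{r + 1}" for r in range(n)])


def run_psa(registry: ParameterRegistry, strategies=None, n_draws: int = 1000,
            seed: int = 0, config: ModelConfig | None = None,
            life_table: LifeTable | None = None) -> PSAResult:
    """Run the PSA: ``n_draws`` coherent parameter draws through the model.

    ``strategies`` selects a subset by name (default: all eleven). Results
    are bit-reproducible given ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    config = config or ModelConfig()
    if life_table is None:
        from .synthetic import synth_life_table
        life_table = synth_life_table()
    base_strategies = build_default_strategies(registry)
    names = list(strategies) if strategies else list(base_strategies)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    costs = np.empty((n_draws, len(names)))
    qalys = np.empty((n_draws, len(names)))
    for d in range(n_draws):
        draw = draw_registry(registry, rng, draw_index=d)
        sampled = draw.registry(registry)
        inputs = ModelInputs.from_registry(sampled)
        for j, name in enumerate(names):
            res = run_cohort(name, inputs, config, life_table,
                             keep_trace=False)
            costs[d, j] = res.cost
            qalys[d, j] = res.qalys
    display = {n: base_strategies[n].display_name for n in names}
    return PSAResult(strategies=names, costs=costs, qalys=qalys,
                     thresholds=tuple(config.wtp_thresholds),
                     n_draws=n_draws, seed=seed, display_names=display)
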