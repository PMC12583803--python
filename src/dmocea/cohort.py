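"""Lifetime cohort projection for one treatment strategy.

The alive cohort is tracked over 8 BCVA bands x 3 treated-eye
configurations (both eyes, worst seeing eye, best seeing eye) plus death.
Each 3-monthly cycle removes mortality as a competing hazard, moves
survivors by the strategy's BCVA kernel, converts a fraction of one-eye
configurations to both-eyes (fellow-eye involvement), and accrues
discounted costs and QALYs with a trapezoidal half-cycle correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ModelConfig, ParameterRegistry, UtilityTable
from .states import (DEATH, EYE_CONFIGS, LOW_VISION_STATES, N_ALIVE, N_STATES,
                     STATE_LABELS)
from .strategies import StrategyDefinition, build_default_strategies
from .transitions import (LifeTable, build_band_matrix,
                          build_natural_history_matrix,
                          cycle_death_probability, maintenance_matrix,
                          treatment_transition_probs)

__all__ = [
    "ModelInputs",
    "CohortTrace",
    "StrategyResult",
    "on_treatment_fraction",
    "utility_for",
    "cycle_cost",
    "run_cohort",
    "project_cohort",
]

COST_CATEGORIES = ("drug", "administration", "monitoring", "adverse_events",
                   "low_vision", "subsequent")


@dataclass
class ModelInputs:
    """Population-level inputs shared by all strategies in one evaluation."""

    baseline_distribution: np.ndarray      # over the 8 alive BCVA bands
    eye_split: np.ndarray                  # (both, wse, bse) at baseline
    p_fellow: float                        # per-cycle one-eye -> both-eyes
    nh_gain: float
    nh_lose: float
    mortality_hr: float
    utilities: UtilityTable
    prices: dict[str, float]
    strategies: dict[str, StrategyDefinition]

    @classmethod
    def from_registry(cls, registry: ParameterRegistry,
                      strategies: dict[str, StrategyDefinition] | None = None,
                      ) -> "ModelInputs":
        if strategies is None:
            strategies = build_default_strategies(registry)
        p_both = registry.value("p_both_eyes_baseline")
        one_eye = 1.0 - p_both
        eye_split = np.array([
            p_both,
            one_eye * registry.value("p_wse_treated"),
            one_eye * registry.value("p_bse_treated"),
        ])
        eye_split /= eye_split.sum()
        nh_gain = registry.value("nh_gain")
        nh_lose = registry.value("nh_lose")
        prices = {
            "admin_visit": registry.value("cost_admin_anti_vegf_visit"),
            "monitoring_on": registry.value("cost_monitoring_on_treatment"),
            "monitoring_post": registry.value("cost_monitoring_post_treatment"),
            "low_vision": registry.value("cost_low_vision_cycle"),
        }
        return cls(
            baseline_distribution=registry.baseline_distribution(),
            eye_split=eye_split,
            p_fellow=registry.value("p_fellow_eye_dmo"),
            nh_gain=nh_gain,
            nh_lose=nh_lose,
            mortality_hr=registry.value("mortality_hr_diabetes"),
            utilities=registry.utility_table(),
            prices=prices,
            strategies=strategies,
        )


# ---------------------------------------------------------------------------
# treatment continuation
# ---------------------------------------------------------------------------

def on_treatment_fraction(strategy: StrategyDefinition, cycle_index: int,
                          config: ModelConfig) -> float:
    """Fraction of the alive cohort still on first-line treatment.

    Everyone continues through year 1; strategy-specific annual hazards
    apply thereafter, and the fixed continuation fractions (75% in years
    3-5, 50% from year 5) multiply alongside them from year 3 onward.
    The no-treatment arm is never "on treatment".
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if strategy.is_no_treatment:
        return 0.0
    t = cycle_index * config.cycle_fraction  # years since entry, cycle start
    if t < 1.0:
        return 1.0
    h_y2, h_y3, h_later = strategy.disc_rates_y1_3
    # cumulative specific hazard from the end of year 1
    cum = h_y2 * min(t - 1.0, 1.0)
    if t > 2.0:
        cum += h_y3 * min(t - 2.0, 1.0)
    if t > 3.0:
        cum += h_later * (t - 3.0)
    s_specific = math.exp(-cum)
    if t < 3.0:
        fixed = 1.0
    elif t < 5.0:
        fixed = config.continuation_after_y3
    else:
        fixed = config.continuation_after_y5
    return s_specific * fixed


# ---------------------------------------------------------------------------
# utilities and costs
# ---------------------------------------------------------------------------

def utility_for(state: int | str, eye_config: str,
                tables: UtilityTable) -> float:
    """Utility of one state under a treated-eye configuration.

    People treated in both eyes take the best-seeing-eye column (BSE
    drives overall quality of life); only the WSE-treated configuration
    uses the worst-seeing-eye column. Death has utility 0.
    """
    idx = STATE_LABELS.index(state) if isinstance(state, str) else state
    if eye_config not in EYE_CONFIGS:
        raise ValueError(f"unknown eye configuration {eye_config!r}")
    return float(tables.column(eye_config)[idx])


def _year_value(schedule: tuple[float, ...], year: int, delta: float = 0.0,
                ) -> float:
    base = schedule[min(year, len(schedule) - 1)]
    return max(0.0, base + delta) if base > 0 else base


def _utility_weights(inputs: ModelInputs) -> np.ndarray:
    """(3, 9) utility array: rows are eye configurations."""
    return np.vstack([inputs.utilities.column(cfg) for cfg in EYE_CONFIGS])


@dataclass
class _CycleCostBreakdown:
    drug: float = 0.0
    administration: float = 0.0
    monitoring: float = 0.0
    adverse_events: float = 0.0
    low_vision: float = 0.0
    subsequent: float = 0.0

    def total(self) -> float:
        return (self.drug + self.administration + self.monitoring
                + self.adverse_events + self.low_vision + self.subsequent)


def _cycle_costs(strategy: StrategyDefinition, inputs: ModelInputs,
                 config: ModelConfig, cycle_index: int,
                 occ_start: np.ndarray, occ_end: np.ndarray,
                 on_treat: float, window_fraction: float,
                 subsequent_unit_cost: float) -> _CycleCostBreakdown:
    """Undiscounted costs accrued in one cycle (occupancy-scaled).

    One-off items (injections, laser sessions, adverse events, subsequent
    treatment) use start-of-cycle occupancy; recurring items (monitoring,
    low vision) use the trapezoidal average, consistent with the
    half-cycle correction.
    """
    out = _CycleCostBreakdown()
    cpy = config.cycles_per_year
    year = int(cycle_index * config.cycle_fraction)
    alive_start = occ_start[:, :N_ALIVE].sum()
    alive_end = occ_end[:, :N_ALIVE].sum()
    alive_mid = 0.5 * (alive_start + alive_end)
    if alive_start <= 0:
        return out
    f_both = occ_start[0, :N_ALIVE].sum() / alive_start
    eyes_factor = 1.0 + f_both  # drug doubled for the both-eyes fraction

    delta = config.schedule_delta if strategy.uses_injections else 0.0
    inj_year = _year_value(strategy.injections_per_year, year, delta)
    mon_year = _year_value(strategy.monitoring_visits_per_year, year, delta)
    sess_year = _year_value(strategy.laser_sessions_per_year, year)
    inj_cycle = inj_year / cpy
    sess_cycle = sess_year / cpy
    on_mass = on_treat * alive_start

    out.drug = (strategy.drug_unit_cost * inj_cycle * eyes_factor
                + strategy.laser_unit_cost * sess_cycle * eyes_factor) * on_mass
    # anti-VEGF administration: one visit per injection, both eyes together;
    # laser administration is folded into the laser treatment cost
    out.administration = inputs.prices["admin_visit"] * inj_cycle * on_mass

    if strategy.uses_injections and not config.separate_monitoring_visit:
        # treatment delivered at monitoring visits: only the excess
        # monitoring visits are charged separately
        mon_visits_cycle = max(0.0, mon_year - inj_year) / cpy
    else:
        mon_visits_cycle = mon_year / cpy
    out.monitoring = (inputs.prices["monitoring_on"] * mon_visits_cycle
                      * on_treat * alive_mid)
    if not strategy.is_no_treatment:
        post_cycle = config.post_monitoring_visits_per_year / cpy
        out.monitoring += (inputs.prices["monitoring_post"] * post_cycle
                           * (1.0 - on_treat) * alive_mid)

    out.adverse_events = strategy.ae_expected_cost_per_cycle * on_mass
    lv_start = occ_start[:, LOW_VISION_STATES].sum()
    lv_end = occ_end[:, LOW_VISION_STATES].sum()
    out.low_vision = inputs.prices["low_vision"] * 0.5 * (lv_start + lv_end)
    out.subsequent = subsequent_unit_cost * window_fraction * alive_start
    return out


def cycle_cost(strategy: StrategyDefinition, state: int | str,
               eye_split: np.ndarray, on_treatment: float, cycle_index: int,
               registry: ParameterRegistry, config: ModelConfig) -> float:
    """Cost accrued in one cycle by a cohort fully occupying one state.

    Convenience single-state wrapper around the vectorised accounting used
    by :func:`run_cohort` (no half-cycle correction, no subsequent window).
    """
    inputs = ModelInputs.from_registry(registry)
    idx = STATE_LABELS.index(state) if isinstance(state, str) else state
    occ = np.zeros((3, N_STATES))
    occ[:, idx] = np.asarray(eye_split, dtype=float)
    bd = _cycle_costs(strategy, inputs, config, cycle_index, occ, occ,
                      on_treatment, 0.0, 0.0)
    return bd.total()


def _subsequent_unit_cost(strategy: StrategyDefinition, inputs: ModelInputs,
                          config: ModelConfig) -> float:
    """Expected per-cycle cost of subsequent treatment for one switcher,
    using each switch target's first-year schedule."""
    cpy = config.cycles_per_year
    total = 0.0
    for to, w in strategy.subsequent_weights.items():
        sub = inputs.strategies[to]
        inj = sub.injections_per_year[0] / cpy
        sess = sub.laser_sessions_per_year[0] / cpy
        per_cycle = (sub.drug_unit_cost * inj
                     + inputs.prices["admin_visit"] * inj
                     + sub.laser_unit_cost * sess
                     + sub.ae_expected_cost_per_cycle)
        total += w * per_cycle
    return total


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_cohort(kernels: list[np.ndarray] | np.ndarray,
                   initial: np.ndarray, n_cycles: int) -> np.ndarray:
    """Evolve a distribution under per-cycle kernels.

    Returns occupancy at cycle boundaries, shape ``(n_cycles + 1, n_states)``.
    ``kernels`` is either a single matrix or one matrix per cycle. This is
    the bare Markov recursion the engine is built on; kept separate so it
    can be checked against a matrix-power closed form.
    """
    initial = np.asarray(initial, dtype=float)
    single = isinstance(kernels, np.ndarray) and kernels.ndim == 2
    out = np.empty((n_cycles + 1, initial.size))
    out[0] = initial
    for c in range(n_cycles):
        k = kernels if single else kernels[c]
        out[c + 1] = out[c] @ k
    return out


@dataclass
class CohortTrace:
    """Per-cycle record of occupancy and accruals."""

    occupancy: np.ndarray          # (n_cycles + 1, 3, 9), cycle boundaries
    on_treatment: np.ndarray       # (n_cycles,)
    utility: np.ndarray            # (n_cycles,) undiscounted QALYs per cycle
    utility_discounted: np.ndarray
    costs: dict[str, np.ndarray]   # category -> (n_cycles,) undiscounted
    costs_discounted: dict[str, np.ndarray]

    def conservation_error(self) -> float:
        return float(np.abs(self.occupancy.sum(axis=(1, 2)) - 1.0).max())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle/state/eye-configuration export."""
        n = self.occupancy.shape[0]
        rows = []
        for c in range(n):
            for e, cfg in enumerate(EYE_CONFIGS):
                for s, lab in enumerate(STATE_LABELS):
                    rows.append((c, lab, cfg, self.occupancy[c, e, s]))
        df = pd.DataFrame(rows, columns=["cycle", "state", "eye_config",
                                         "occupancy"])
        per_cycle = pd.DataFrame(
            {"cycle": np.arange(n - 1), "on_treatment": self.on_treatment,
             "utility": self.utility,
             "utility_discounted": self.utility_discounted}
            | {f"cost_{k}": v for k, v in self.costs.items()}
            | {f"cost_{k}_discounted": v
               for k, v in self.costs_discounted.items()})
        return df.merge(per_cycle, on="cycle", how="left")


@dataclass
class StrategyResult:
    """Lifetime totals for one strategy."""

    strategy: str
    display_name: str
    cost: float                    # total discounted cost
    qalys: float                   # total discounted QALYs
    cost_undiscounted: float
    qalys_undiscounted: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    life_years: float = 0.0        # discounted
    trace: CohortTrace | None = None

    def to_dict(self) -> dict:
        return {"strategy": self.strategy, "display_name": self.display_name,
                "cost": self.cost, "qalys": self.qalys,
                "cost_undiscounted": self.cost_undiscounted,
                "qalys_undiscounted": self.qalys_undiscounted,
                "life_years": self.life_years,
                "cost_breakdown": dict(self.cost_breakdown)}


def _kernel_schedule(strategy: StrategyDefinition, inputs: ModelInputs,
                     config: ModelConfig) -> list[np.ndarray]:
    """Alive-conditional kernel per cycle for one strategy.

    No-treatment (and any zero-effect arm) follows natural history
    throughout. Treated arms apply the effect-derived kernel during model
    year 1; while the effect persists they hold achieved BCVA (base case)
    or follow the configured post-year-1 mode; natural history resumes
    once persistence ends.
    """
    nh = build_natural_history_matrix(inputs.nh_gain, inputs.nh_lose).entries
    n_cycles = config.n_cycles()
    if strategy.is_no_treatment or strategy.effect.md_logmar == 0.0:
        return [nh] * n_cycles
    pg, pl = treatment_transition_probs(strategy.effect.md_logmar,
                                        config.sigma_letters_cycle,
                                        config.cycle_fraction)
    effect = build_band_matrix(pg, pl, label=f"{strategy.name} effect").entries
    post = {"maintenance": maintenance_matrix().entries,
            "continued-effect": effect,
            "natural-history": nh}[config.effect_mode]
    kernels = []
    for c in range(n_cycles):
        t = c * config.cycle_fraction
        if t >= config.effect_persistence_years:
            kernels.append(nh)
        elif t < 1.0:
            kernels.append(effect)
        else:
            kernels.append(post)
    return kernels


def run_cohort(strategy: StrategyDefinition | str,
               registry: ParameterRegistry | ModelInputs,
               config: ModelConfig | None = None,
               life_table: LifeTable | None = None,
               keep_trace: bool = True) -> StrategyResult:
    """Run the lifetime projection for one strategy.

    ``registry`` may be a :class:`ParameterRegistry` (point estimates) or a
    pre-built :class:`ModelInputs` (e.g. one PSA draw). The run is fully
    deterministic given its inputs.
    """
    config = config or ModelConfig()
    if isinstance(registry, ModelInputs):
        inputs = registry
    else:
        inputs = ModelInputs.from_registry(registry)
    if isinstance(strategy, str):
        if strategy not in inputs.strategies:
            raise KeyError(f"unknown strategy {strategy!r}; expected one of "
                           f"{sorted(inputs.strategies)}")
        strategy = inputs.strategies[strategy]
    if life_table is None:
        from .synthetic import synth_life_table
        life_table = synth_life_table()

    n_cycles = config.n_cycles()
    cf = config.cycle_fraction
    kernels = _kernel_schedule(strategy, inputs, config)
    u_cols = _utility_weights(inputs)                  # (3, 9)
    sub_unit = _subsequent_unit_cost(strategy, inputs, config)
    window_cycles = round(config.subsequent_treatment_years
                          * config.cycles_per_year)

    occ = np.zeros((3, N_STATES))
    for e in range(3):
        occ[e, :N_ALIVE] = inputs.baseline_distribution * inputs.eye_split[e]

    occupancy = np.empty((n_cycles + 1, 3, N_STATES))
    occupancy[0] = occ
    on_tr_arr = np.empty(n_cycles)
    util = np.empty(n_cycles)
    util_disc = np.empty(n_cycles)
    costs = {k: np.zeros(n_cycles) for k in COST_CATEGORIES}
    costs_disc = {k: np.zeros(n_cycles) for k in COST_CATEGORIES}

    for c in range(n_cycles):
        age = config.start_age + c * cf
        p_death = cycle_death_probability(age, config.male_fraction,
                                          life_table, inputs.mortality_hr, cf)
        m = kernels[c].copy()
        m[:N_ALIVE, :] *= (1.0 - p_death)
        m[:N_ALIVE, DEATH] += p_death
        occ_end = occ @ m
        # fellow-eye conversion: one-eye alive mass moves to both-eyes
        conv = inputs.p_fellow * occ_end[1:, :N_ALIVE]
        occ_end[0, :N_ALIVE] += conv.sum(axis=0)
        occ_end[1:, :N_ALIVE] -= conv

        on_tr = on_treatment_fraction(strategy, c, config)
        on_tr_arr[c] = on_tr
        if strategy.is_no_treatment:
            window = 0.0
        else:
            # fraction that discontinued within the subsequent-treatment window
            prev = on_treatment_fraction(strategy,
                                         max(0, c - window_cycles), config)
            window = max(0.0, prev - on_tr)

        disc = (1.0 + config.discount_rate) ** (-(c + 0.5) * cf)
        u_start = float((occ * u_cols).sum())
        u_end = float((occ_end * u_cols).sum())
        q = cf * 0.5 * (u_start + u_end)
        q -= (strategy.ae_expected_disutility_per_cycle * on_tr
              * occ[:, :N_ALIVE].sum())
        util[c] = q
        util_disc[c] = q * disc

        bd = _cycle_costs(strategy, inputs, config, c, occ, occ_end, on_tr,
                          window, sub_unit)
        for k in COST_CATEGORIES:
            v = getattr(bd, k)
            costs[k][c] = v
            costs_disc[k][c] = v * disc
        occ = occ_end
        occupancy[c + 1] = occ

    trace = CohortTrace(occupancy=occupancy, on_treatment=on_tr_arr,
                        utility=util, utility_discounted=util_disc,
                        costs=costs, costs_discounted=costs_disc)
    alive = occupancy[:, :, :N_ALIVE].sum(axis=(1, 2))
    disc_factors = (1.0 + config.discount_rate) ** (
        -(np.arange(n_cycles) + 0.5) * cf)
    life_years = float((0.5 * (alive[:-1] + alive[1:]) * cf
                        * disc_factors).sum())
    result = StrategyResult(
        strategy=strategy.name,
        display_name=strategy.display_name,
        cost=float(sum(v.sum() for v in costs_disc.values())),
        qalys=float(util_disc.sum()),
        cost_undiscounted=float(sum(v.sum() for v in costs.values())),
        qalys_undiscounted=float(util.sum()),
        cost_breakdown={k: float(v.sum()) for k, v in costs_disc.items()},
        life_years=life_years,
        trace=trace if keep_trace else None,
    )
    return result
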