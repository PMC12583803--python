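"""The eleven treatment strategies and their construction from the registry."""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ParameterRegistry, TreatmentEffect
from .synthetic import (AEEvent, COMBINATION_ARMS, LASER_ARMS,
                        STRATEGY_ORDER)

__all__ = ["StrategyDefinition", "build_default_strategies", "STRATEGY_ORDER",
           "DISPLAY_NAMES"]

DISPLAY_NAMES = {
    "no_treatment": "No treatment",
    "laser_subthreshold": "Subthreshold micropulse laser",
    "laser_standard": "Standard threshold laser",
    "bevacizumab": "Bevacizumab",
    "bevacizumab_laser": "Bevacizumab plus standard threshold laser",
    "ranibizumab_ongavia": "Ranibizumab biosimilar (Ongavia)",
    "ranibizumab_lucentis": "Ranibizumab (Lucentis)",
    "ranibizumab_laser": "Ranibizumab (Lucentis) plus standard threshold laser",
    "brolucizumab": "Brolucizumab",
    "faricimab": "Faricimab",
    "aflibercept": "Aflibercept",
}

# registry id indirections implementing the stated equivalences
_EFFECT_KEY = {
    "ranibizumab_lucentis": "effect_ranibizumab",
    "ranibizumab_ongavia": "effect_ranibizumab",
}
_SCHEDULE_SOURCE = {           # biosimilar shares the originator's resource use
    "ranibizumab_ongavia": "ranibizumab_lucentis",
}
_DRUG_COST_KEY = {
    "bevacizumab_laser": "cost_drug_bevacizumab",
    "ranibizumab_laser": "cost_drug_ranibizumab_lucentis",
}


@dataclass(frozen=True)
class StrategyDefinition:
    """One treatment strategy: effect, unit costs, schedules and profiles.

    Schedules are per model year; the last entry persists. Fields sourced
    from synthetic supplementary inputs carry ``is_synthetic=True``.
    """

    name: str
    display_name: str
    effect: TreatmentEffect
    drug_unit_cost: float
    laser_unit_cost: float
    injections_per_year: tuple[float, ...]
    monitoring_visits_per_year: tuple[float, ...]
    laser_sessions_per_year: tuple[float, ...]
    ae_profile: tuple[AEEvent, ...]
    disc_rates_y1_3: tuple[float, float, float]
    subsequent_weights: dict[str, float] = field(default_factory=dict)
    is_laser: bool = False
    is_combination: bool = False
    is_no_treatment: bool = False
    is_synthetic: bool = True  # schedules/AE/discontinuation are stand-ins

    def __post_init__(self) -> None:
        if self.drug_unit_cost < 0 or self.laser_unit_cost < 0:
            raise ValueError(f"{self.name}: negative unit cost")
        for ev in self.ae_profile:
            if not 0 <= ev.per_cycle_probability <= 1:
                raise ValueError(f"{self.name}/{ev.label}: AE probability "
                                 f"{ev.per_cycle_probability} outside [0, 1]")

    @property
    def uses_injections(self) -> bool:
        return any(v > 0 for v in self.injections_per_year)

    @property
    def ae_expected_cost_per_cycle(self) -> float:
        return sum(e.per_cycle_probability * e.cost for e in self.ae_profile)

    @property
    def ae_expected_disutility_per_cycle(self) -> float:
        return sum(e.per_cycle_probability * e.disutility for e in self.ae_profile)


def _schedule(registry: ParameterRegistry, prefix: str, arm: str) -> tuple[float, ...]:
    out, year = [], 1
    while f"{prefix}__{arm}__y{year}" in registry:
        out.append(registry.value(f"{prefix}__{arm}__y{year}"))
        year += 1
    return tuple(out) if out else (0.0,)


def build_default_strategies(registry: ParameterRegistry
                             ) -> dict[str, StrategyDefinition]:
    """Build all eleven strategies from a (possibly sampled) registry."""
    strategies: dict[str, StrategyDefinition] = {}
    for arm in STRATEGY_ORDER:
        sched_arm = _SCHEDULE_SOURCE.get(arm, arm)
        if arm == "no_treatment":
            effect = TreatmentEffect(0.0, 0.0)
            drug_cost = laser_cost = 0.0
        else:
            key = _EFFECT_KEY.get(arm, f"effect_{arm}")
            effect = TreatmentEffect(
                md_logmar=registry.value(key),
                se_logmar=float(registry[key].distribution.params.get(
                    "sigma", 0.0)))
            drug_key = _DRUG_COST_KEY.get(arm, f"cost_drug_{arm}")
            drug_cost = registry.value(drug_key) if arm not in LASER_ARMS else 0.0
            if arm in LASER_ARMS:
                laser_cost = registry.value(f"cost_drug_{arm}")
            elif arm in COMBINATION_ARMS:
                laser_cost = registry.value("cost_drug_laser_standard")
            else:
                laser_cost = 0.0

        ae_profile = tuple(
            AEEvent(ev, registry.value(f"ae_p__{sched_arm}__{ev}"),
                    registry.value(f"ae_cost__{ev}"),
                    registry.value(f"ae_du__{ev}"))
            for ev in _ae_events_of(registry, sched_arm))
        disc = tuple(registry.value(f"disc__{sched_arm}__{lab}")
                     for lab in ("y2", "y3", "later"))
        weights = {to: registry.value(f"weight__{sched_arm}__{to}")
                   for to in _weight_targets_of(registry, sched_arm)}
        strategies[arm] = StrategyDefinition(
            name=arm,
            display_name=DISPLAY_NAMES[arm],
            effect=effect,
            drug_unit_cost=drug_cost,
            laser_unit_cost=laser_cost,
            injections_per_year=_schedule(registry, "inj", sched_arm),
            monitoring_visits_per_year=_schedule(registry, "mon", sched_arm),
            laser_sessions_per_year=_schedule(registry, "laser", sched_arm),
            ae_profile=ae_profile,
            disc_rates_y1_3=disc,
            subsequent_weights=weights,
            is_laser=arm in LASER_ARMS,
            is_combination=arm in COMBINATION_ARMS,
            is_no_treatment=arm == "no_treatment",
        )
    return strategies


def _suffixes_of(registry: ParameterRegistry, base: str, arm: str) -> list[str]:
    """Suffixes of ids ``{base}__{arm}__{suffix}`` owned by ``arm``."""
    prefix = f"{base}__{arm}__"
    return [pid[len(prefix):] for pid in registry if pid.startswith(prefix)]


def _ae_events_of(registry: ParameterRegistry, arm: str) -> list[str]:
    return _suffixes_of(registry, "ae_p", arm)


def _weight_targets_of(registry: ParameterRegistry, arm: str) -> list[str]:
    return _suffixes_of(registry, "weight", arm)
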