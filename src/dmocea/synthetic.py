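"""Synthetic stand-ins for inputs the published evidence base does not
report: a Gompertz-Makeham life table (in place of national life tables)
and supplementary treatment-level inputs (injection/monitoring schedules,
laser session counts, adverse-event profiles, discontinuation hazards and
subsequent-treatment weights).

Everything produced here is a placeholder by design and is flagged
``is_synthetic`` wherever it enters the parameter registry. The defaults
emulate the *structure* of the modelled care pathway — anti-VEGF loading
in year 1 with declining retreatment, a handful of laser sessions, small
per-cycle adverse-event probabilities, and annual discontinuation hazards
— not the confidential supplementary values themselves.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import DistributionSpec
from .transitions import LifeTable

__all__ = [
    "synth_life_table",
    "default_supplementary_inputs",
    "SupplementaryDefaults",
    "AEEvent",
]

#: Strategy slugs in canonical (reporting) order.
STRATEGY_ORDER = (
    "no_treatment",
    "laser_subthreshold",
    "laser_standard",
    "bevacizumab",
    "bevacizumab_laser",
    "ranibizumab_ongavia",
    "ranibizumab_lucentis",
    "ranibizumab_laser",
    "brolucizumab",
    "faricimab",
    "aflibercept",
)

ANTI_VEGF_ARMS = ("aflibercept", "bevacizumab", "brolucizumab", "faricimab",
                  "ranibizumab_lucentis", "ranibizumab_ongavia")
LASER_ARMS = ("laser_standard", "laser_subthreshold")
COMBINATION_ARMS = ("bevacizumab_laser", "ranibizumab_laser")


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

def synth_life_table(a: float = 3e-5, b: float = 0.095, c: float = 5e-4,
                     max_age: int = 110, sex_gap: float = 1.4,
                     min_age: int = 0) -> LifeTable:
    """Gompertz-Makeham life table stand-in.

    The annual hazard at age x is ``c + a*exp(b*x)``; sexes are separated
    by the multiplicative gap ``sex_gap`` split symmetrically (male hazard
    x sqrt(sex_gap), female / sqrt(sex_gap)). The table closes out with
    qx = 1 at ``max_age``. Defaults give qx(63) around 0.012, a plausible
    annual risk for the modelled cohort's entry age.
    """
    if a < 0 or b <= 0 or c < 0 or sex_gap <= 0:
        raise ValueError("life-table parameters must be non-negative (b, sex_gap > 0)")
    ages = np.arange(min_age, max_age + 1)
    hazard = c + a * np.exp(b * ages)
    qm = 1.0 - np.exp(-hazard * np.sqrt(sex_gap))
    qf = 1.0 - np.exp(-hazard / np.sqrt(sex_gap))
    qm[-1] = qf[-1] = 1.0
    return LifeTable(ages, np.clip(qm, 0, 1), np.clip(qf, 0, 1),
                     source="synthetic Gompertz-Makeham")


# ---------------------------------------------------------------------------
# supplementary treatment-level inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AEEvent:
    """One adverse event: per-cycle probability with one-off consequences."""

    label: str
    per_cycle_probability: float
    cost: float
    disutility: float


# schedules are per model year; the final entry persists thereafter
_AV_INJECTIONS = (8.0, 5.0, 3.0, 2.0, 2.0)
_AV_MONITORING = (8.0, 6.0, 4.0, 4.0)
_COMBO_MONITORING = (10.0, 7.0, 4.0, 4.0)
_LASER_SESSIONS = (2.0, 1.0, 0.0)
_LASER_MONITORING = (4.0, 4.0, 2.0, 2.0)

_AV_DISC = (0.10, 0.10, 0.05)     # annual hazards: year 2, year 3, later
_LASER_DISC = (0.20, 0.15, 0.05)

_AE_EVENTS = {
    "endophthalmitis": AEEvent("endophthalmitis", 0.0004, 1200.0, 0.040),
    "cataract": AEEvent("cataract", 0.0020, 900.0, 0.010),
    "inflammation": AEEvent("inflammation", 0.0030, 150.0, 0.005),
    "laser_scarring": AEEvent("laser_scarring", 0.0010, 300.0, 0.004),
}

_ANTI_VEGF_EVENTS = ("endophthalmitis", "cataract", "inflammation")
_LASER_EVENTS = ("laser_scarring",)


@dataclass
class SupplementaryDefaults:
    """Per-strategy supplementary inputs (all synthetic).

    Schedules are tuples per model year with the last value persisting.
    ``ae_probs`` maps strategy -> event label -> per-cycle probability;
    event costs and disutilities are shared across strategies.
    """

    injections: dict[str, tuple[float, ...]]
    monitoring: dict[str, tuple[float, ...]]
    laser_sessions: dict[str, tuple[float, ...]]
    ae_probs: dict[str, dict[str, float]]
    ae_costs: dict[str, float]
    ae_disutilities: dict[str, float]
    disc_hazards: dict[str, tuple[float, float, float]]
    subsequent_weights: dict[str, dict[str, float]]
    seed: int = 0
    is_synthetic: bool = True

    def validate(self) -> list[str]:
        """Structural checks; returns a list of violation messages."""
        out = []
        for arm, probs in self.ae_probs.items():
            for ev, p in probs.items():
                if not 0 <= p <= 0.05:
                    out.append(f"{arm}/{ev}: AE probability {p} outside [0, 0.05]")
        for arm, hs in self.disc_hazards.items():
            if any(h < 0 for h in hs):
                out.append(f"{arm}: negative discontinuation hazard")
        for arm, w in self.subsequent_weights.items():
            if w and abs(sum(w.values()) - 1.0) > 1e-9:
                out.append(f"{arm}: subsequent weights sum to {sum(w.values())}")
            if arm in ANTI_VEGF_ARMS and any(t in ANTI_VEGF_ARMS for t in w):
                out.append(f"{arm}: within-class anti-VEGF switch")
            if arm in LASER_ARMS and any(t in LASER_ARMS for t in w):
                out.append(f"{arm}: within-class laser switch")
        for arm in ANTI_VEGF_ARMS + COMBINATION_ARMS:
            inj = self.injections[arm]
            if inj[0] < inj[min(2, len(inj) - 1)]:
                out.append(f"{arm}: year-1 injections below year-3")
        return out

    # -- registry integration --------------------------------------------
    def registry_entries(self) -> dict[str, tuple[float, DistributionSpec, str]]:
        """Flatten into registry entries: id -> (point, distribution, units).

        Counts are fixed; probabilities get weakly informative betas and
        costs gammas with SD = 10% of the mean (so +/-20% is about 2 SD),
        matching the "varied by +/-20% when data were not available" rule.
        """
        ess = 1000.0
        entries: dict[str, tuple[float, DistributionSpec, str]] = {}

        def beta(p):
            a = max(p * ess, 1e-6)
            return DistributionSpec("beta", {"alpha": a, "beta": ess - a})

        def gamma(m):
            return DistributionSpec("gamma", {"shape": 100.0, "scale": m / 100.0})

        def fixed(v):
            return DistributionSpec("fixed", {"value": float(v)})

        for arm in STRATEGY_ORDER:
            for y, v in enumerate(self.injections[arm], start=1):
                entries[f"inj__{arm}__y{y}"] = (v, fixed(v), "injections per year")
            for y, v in enumerate(self.monitoring[arm], start=1):
                entries[f"mon__{arm}__y{y}"] = (v, fixed(v), "visits per year")
            for y, v in enumerate(self.laser_sessions[arm], start=1):
                entries[f"laser__{arm}__y{y}"] = (v, fixed(v), "sessions per year")
            for k, h in enumerate(self.disc_hazards[arm]):
                label = ("y2", "y3", "later")[k]
                dist = beta(h) if h > 0 else fixed(0.0)
                entries[f"disc__{arm}__{label}"] = (h, dist, "annual hazard")
            for ev, p in self.ae_probs[arm].items():
                entries[f"ae_p__{arm}__{ev}"] = (p, beta(p),
                                               "probability per cycle")
            for to, w in self.subsequent_weights[arm].items():
                entries[f"weight__{arm}__{to}"] = (w, fixed(w), "proportion")
        for ev, c in self.ae_costs.items():
            entries[f"ae_cost__{ev}"] = (c, gamma(c), "GBP one-off")
        for ev, d in self.ae_disutilities.items():
            entries[f"ae_du__{ev}"] = (d, beta(d), "utility decrement one-off")
        return entries

    # -- CSV round trip ---------------------------------------------------
    def write_csvs(self, out_dir: str | Path) -> list[Path]:
        """Emit one CSV per input family; returns the paths written."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []

        def dump(name, header, rows):
            p = out_dir / f"{name}.csv"
            with open(p, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(header)
                w.writerows(rows)
            paths.append(p)

        sched_rows = []
        for arm in STRATEGY_ORDER:
            for fam, d in (("injections", self.injections),
                           ("monitoring", self.monitoring),
                           ("laser_sessions", self.laser_sessions)):
                for y, v in enumerate(d[arm], start=1):
                    sched_rows.append([arm, fam, y, repr(float(v))])
        dump("schedules", ["strategy", "family", "year", "value"], sched_rows)
        dump("discontinuation", ["strategy", "hazard_y2", "hazard_y3", "hazard_later"],
             [[a, *(repr(float(h)) for h in self.disc_hazards[a])]
              for a in STRATEGY_ORDER])
        dump("ae_profile", ["strategy", "event", "per_cycle_probability"],
             [[a, ev, repr(float(p))] for a in STRATEGY_ORDER
              for ev, p in self.ae_probs[a].items()])
        dump("ae_events", ["event", "cost", "disutility"],
             [[ev, repr(float(self.ae_costs[ev])),
               repr(float(self.ae_disutilities[ev]))] for ev in self.ae_costs])
        dump("subsequent_weights", ["strategy", "switch_to", "weight"],
             [[a, to, repr(float(w))] for a in STRATEGY_ORDER
              for to, w in self.subsequent_weights[a].items()])
        return paths

    @classmethod
    def read_csvs(cls, in_dir: str | Path, seed: int = 0) -> "SupplementaryDefaults":
        in_dir = Path(in_dir)
        injections: dict[str, dict[int, float]] = {}
        monitoring: dict[str, dict[int, float]] = {}
        sessions: dict[str, dict[int, float]] = {}
        fam_map = {"injections": injections, "monitoring": monitoring,
                   "laser_sessions": sessions}
        with open(in_dir / "schedules.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                fam_map[row["family"]].setdefault(row["strategy"], {})[
                    int(row["year"])] = float(row["value"])

        def tup(d):
            return {a: tuple(v for _, v in sorted(y.items())) for a, y in d.items()}

        disc = {}
        with open(in_dir / "discontinuation.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                disc[row["strategy"]] = (float(row["hazard_y2"]),
                                         float(row["hazard_y3"]),
                                         float(row["hazard_later"]))
        ae_probs: dict[str, dict[str, float]] = {a: {} for a in STRATEGY_ORDER}
        with open(in_dir / "ae_profile.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                ae_probs[row["strategy"]][row["event"]] = float(
                    row["per_cycle_probability"])
        ae_costs, ae_du = {}, {}
        with open(in_dir / "ae_events.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                ae_costs[row["event"]] = float(row["cost"])
                ae_du[row["event"]] = float(row["disutility"])
        weights: dict[str, dict[str, float]] = {a: {} for a in STRATEGY_ORDER}
        with open(in_dir / "subsequent_weights.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                weights[row["strategy"]][row["switch_to"]] = float(row["weight"])
        return cls(injections=tup(injections), monitoring=tup(monitoring),
                   laser_sessions=tup(sessions), ae_probs=ae_probs,
                   ae_costs=ae_costs, ae_disutilities=ae_du,
                   disc_hazards=disc, subsequent_weights=weights, seed=seed)


def default_supplementary_inputs(seed: int = 0) -> SupplementaryDefaults:
    """Default synthetic supplementary inputs.

    Sharing rules mirror the model's stated equivalences: the ranibizumab
    biosimilar shares the originator's resource use; bevacizumab+laser
    shares ranibizumab+laser's resource use (but bevacizumab's adverse
    events); the subthreshold laser shares the standard laser's adverse
    events; all combination arms share one laser schedule. Switch targets
    never stay within the therapeutic class. The values are deterministic;
    ``seed`` is recorded for provenance of any user-side perturbation.
    """
    zeros = (0.0,)
    injections: dict[str, tuple[float, ...]] = {}
    monitoring: dict[str, tuple[float, ...]] = {}
    sessions: dict[str, tuple[float, ...]] = {}
    ae_probs: dict[str, dict[str, float]] = {}
    disc: dict[str, tuple[float, float, float]] = {}
    weights: dict[str, dict[str, float]] = {}

    av_events = {ev: _AE_EVENTS[ev].per_cycle_probability
                 for ev in _ANTI_VEGF_EVENTS}
    laser_events = {ev: _AE_EVENTS[ev].per_cycle_probability
                    for ev in _LASER_EVENTS}

    for arm in ANTI_VEGF_ARMS:
        injections[arm] = _AV_INJECTIONS
        monitoring[arm] = _AV_MONITORING
        sessions[arm] = zeros
        ae_probs[arm] = dict(av_events)
        disc[arm] = _AV_DISC
        weights[arm] = {"laser_standard": 1.0}
    for arm in COMBINATION_ARMS:
        injections[arm] = _AV_INJECTIONS
        monitoring[arm] = _COMBO_MONITORING
        sessions[arm] = _LASER_SESSIONS
        disc[arm] = _AV_DISC
        weights[arm] = {"laser_standard": 1.0}
    ae_probs["ranibizumab_laser"] = {**av_events, **laser_events}
    ae_probs["bevacizumab_laser"] = dict(ae_probs["bevacizumab"])
    for arm in LASER_ARMS:
        injections[arm] = zeros
        monitoring[arm] = _LASER_MONITORING
        sessions[arm] = _LASER_SESSIONS
        ae_probs[arm] = dict(laser_events)
        disc[arm] = _LASER_DISC
        # laser non-responders are rescued with an anti-VEGF; the cheapest
        # cost-effective agent is the realistic switch target in UK practice
        weights[arm] = {"bevacizumab": 1.0}
    injections["no_treatment"] = zeros
    monitoring["no_treatment"] = zeros
    sessions["no_treatment"] = zeros
    ae_probs["no_treatment"] = {}
    disc["no_treatment"] = (0.0, 0.0, 0.0)
    weights["no_treatment"] = {}

    supp = SupplementaryDefaults(
        injections=injections, monitoring=monitoring, laser_sessions=sessions,
        ae_probs=ae_probs,
        ae_costs={ev: e.cost for ev, e in _AE_EVENTS.items()},
        ae_disutilities={ev: e.disutility for ev, e in _AE_EVENTS.items()},
        disc_hazards=disc, subsequent_weights=weights, seed=seed)
    problems = supp.validate()
    if problems:  # pragma: no cover - defaults are constructed valid
        raise AssertionError("invalid synthetic defaults: " + "; ".join(problems))
    return supp
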