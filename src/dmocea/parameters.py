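"""Parameter registry: every model quantity with its point estimate and
probabilistic-sensitivity-analysis distribution.

The registry holds three families of quantities:

* epidemiology / natural history (baseline BCVA distribution, fellow-eye
  involvement, per-cycle gain/lose/stay probabilities, diabetes mortality
  hazard ratio),
* treatment effects at 12 months (mean BCVA differences vs no treatment on
  the logMAR scale, from a network meta-analysis),
* unit costs and health-state utilities.

Quantities the published evidence base does not report (injection and
monitoring schedules, adverse-event profiles, discontinuation hazards,
subsequent-treatment weights) are provided by :mod:`dmocea.synthetic` and
are flagged ``is_synthetic`` wherever they enter the registry.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "ParameterSpec",
    "ParameterRegistry",
    "UtilityTable",
    "TreatmentEffect",
    "ModelConfig",
    "Violation",
    "ValidationReport",
    "build_default_registry",
    "validate_registry",
    "load_config",
]

_DIST_KINDS = {"fixed", "beta", "gamma", "dirichlet", "normal", "lognormal"}

#: slugs used in parameter ids, one per BCVA band (best -> worst)
STATE_SLUGS = ("gt85", "76_85", "66_75", "56_65", "46_55", "36_45", "26_35", "le25")


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution.

    ``params`` is keyed by conventional names per kind:
    fixed: value; beta: alpha, beta; gamma: shape, scale; normal: mu, sigma;
    lognormal: mu, sigma; dirichlet: alpha (plus a ``group`` label that ties
    the member to its simplex block).
    """

    kind: str
    params: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _DIST_KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def group(self) -> str | None:
        g = self.params.get("group")
        return str(g) if g is not None else None

    def central_value(self) -> float | None:
        """Analytic centre used for point-estimate consistency checks.

        Beta/gamma/normal use the mean; lognormal uses exp(mu) (the scale
        the hazard ratio is reported on); fixed returns its value.
        Dirichlet members return their share of the group's concentration
        only when the group total is supplied externally, so None here.
        """
        p = self.params
        if self.kind == "fixed":
            return float(p["value"])
        if self.kind == "beta":
            a, b = float(p["alpha"]), float(p["beta"])
            return a / (a + b)
        if self.kind == "gamma":
            return float(p["shape"]) * float(p["scale"])
        if self.kind == "normal":
            return float(p["mu"])
        if self.kind == "lognormal":
            return math.exp(float(p["mu"]))
        return None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        p = self.params
        out: list[str] = []

        def pos(name: str) -> None:
            v = p.get(name)
            if v is None or float(v) <= 0:
                out.append(f"{self.kind} requires {name} > 0 (got {v!r})")

        def nonneg(name: str) -> None:
            v = p.get(name)
            if v is None or float(v) < 0:
                out.append(f"{self.kind} requires {name} >= 0 (got {v!r})")

        if self.kind == "beta":
            pos("alpha"); pos("beta")
        elif self.kind == "gamma":
            pos("shape"); pos("scale")
        elif self.kind in ("normal", "lognormal"):
            nonneg("sigma")
        elif self.kind == "dirichlet":
            pos("alpha")
        elif self.kind == "fixed" and "value" not in p:
            out.append("fixed requires a value")
        return out


@dataclass(frozen=True)
class ParameterSpec:
    """One registry entry: a named quantity with its PSA distribution."""

    id: str
    point_estimate: float
    distribution: DistributionSpec
    units: str = ""
    source: str = ""
    is_synthetic: bool = False


@dataclass(frozen=True)
class TreatmentEffect:
    """12-month mean BCVA difference vs no treatment (logMAR; negative = gain)."""

    md_logmar: float
    se_logmar: float

    def __post_init__(self) -> None:
        if self.se_logmar < 0:
            raise ValueError("se_logmar must be >= 0")


@dataclass(frozen=True)
class UtilityTable:
    """Per-band utilities for the two treated-eye configurations.

    ``bse`` applies when the treated eye is the best seeing eye (and to
    people treated in both eyes); ``wse`` when it is the worst seeing eye.
    Death carries utility 0.
    """

    bse: tuple[float, ...]
    wse: tuple[float, ...]

    def column(self, eye_config: str) -> np.ndarray:
        vals = self.wse if eye_config == "wse" else self.bse
        return np.asarray(vals + (0.0,))


class ParameterRegistry:
    """Ordered mapping of parameter id -> :class:`ParameterSpec`."""

    def __init__(self, specs: Mapping[str, ParameterSpec] | None = None):
        self._specs: dict[str, ParameterSpec] = dict(specs or {})

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> ParameterSpec:
        return self._specs[key]

    def __setitem__(self, key: str, spec: ParameterSpec) -> None:
        self._specs[key] = spec

    def __contains__(self, key: str) -> bool:
        return key in self._specs

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def items(self):
        return self._specs.items()

    def value(self, key: str) -> float:
        return self._specs[key].point_estimate

    def replace(self, key: str, **changes) -> None:
        """Replace fields of an existing entry in place."""
        self._specs[key] = replace(self._specs[key], **changes)

    def groups(self) -> dict[str, list[str]]:
        """Dirichlet group label -> member ids, in registry order."""
        out: dict[str, list[str]] = {}
        for pid, spec in self._specs.items():
            g = spec.distribution.group
            if spec.distribution.kind == "dirichlet" and g:
                out.setdefault(g, []).append(pid)
        return out

    def copy(self) -> "ParameterRegistry":
        return ParameterRegistry(self._specs)

    # -- derived objects --------------------------------------------------
    def utility_table(self) -> UtilityTable:
        bse = tuple(self.value(f"utility_bse_{s}") for s in STATE_SLUGS)
        wse = tuple(self.value(f"utility_wse_{s}") for s in STATE_SLUGS)
        return UtilityTable(bse=bse, wse=wse)

    def baseline_distribution(self) -> np.ndarray:
        p = np.array([self.value(f"baseline_bcva_{s}") for s in STATE_SLUGS])
        return p / p.sum()

    # -- serialisation ----------------------------------------------------
    CSV_COLUMNS = ("id", "point_estimate", "dist_kind", "dist_params",
                   "units", "source", "is_synthetic")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.CSV_COLUMNS)
            for pid, spec in self._specs.items():
                params = ";".join(
                    f"{k}={v if isinstance(v, str) else repr(float(v))}"
                    for k, v in spec.distribution.params.items()
                )
                w.writerow([pid, repr(float(spec.point_estimate)),
                            spec.distribution.kind, params,
                            spec.units, spec.source, int(spec.is_synthetic)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterRegistry":
        reg = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                params: dict[str, float | str] = {}
                if row["dist_params"]:
                    for item in row["dist_params"].split(";"):
                        k, v = item.split("=", 1)
                        try:
                            params[k] = float(v)
                        except ValueError:
                            params[k] = v
                reg[row["id"]] = ParameterSpec(
                    id=row["id"],
                    point_estimate=float(row["point_estimate"]),
                    distribution=DistributionSpec(row["dist_kind"], params),
                    units=row["units"],
                    source=row["source"],
                    is_synthetic=bool(int(row["is_synthetic"])),
                )
        return reg


@dataclass
class ModelConfig:
    """Run-level settings of the cohort model.

    Attributes
    ----------
    start_age, male_fraction
        Cohort entry age (63 years) and male proportion (0.58).
    cycle_length_months
        Markov cycle length; must divide 12. Default 3 months.
    horizon_age
        Age at which the projection stops (lifetime horizon).
    discount_rate
        Annual discount rate applied to both costs and QALYs (0.035).
    wtp_thresholds
        Willingness-to-pay thresholds (GBP per QALY) for net monetary
        benefit reporting.
    sigma_letters_annual
        Individual-level SD of the 12-month BCVA change in ETDRS letters,
        used to convert mean treatment effects into per-cycle transition
        probabilities under a normal model. The per-cycle SD scales as
        sigma * sqrt(cycle_fraction). This is a design parameter with no
        published value; the default of 10 letters is flagged prominently.
    effect_persistence_years
        Years for which the achieved treatment effect persists before
        natural history resumes (inf = lifetime, the base case).
    effect_mode
        Kernel used after year 1 while the effect persists:
        "maintenance" (hold achieved BCVA; base case), "continued-effect"
        (keep applying the improving kernel) or "natural-history".
    continuation_after_y3, continuation_after_y5
        Fixed fractions of the cohort remaining on treatment during model
        years 3-5 and from year 5 onward (0.75, 0.50).
    subsequent_treatment_years
        Duration of the post-discontinuation subsequent-treatment cost
        window (2 years).
    separate_monitoring_visit
        Scenario lever: when True, monitoring visits are costed
        independently of injection visits rather than shared.
    schedule_delta
        Scenario lever: visits/injections added to (or removed from) every
        anti-VEGF schedule year, floored at zero.
    post_monitoring_visits_per_year
        Monitoring visits per year for discontinuers, at the post-treatment
        tariff (applied indefinitely).
    """

    start_age: float = 63.0
    male_fraction: float = 0.58
    cycle_length_months: int = 3
    horizon_age: float = 100.0
    discount_rate: float = 0.035
    wtp_thresholds: tuple[float, ...] = (20000.0, 25000.0, 30000.0)
    sigma_letters_annual: float = 10.0
    effect_persistence_years: float = math.inf
    effect_mode: str = "maintenance"
    continuation_after_y3: float = 0.75
    continuation_after_y5: float = 0.50
    subsequent_treatment_years: float = 2.0
    separate_monitoring_visit: bool = False
    schedule_delta: float = 0.0
    post_monitoring_visits_per_year: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.discount_rate < 1:
            raise ValueError("discount_rate must lie in (0, 1)")
        if 12 % self.cycle_length_months:
            raise ValueError("cycle_length_months must divide 12")
        for name in ("male_fraction", "continuation_after_y3",
                     "continuation_after_y5"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.horizon_age <= self.start_age:
            raise ValueError("horizon_age must exceed start_age")
        if self.effect_mode not in ("maintenance", "continued-effect",
                                    "natural-history"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")

    @property
    def cycle_fraction(self) -> float:
        return self.cycle_length_months / 12.0

    @property
    def cycles_per_year(self) -> int:
        return 12 // self.cycle_length_months

    @property
    def sigma_letters_cycle(self) -> float:
        return self.sigma_letters_annual * math.sqrt(self.cycle_fraction)

    def n_cycles(self) -> int:
        return round((self.horizon_age - self.start_age) * self.cycles_per_year)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["wtp_thresholds"] = list(self.wtp_thresholds)
        if math.isinf(d["effect_persistence_years"]):
            d["effect_persistence_years"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        kw = dict(d)
        if "wtp_thresholds" in kw:
            kw["wtp_thresholds"] = tuple(kw["wtp_thresholds"])
        epy = kw.get("effect_persistence_years")
        if isinstance(epy, str):
            kw["effect_persistence_years"] = float(epy)
        return cls(**kw)


def load_config(path: str | Path) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ModelConfig.from_dict(data)


# ---------------------------------------------------------------------------
# default registry
# ---------------------------------------------------------------------------

#: Dirichlet effective sample size used to turn printed proportions into
#: concentration parameters (configurable; a weakly informative default).
DIRICHLET_ESS = 100.0

#: Concentration assigned to zero-proportion Dirichlet members so the
#: simplex support stays intact under sampling.
DIRICHLET_EPSILON = 1e-6

_BASELINE_BCVA = (0.0, 0.11, 0.39, 0.27, 0.15, 0.08, 0.0, 0.0)

_BSE_UTILITIES = {
    "gt85": (0.860, 88.711, 14.441),
    "76_85": (0.860, 527.426, 85.860),
    "66_75": (0.813, 857.529, 197.242),
    "56_65": (0.802, 648.965, 160.218),
    "46_55": (0.770, 420.116, 125.489),
    "36_45": (0.760, 189.396, 59.809),
    "26_35": (0.681, 51.985, 24.351),
    "le25": (0.547, 19.128, 15.841),
}

# WSE utilities: 0.860 for the top two bands, then a linear decline to a
# floor of 0.760 (total decrement 0.1 across the six remaining bands).
_WSE_BETAS = {
    "gt85": (88.711, 14.441),
    "76_85": (527.426, 85.860),
    "66_75": (772.928, 143.587),
    "56_65": (603.521, 126.545),
    "46_55": (383.940, 90.060),
    "36_45": (177.631, 46.274),
    "26_35": (47.182, 13.567),
    "le25": (19.363, 6.114),
}

_EFFECTS = {  # arm slug -> (mean difference logMAR, SE)
    "aflibercept": (-0.286, 0.060),
    "bevacizumab": (-0.220, 0.059),
    "brolucizumab": (-0.285, 0.067),
    "faricimab": (-0.303, 0.066),
    "ranibizumab": (-0.234, 0.056),
    "laser_standard": (-0.087, 0.059),
    "laser_subthreshold": (-0.087, 0.059),
    "bevacizumab_laser": (-0.222, 0.060),
    "ranibizumab_laser": (-0.222, 0.060),
}

_DRUG_COSTS = {  # arm slug -> (cost per administration GBP, gamma scale)
    "aflibercept": (816.00, 8.497),
    "brolucizumab": (816.00, 8.497),
    "faricimab": (857.00, 8.924),
    "ranibizumab_lucentis": (551.00, 5.737),
    "ranibizumab_ongavia": (523.45, 5.451),
    "bevacizumab": (50.00, 0.521),
    "laser_standard": (41.16, 0.429),
    "laser_subthreshold": (47.11, 0.491),
}

_GAMMA_SHAPE = 96.036  # shared shape of the cost gammas


def _beta(pid, point, a, b, units="", source="", synthetic=False):
    return ParameterSpec(pid, point, DistributionSpec("beta", {"alpha": a, "beta": b}),
                         units, source, synthetic)


def _gamma(pid, point, shape, scale, units="GBP", source="", synthetic=False):
    return ParameterSpec(pid, point,
                         DistributionSpec("gamma", {"shape": shape, "scale": scale}),
                         units, source, synthetic)


def _dirichlet(pid, point, group, units="proportion", source="", synthetic=False):
    alpha = point * DIRICHLET_ESS if point > 0 else DIRICHLET_EPSILON
    return ParameterSpec(pid, point,
                         DistributionSpec("dirichlet", {"alpha": alpha, "group": group}),
                         units, source, synthetic)


def _fixed(pid, point, units="", source="", synthetic=False):
    return ParameterSpec(pid, point, DistributionSpec("fixed", {"value": point}),
                         units, source, synthetic)


def build_default_registry(supplementary=None) -> ParameterRegistry:
    """Construct the default registry of all model quantities.

    Parameters from the published tables enter with their printed point
    estimates and PSA distributions; supplementary quantities without a
    published value come from :func:`dmocea.synthetic.default_supplementary_inputs`
    and are flagged ``is_synthetic``.
    """
    reg = ParameterRegistry()

    # baseline BCVA distribution of the treated eye
    for slug, p in zip(STATE_SLUGS, _BASELINE_BCVA):
        reg[f"baseline_bcva_{slug}"] = _dirichlet(
            f"baseline_bcva_{slug}", p, "baseline_bcva", source="Regnier et al.")

    # fellow-eye involvement
    reg["p_fellow_eye_dmo"] = _beta(
        "p_fellow_eye_dmo", 0.054, 7.900, 138.397,
        "probability per 3-month cycle", "Pochopien et al.")
    reg["p_both_eyes_baseline"] = _beta(
        "p_both_eyes_baseline", 0.220, 75.900, 269.100,
        "proportion", "Regnier et al.")
    reg["p_wse_treated"] = _dirichlet(
        "p_wse_treated", 0.672, "eye_split", source="Mitchell et al.")
    reg["p_bse_treated"] = _dirichlet(
        "p_bse_treated", 0.328, "eye_split", source="Mitchell et al.")

    # natural history (per 3-month cycle)
    for pid, p in (("nh_gain", 0.035), ("nh_lose", 0.045), ("nh_stay", 0.920)):
        reg[pid] = _dirichlet(pid, p, "natural_history",
                              "probability per 3-month cycle", "Mitchell et al.")

    # mortality
    reg["mortality_hr_diabetes"] = ParameterSpec(
        "mortality_hr_diabetes", 1.950,
        DistributionSpec("lognormal", {"mu": 0.668, "sigma": 0.090}),
        "hazard ratio", "Preis et al.")

    # treatment effects (12-month mean difference vs no treatment, logMAR)
    for slug, (md, se) in _EFFECTS.items():
        reg[f"effect_{slug}"] = ParameterSpec(
            f"effect_{slug}", md,
            DistributionSpec("normal", {"mu": md, "sigma": se}),
            "logMAR", "network meta-analysis")

    # drug / laser unit costs (list prices)
    for slug, (cost, scale) in _DRUG_COSTS.items():
        reg[f"cost_drug_{slug}"] = _gamma(
            f"cost_drug_{slug}", cost, _GAMMA_SHAPE, scale,
            "GBP per administration", "BNF / NICE TA / Lois et al.")

    # administration and monitoring
    reg["cost_oct"] = _gamma("cost_oct", 101.804, _GAMMA_SHAPE, 1.060,
                             "GBP per visit", "NHS reference costs 2019-20")
    reg["cost_admin_outpatient"] = _gamma(
        "cost_admin_outpatient", 129.616, _GAMMA_SHAPE, 1.350,
        "GBP per visit (95% of visits)", "NHS reference costs 2019-20")
    reg["cost_admin_daycase"] = _gamma(
        "cost_admin_daycase", 660.838, _GAMMA_SHAPE, 6.881,
        "GBP per visit (5% of visits)", "NHS reference costs 2019-20")
    reg["cost_admin_anti_vegf_visit"] = _fixed(
        "cost_admin_anti_vegf_visit", 257.981,
        "GBP per injection visit", "weighted from the three components above")
    reg["cost_monitoring_on_treatment"] = _gamma(
        "cost_monitoring_on_treatment", 101.804, _GAMMA_SHAPE, 1.060,
        "GBP per visit", "NHS reference costs 2019-20")
    reg["cost_monitoring_post_treatment"] = _gamma(
        "cost_monitoring_post_treatment", 38.344, _GAMMA_SHAPE, 0.399,
        "GBP per visit", "Scanlon et al., inflated")
    reg["cost_low_vision_cycle"] = _gamma(
        "cost_low_vision_cycle", 421.609, 25.003, 16.862,
        "GBP per 3-month cycle", "Regnier et al.")

    # utilities
    for slug, (point, a, b) in _BSE_UTILITIES.items():
        reg[f"utility_bse_{slug}"] = _beta(
            f"utility_bse_{slug}", point, a, b, "utility", "Czoski-Murray et al.")
    for k, slug in enumerate(STATE_SLUGS):
        point = 0.860 if k < 2 else 0.860 - 0.1 * (k - 1) / 6.0
        a, b = _WSE_BETAS[slug]
        reg[f"utility_wse_{slug}"] = _beta(
            f"utility_wse_{slug}", point, a, b, "utility",
            "linear decrement per Regnier et al.")

    # synthetic supplementary quantities
    if supplementary is None:
        from .synthetic import default_supplementary_inputs
        supplementary = default_supplementary_inputs()
    for pid, (point, dist, units) in supplementary.registry_entries().items():
        reg[pid] = ParameterSpec(pid, point, dist, units,
                                 "synthetic stand-in", is_synthetic=True)
    return reg


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    parameter_id: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, pid: str, message: str) -> None:
        self.violations.append(Violation(pid, message))

    def __str__(self) -> str:
        if self.ok:
            return "registry valid: no violations"
        lines = [f"{v.parameter_id}: {v.message}" for v in self.violations]
        return "\n".join(lines)


def validate_registry(registry: ParameterRegistry) -> ValidationReport:
    """Check all registry invariants; violations are reported, not raised."""
    report = ValidationReport()
    for pid, spec in registry.items():
        for msg in spec.distribution.validate():
            report.add(pid, msg)
        # point estimate vs distribution centre (1% relative tolerance)
        centre = spec.distribution.central_value()
        if centre is not None and spec.distribution.kind != "fixed":
            denom = max(abs(centre), 1e-12)
            if abs(spec.point_estimate - centre) / denom > 0.01:
                report.add(pid, f"point estimate {spec.point_estimate} differs "
                                f"from distribution centre {centre:.6g} by >1%")
        # probability bounds
        if pid.startswith(("p_", "nh_", "baseline_bcva_", "utility_", "ae_p_",
                           "disc_", "weight_")):
            if not 0.0 <= spec.point_estimate <= 1.0:
                report.add(pid, f"probability/utility {spec.point_estimate} "
                                "outside [0, 1]")
        if pid.startswith(("cost_", "ae_cost_")) and spec.point_estimate < 0:
            report.add(pid, f"cost {spec.point_estimate} is negative")

    # dirichlet groups: proportions consistent with concentrations
    for group, members in registry.groups().items():
        total_alpha = sum(float(registry[m].distribution.params["alpha"])
                          for m in members)
        total_p = sum(registry[m].point_estimate for m in members)
        if abs(total_p - 1.0) > 1e-6:
            report.add(members[0], f"dirichlet group {group!r} proportions "
                                   f"sum to {total_p:.6g}, not 1")
        for m in members:
            share = float(registry[m].distribution.params["alpha"]) / total_alpha
            if abs(share - registry[m].point_estimate) > 0.01:
                report.add(m, f"dirichlet share {share:.4g} inconsistent with "
                              f"point estimate {registry[m].point_estimate}")

    # utility monotonicity (best -> worst vision, non-increasing; in [0,1])
    for col in ("bse", "wse"):
        vals = [registry.value(f"utility_{col}_{s}") for s in STATE_SLUGS]
        for k in range(1, len(vals)):
            if vals[k] > vals[k - 1] + 1e-12:
                report.add(f"utility_{col}_{STATE_SLUGS[k]}",
                           f"utility {vals[k]} exceeds better-vision state "
                           f"value {vals[k - 1]} (must be non-increasing)")
    return report
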