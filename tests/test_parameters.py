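"""Registry contents, validation and serialisation."""

import dataclasses
import math

import pytest

from dmocea.parameters import (STATE_SLUGS, DistributionSpec, ModelConfig,
                               ParameterSpec, validate_registry)
from dmocea.strategies import STRATEGY_ORDER


class TestDefaultRegistry:
    @pytest.mark.parametrize("pid, point, kind, params", [
        ("p_fellow_eye_dmo", 0.054, "beta", {"alpha": 7.900, "beta": 138.397}),
        ("p_both_eyes_baseline", 0.220, "beta",
         {"alpha": 75.900, "beta": 269.100}),
        ("mortality_hr_diabetes", 1.950, "lognormal",
         {"mu": 0.668, "sigma": 0.090}),
        ("effect_aflibercept", -0.286, "normal",
         {"mu": -0.286, "sigma": 0.060}),
        ("effect_faricimab", -0.303, "normal", {"mu": -0.303, "sigma": 0.066}),
        ("cost_drug_aflibercept", 816.00, "gamma",
         {"shape": 96.036, "scale": 8.497}),
        ("cost_low_vision_cycle", 421.609, "gamma",
         {"shape": 25.003, "scale": 16.862}),
        ("cost_admin_anti_vegf_visit", 257.981, "fixed", None),
        ("utility_bse_gt85", 0.860, "beta",
         {"alpha": 88.711, "beta": 14.441}),
        ("utility_bse_le25", 0.547, "beta",
         {"alpha": 19.128, "beta": 15.841}),
        ("utility_wse_le25", 0.760, "beta",
         {"alpha": 19.363, "beta": 6.114}),
    ])
    def test_printed_entries(self, registry, pid, point, kind, params):
        spec = registry[pid]
        assert spec.point_estimate == pytest.approx(point)
        assert spec.distribution.kind == kind
        if params:
            for k, v in params.items():
                assert float(spec.distribution.params[k]) == pytest.approx(v)

    def test_natural_history_triple_sums_to_one(self, registry):
        total = sum(registry.value(k) for k in ("nh_gain", "nh_lose", "nh_stay"))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_weighted_administration_cost_identity(self, registry):
        # the per-visit administration cost equals OCT + 95%/5% mix of
        # outpatient and day-case procedure tariffs
        derived = (registry.value("cost_oct")
                   + 0.95 * registry.value("cost_admin_outpatient")
                   + 0.05 * registry.value("cost_admin_daycase"))
        assert derived == pytest.approx(
            registry.value("cost_admin_anti_vegf_visit"), abs=5e-4)

    def test_beta_gamma_means_match_points_within_1pct(self, registry):
        for pid, spec in registry.items():
            if spec.distribution.kind in ("beta", "gamma", "lognormal"):
                centre = spec.distribution.central_value()
                denom = max(abs(centre), 1e-12)
                assert abs(spec.point_estimate - centre) / denom < 0.01, pid

    def test_wse_utilities_linear_decline_to_floor(self, registry):
        vals = [registry.value(f"utility_wse_{s}") for s in STATE_SLUGS]
        assert vals[0] == vals[1] == 0.860
        assert vals[-1] == pytest.approx(0.760)
        steps = [vals[i] - vals[i + 1] for i in range(1, 7)]
        assert all(s == pytest.approx(0.1 / 6, abs=1e-9) for s in steps)

    def test_baseline_distribution_normalised(self, registry):
        dist = registry.baseline_distribution()
        assert dist.sum() == pytest.approx(1.0)
        assert dist[2] == pytest.approx(0.39)  # 66-75 band is the mode

    def test_synthetic_entries_flagged(self, registry):
        assert registry["inj__bevacizumab__y1"].is_synthetic
        assert registry["ae_cost__cataract"].is_synthetic
        assert not registry["p_fellow_eye_dmo"].is_synthetic


class TestValidation:
    def test_default_registry_is_clean(self, registry):
        report = validate_registry(registry)
        assert report.ok, str(report)

    def test_zero_beta_parameter_reported(self, registry):
        reg = registry.copy()
        reg["p_fellow_eye_dmo"] = ParameterSpec(
            "p_fellow_eye_dmo", 0.054,
            DistributionSpec("beta", {"alpha": 7.9, "beta": 0.0}))
        report = validate_registry(reg)
        assert any(v.parameter_id == "p_fellow_eye_dmo"
                   and "beta" in v.message for v in report.violations)

    def test_utility_monotonicity_violation_reported(self, registry):
        reg = registry.copy()
        bad = dataclasses.replace(reg["utility_bse_56_65"],
                                  point_estimate=0.90)
        reg["utility_bse_56_65"] = bad
        report = validate_registry(reg)
        assert any("non-increasing" in v.message for v in report.violations)

    def test_point_mean_inconsistency_reported(self, registry):
        reg = registry.copy()
        reg.replace("cost_drug_bevacizumab", point_estimate=75.0)
        report = validate_registry(reg)
        assert any(v.parameter_id == "cost_drug_bevacizumab"
                   for v in report.violations)


class TestSerialisation:
    def test_csv_round_trip_bit_exact(self, registry, tmp_path):
        path = tmp_path / "params.csv"
        registry.to_csv(path)
        back = registry.__class__.from_csv(path)
        assert set(back) == set(registry)
        for pid, spec in registry.items():
            other = back[pid]
            assert other.point_estimate == spec.point_estimate  # bit-exact
            assert other.distribution.kind == spec.distribution.kind
            for k, v in spec.distribution.params.items():
                if isinstance(v, str):
                    assert other.distribution.params[k] == v
                else:
                    assert float(other.distribution.params[k]) == float(v)
            assert other.is_synthetic == spec.is_synthetic


class TestStrategies:
    def test_exactly_eleven_strategies(self, strategies):
        assert len(strategies) == 11
        assert set(strategies) == set(STRATEGY_ORDER)

    def test_biosimilar_shares_originator_fields(self, strategies):
        ong = strategies["ranibizumab_ongavia"]
        luc = strategies["ranibizumab_lucentis"]
        assert ong.effect == luc.effect
        assert ong.injections_per_year == luc.injections_per_year
        assert ong.monitoring_visits_per_year == luc.monitoring_visits_per_year
        assert ong.ae_profile == luc.ae_profile
        assert ong.disc_rates_y1_3 == luc.disc_rates_y1_3
        assert ong.drug_unit_cost != luc.drug_unit_cost  # own price

    def test_bevacizumab_laser_shares_ranibizumab_laser_resources(self, strategies):
        bev = strategies["bevacizumab_laser"]
        ran = strategies["ranibizumab_laser"]
        assert bev.effect.md_logmar == ran.effect.md_logmar
        assert bev.injections_per_year == ran.injections_per_year
        assert bev.laser_sessions_per_year == ran.laser_sessions_per_year
        # adverse events follow bevacizumab, not the combination partner
        assert bev.ae_profile == strategies["bevacizumab"].ae_profile

    def test_subthreshold_shares_standard_efficacy_and_aes(self, strategies):
        sub = strategies["laser_subthreshold"]
        std = strategies["laser_standard"]
        assert sub.effect == std.effect
        assert [e.label for e in sub.ae_profile] == \
               [e.label for e in std.ae_profile]
        assert sub.laser_unit_cost != std.laser_unit_cost

    def test_probabilities_and_costs_in_bounds(self, strategies):
        for s in strategies.values():
            assert s.drug_unit_cost >= 0 and s.laser_unit_cost >= 0
            for ev in s.ae_profile:
                assert 0 <= ev.per_cycle_probability <= 1
            for w in s.subsequent_weights.values():
                assert 0 <= w <= 1


class TestModelConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            ModelConfig(discount_rate=1.5)
        with pytest.raises(ValueError):
            ModelConfig(cycle_length_months=5)
        with pytest.raises(ValueError):
            ModelConfig(horizon_age=60.0)

    def test_cycle_derivations(self):
        cfg = ModelConfig()
        assert cfg.cycle_fraction == 0.25
        assert cfg.cycles_per_year == 4
        assert cfg.sigma_letters_cycle == pytest.approx(5.0)
        assert cfg.n_cycles() == 148

    def test_dict_round_trip_including_infinity(self):
        cfg = ModelConfig()
        back = ModelConfig.from_dict(cfg.to_dict())
        assert math.isinf(back.effect_persistence_years)
        assert back == cfg
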