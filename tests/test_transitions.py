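"""Transition kernels: structure, normal-model derivation, mortality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from dmocea.states import DEATH, N_ALIVE
from dmocea.transitions import (TransitionMatrix, assemble_matrix,
                                build_band_matrix,
                                build_natural_history_matrix,
                                cycle_death_probability,
                                logmar_md_to_letters, maintenance_matrix,
                                treatment_transition_probs)


class TestNaturalHistoryMatrix:
    def test_interior_row_matches_printed_probabilities(self):
        m = build_natural_history_matrix().entries
        row = 3  # "56-65"
        assert m[row, row - 1] == pytest.approx(0.035)
        assert m[row, row] == pytest.approx(0.920)
        assert m[row, row + 1] == pytest.approx(0.045)

    def test_boundary_rows_renormalise_into_stay(self):
        m = build_natural_history_matrix().entries
        assert m[0, 0] == pytest.approx(0.955)   # cannot gain at the top
        assert m[0, 1] == pytest.approx(0.045)
        assert m[7, 7] == pytest.approx(0.965)   # cannot lose at the bottom
        assert m[7, 6] == pytest.approx(0.035)

    def test_zero_probabilities_give_identity_on_alive(self):
        m = maintenance_matrix().entries
        assert np.allclose(m[:N_ALIVE, :N_ALIVE], np.eye(N_ALIVE))

    def test_rejects_excess_probability(self):
        with pytest.raises(ValueError):
            build_band_matrix(0.6, 0.5)

    @given(pg=st.floats(0, 0.5), pl=st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_band_matrix_always_valid(self, pg, pl):
        build_band_matrix(pg, pl).validate()


class TestLetterConversion:
    @pytest.mark.parametrize("md, letters", [
        (-0.286, 14.3), (0.0, 0.0), (-0.087, 4.35), (0.1, -5.0)])
    def test_logmar_to_letters(self, md, letters):
        assert logmar_md_to_letters(md) == pytest.approx(letters)


class TestTreatmentTransitionProbs:
    def test_zero_effect_is_symmetric_phi_minus_one(self):
        pg, pl = treatment_transition_probs(0.0, 5.0, 0.25)
        assert pg == pytest.approx(0.15865525393145707, abs=1e-12)
        assert pl == pytest.approx(pg, abs=1e-12)

    def test_aflibercept_quarterly_example(self):
        # 14.3 letters over 12 months -> 3.575 per quarter at sigma 5
        pg, pl = treatment_transition_probs(-0.286, 5.0, 0.25)
        assert pg == pytest.approx(0.3878220709625014, abs=1e-9)
        assert pl == pytest.approx(0.043172613464464375, abs=1e-9)

    def test_degenerate_sigma_limit(self):
        # mean change beyond the band threshold: the move becomes certain
        pg, pl = treatment_transition_probs(-0.286, 1e-9, 1.0)
        assert pg == pytest.approx(1.0)
        assert pl == pytest.approx(0.0)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            treatment_transition_probs(-0.1, 0.0, 0.25)

    @pytest.mark.parametrize("md", [-0.303, -0.22, -0.087, 0.0, 0.05])
    def test_matches_numerical_integration_oracle(self, md):
        sigma, cf = 5.0, 0.25
        mu = logmar_md_to_letters(md) * cf
        dens = lambda x: math.exp(-0.5 * ((x - mu) / sigma) ** 2) / (
            sigma * math.sqrt(2 * math.pi))
        pg_oracle, _ = quad(dens, 5.0, np.inf)
        pl_oracle, _ = quad(dens, -np.inf, -5.0)
        pg, pl = treatment_transition_probs(md, sigma, cf)
        assert pg == pytest.approx(pg_oracle, abs=1e-8)
        assert pl == pytest.approx(pl_oracle, abs=1e-8)

    @given(st.floats(-0.4, 0.1), st.floats(-0.4, 0.1))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_letter_gain(self, md1, md2):
        if abs(md1 - md2) < 1e-6:
            return
        more_gain, less_gain = min(md1, md2), max(md1, md2)  # negative = gain
        pg_m, pl_m = treatment_transition_probs(more_gain, 5.0, 0.25)
        pg_l, pl_l = treatment_transition_probs(less_gain, 5.0, 0.25)
        assert pg_m > pg_l
        assert pl_m < pl_l


class TestMortality:
    def test_hazard_ratio_period_conversion(self, life_table):
        # engineered table: qx = 0.01 at the probe age
        from dmocea.transitions import LifeTable
        lt = LifeTable(np.array([60, 61]), np.array([0.01, 1.0]),
                       np.array([0.01, 1.0]))
        p = cycle_death_probability(60, 0.58, lt, hr=1.95, cycle_fraction=0.25)
        assert p == pytest.approx(0.004887555567347657, abs=1e-12)
        # identity: hr = 1 over a full year returns qx exactly
        assert cycle_death_probability(60, 0.58, lt, 1.0, 1.0) == \
            pytest.approx(0.01, abs=1e-15)

    def test_terminal_age_is_certain_death(self, life_table):
        assert cycle_death_probability(life_table.max_age + 5, 0.5,
                                       life_table, 1.95, 0.25) == 1.0

    def test_zero_qx_gives_zero(self):
        from dmocea.transitions import LifeTable
        lt = LifeTable(np.array([30, 31]), np.array([0.0, 1.0]),
                       np.array([0.0, 1.0]))
        assert cycle_death_probability(30, 0.5, lt, 1.95, 0.25) == 0.0


class TestAssembleMatrix:
    def test_zero_death_embeds_unchanged(self):
        nh = build_natural_history_matrix()
        out = assemble_matrix(nh, 0.0)
        assert np.allclose(out.entries, nh.entries)
        out.validate()

    def test_interior_row_scaled_by_survival(self):
        nh = build_natural_history_matrix()
        out = assemble_matrix(nh, 0.004887555567347657).entries
        row = 3
        assert out[row, row - 1] == pytest.approx(0.03483, abs=5e-6)
        assert out[row, row] == pytest.approx(0.91550, abs=5e-6)
        assert out[row, row + 1] == pytest.approx(0.04478, abs=5e-6)
        assert out[row, DEATH] == pytest.approx(0.004888, abs=5e-7)

    @given(pd_=st.floats(0, 1), pg=st.floats(0, 0.5), pl=st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_rows_stochastic_for_any_death_probability(self, pd_, pg, pl):
        out = assemble_matrix(build_band_matrix(pg, pl), pd_)
        assert np.abs(out.entries.sum(axis=1) - 1.0).max() < 1e-12
        out.validate()


class TestTransitionMatrixValidation:
    def test_detects_two_band_jump(self):
        m = build_natural_history_matrix().entries.copy()
        m[2, 4] += 0.01
        m[2, 2] -= 0.01
        with pytest.raises(ValueError, match="2-band"):
            TransitionMatrix(m).validate()

    def test_detects_non_absorbing_death(self):
        m = build_natural_history_matrix().entries.copy()
        m[DEATH, 0] = 0.1
        m[DEATH, DEATH] = 0.9
        with pytest.raises(ValueError, match="absorbing"):
            TransitionMatrix(m).validate()
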