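"""Unit and property tests for the single-site model family."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptmcycle.io import load_rate_constants, save_rate_constants
from ptmcycle.single_site import (ModelVariant, RateConstants,
                                  VariantConstraintError, as_variant,
                                  build_single_site, input_ratio,
                                  michaelis_constant, observables,
                                  with_input_ratio)

conc = st.floats(0.0, 1e6, allow_nan=False, allow_infinity=False)


class TestMichaelisConstant:
    @pytest.mark.parametrize(
        "k_plus,k_minus,kcat,expected",
        [
            (1.00e-4, 1.00e-3, 9.99e-1, 1.0e4),  # unsaturated reference set
            (1.00e-2, 1.00e-3, 9.99e-1, 1.0e2),  # saturated via K_M
            (1.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_values(self, k_plus, k_minus, kcat, expected):
        assert michaelis_constant(k_plus, k_minus, kcat) == pytest.approx(expected)

    def test_zero_association_rate_rejected(self):
        with pytest.raises(ValueError):
            michaelis_constant(0.0, 1e-3, 1.0)


class TestInputRatio:
    def test_symmetric_is_one(self, params_unsat):
        p = params_unsat.replace(M_total=0.1)
        assert input_ratio(p) == pytest.approx(1.0)

    def test_fig4_style_setup(self, params_unsat):
        p = params_unsat.replace(M_total=10.0)  # kcat_M = kcat_D, D_T = 0.1
        assert input_ratio(p) == pytest.approx(100.0)

    def test_linear_in_m_total(self, params_unsat):
        p = params_unsat.replace(M_total=0.37)
        doubled = p.replace(M_total=0.74)
        assert input_ratio(doubled) == pytest.approx(2 * input_ratio(p))

    def test_zero_denominator_rejected(self, params_unsat):
        with pytest.raises(ValueError):
            input_ratio(params_unsat.replace(D_total=0.0))

    @given(r=st.floats(1e-6, 1e6))
    @settings(deadline=None, derandomize=True)
    def test_with_input_ratio_round_trip(self, r):
        p = RateConstants(1e-4, 1e-3, 0.999, 1e-4, 1e-3, 0.999, D_total=0.1)
        assert input_ratio(with_input_ratio(p, r)) == pytest.approx(r)

    def test_unit_ratio_matches_d_total(self, params_unsat):
        assert with_input_ratio(params_unsat, 1.0).M_total == pytest.approx(0.1)

    def test_r_zero_empties_m(self, params_unsat):
        assert with_input_ratio(params_unsat, 0.0).M_total == 0.0


class TestObservables:
    def test_all_modified(self):
        obs = observables([0.0, 5.0, 0.0, 0.0, 1.0, 1.0])
        assert obs["Sstar_fraction"] == pytest.approx(1.0)

    def test_half_modified(self):
        obs = observables([3.0, 3.0, 0.0, 0.0, 0.0, 0.0])
        assert obs["Sstar_fraction"] == pytest.approx(0.5)

    def test_with_complexes(self):
        obs = observables([900.0, 80.0, 15.0, 5.0, 0.0, 0.0])
        assert obs["S_total"] == pytest.approx(1000.0)
        assert obs["Sstar_fraction"] == pytest.approx(0.08)

    def test_empty_system_reports_missing(self):
        assert np.isnan(observables([0.0] * 6)["Sstar_fraction"])


class TestVariantConstraints:
    def test_gk_rejects_turnover(self, params_unsat):
        with pytest.raises(VariantConstraintError, match="GK"):
            build_single_site(ModelVariant.GK, params_unsat, S_total=1e3)

    def test_gk_requires_total_substrate(self, params_unsat):
        p = as_variant(params_unsat, ModelVariant.GK)
        with pytest.raises(VariantConstraintError, match="S_total"):
            build_single_site(ModelVariant.GK, p)

    def test_intermediate_rejects_unequal_deltas(self, params_unsat):
        with pytest.raises(VariantConstraintError, match="delta2 == delta1"):
            build_single_site(ModelVariant.INTERMEDIATE, params_unsat)

    def test_full_rejects_equal_deltas(self, params_unsat):
        p = params_unsat.replace(delta2=params_unsat.delta1)
        with pytest.raises(VariantConstraintError, match="delta2 > delta1"):
            build_single_site(ModelVariant.FULL, p)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(-1e-4, 1e-3, 1.0, 1e-4, 1e-3, 1.0)


class TestDerivatives:
    def test_gk_empty_substrate_is_inert(self, params_unsat):
        p = as_variant(params_unsat, ModelVariant.GK)
        m = build_single_site(ModelVariant.GK, p, S_total=1e3)
        dy = m.rhs(0.0, np.array([0, 0, 0, 0, p.M_total, p.D_total], float))
        assert np.all(dy == 0)

    @given(y=st.lists(conc, min_size=4, max_size=4))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_intermediate_total_substrate_balance(self, y):
        """Summing substrate-species derivatives gives Q - delta1 [S]_T."""
        base = RateConstants(1e-4, 1e-3, 0.999, 1e-4, 1e-3, 0.999,
                             Q=2e-2, delta1=2e-5, delta2=2e-4, D_total=0.1)
        p = as_variant(with_input_ratio(base, 2.0),
                       ModelVariant.INTERMEDIATE)
        m = build_single_site(ModelVariant.INTERMEDIATE, p)
        state = np.array([y[0], y[1], min(y[2], p.M_total),
                          min(y[3], p.D_total), 0.0, 0.0])
        state[4] = p.M_total - state[2]
        state[5] = p.D_total - state[3]
        dy = m.rhs(0.0, state)
        s_t = state[:4].sum()
        assert dy[:4].sum() == pytest.approx(p.Q - p.delta1 * s_t, rel=1e-9,
                                             abs=1e-12)

    def test_full_unmodified_only_balance(self, params_unsat):
        """With no modified species, d[S]_T/dt = Q - delta1 (S + MS)."""
        p = with_input_ratio(params_unsat, 1.0)
        m = build_single_site(ModelVariant.FULL, p)
        state = np.array([700.0, 0.0, 0.05, 0.0, p.M_total - 0.05, p.D_total])
        dy = m.rhs(0.0, state)
        assert dy[:4].sum() == pytest.approx(p.Q - p.delta1 * 700.05)

    def test_enzyme_conservation_along_trajectory(self, params_unsat):
        from scipy.integrate import solve_ivp

        p = with_input_ratio(params_unsat, 3.0)
        m = build_single_site(ModelVariant.FULL, p)
        sol = solve_ivp(m.rhs, (0, 1e5), m.default_initial, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        m_tot = sol.y[2] + sol.y[4]
        d_tot = sol.y[3] + sol.y[5]
        assert np.allclose(m_tot, p.M_total, rtol=1e-6, atol=1e-9)
        assert np.allclose(d_tot, p.D_total, rtol=1e-6, atol=1e-9)

    def test_complex_degradation_switch(self, params_unsat):
        """'uniform' degrades DS* at delta1 instead of delta2."""
        p = with_input_ratio(params_unsat, 1.0)
        state = np.array([0.0, 0.0, 0.0, 0.05, p.M_total, p.D_total - 0.05])
        d_state = build_single_site(ModelVariant.FULL, p).rhs(0.0, state)
        d_unif = build_single_site(ModelVariant.FULL, p,
                                   complex_degradation="uniform").rhs(0.0, state)
        assert d_state[3] < d_unif[3]  # faster loss under state-carried rate


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path, params_unsat):
        path = tmp_path / "params.yaml"
        save_rate_constants(params_unsat, path)
        assert load_rate_constants(path) == params_unsat

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("k_plus_M: 1.0\nnot_a_rate: 2.0\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            load_rate_constants(path)
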