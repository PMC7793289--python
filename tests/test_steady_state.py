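"""Steady-state solver and dose-response scanning behaviour."""
import numpy as np
import pytest

from ptmcycle.single_site import (ModelVariant, as_variant, build_single_site,
                                  response_family, with_input_ratio)
from ptmcycle.steady_state import (ResponseCurve, ScanError, find_steady_state,
                                   scan_response)


class TestFindSteadyState:
    def test_intermediate_mass_balance(self, params_unsat):
        """[S]_T = Q/delta1 = 1000 nM regardless of r."""
        p = as_variant(params_unsat, ModelVariant.INTERMEDIATE)
        for r in (0.1, 1.0, 50.0):
            m = build_single_site(ModelVariant.INTERMEDIATE,
                                  with_input_ratio(p, r))
            res = find_steady_state(m, enzyme_warning=False)
            assert res.converged
            assert m.substrate_total(res.state) == pytest.approx(1000.0,
                                                                 rel=1e-6)

    def test_full_high_r_reaches_fast_turnover_level(self, params_unsat):
        """At overwhelming E3 activity [S]_T -> Q/delta2 = 100 nM."""
        m = build_single_site(ModelVariant.FULL,
                              with_input_ratio(params_unsat, 1e6))
        res = find_steady_state(m, enzyme_warning=False)
        assert m.substrate_total(res.state) == pytest.approx(100.0, rel=1e-2)

    def test_no_synthesis_stays_empty(self, params_unsat):
        p = as_variant(params_unsat, ModelVariant.GK)
        m = build_single_site(ModelVariant.GK, with_input_ratio(p, 1.0),
                              S_total=1e3)
        empty = np.zeros(6)
        empty[4], empty[5] = 1e-3, 0.1
        # zero-substrate GK system: nothing reacts (substrate conservation
        # totals are projected from the supplied initial state's pivot)
        dy = m.rhs(0.0, empty)
        assert np.all(dy == 0)

    def test_nonneg_initial_required(self, params_unsat):
        m = build_single_site(ModelVariant.FULL, params_unsat)
        with pytest.raises(ValueError):
            find_steady_state(m, initial=-np.ones(6))

    def test_converged_state_nonnegative_small_residual(self, params_unsat):
        m = build_single_site(ModelVariant.FULL,
                              with_input_ratio(params_unsat, 2.0))
        res = find_steady_state(m)
        assert res.converged
        assert np.all(res.state >= 0)
        assert res.residual_norm <= 1e-12 + 1e-8 * np.abs(res.state).max()


class TestScanResponse:
    def test_gk_mirror_state(self, params_unsat):
        """Swapping the M and D enzymes (kinetics and totals) relabels the
        steady state exactly: S <-> S*, MS <-> DS*."""
        p = as_variant(params_unsat, ModelVariant.GK)
        for r in (0.3, 1.0, 7.0):
            pr = with_input_ratio(p, r)
            mirror = pr.replace(M_total=pr.D_total, D_total=pr.M_total)
            y = find_steady_state(
                build_single_site(ModelVariant.GK, pr, S_total=1e3),
                enzyme_warning=False).state
            y_m = find_steady_state(
                build_single_site(ModelVariant.GK, mirror, S_total=1e3),
                enzyme_warning=False).state
            assert y_m[0] == pytest.approx(y[1], rel=1e-6, abs=1e-8)
            assert y_m[1] == pytest.approx(y[0], rel=1e-6, abs=1e-8)
            assert y_m[2] == pytest.approx(y[3], rel=1e-6, abs=1e-8)
            assert y_m[3] == pytest.approx(y[2], rel=1e-6, abs=1e-8)

    def test_gk_symmetry_curve(self, params_unsat):
        """S*(r) = 1 - S*(1/r) on a symmetric grid, up to the (small)
        enzyme-bound fraction excluded from the free-species numerator."""
        p = as_variant(params_unsat, ModelVariant.GK)
        fam = response_family(ModelVariant.GK, p, S_total=1e3)
        grid = np.geomspace(1e-3, 1e3, 61)
        curve = scan_response(fam, r_grid=grid)
        assert np.allclose(curve.response, 1.0 - curve.response[::-1],
                           atol=1e-4)

    def test_saturation_shifts_intermediate_right(self, params_unsat,
                                                  params_sat_q):
        from ptmcycle.response_metrics import r_at_level

        curves = {}
        for name, p in (("unsat", params_unsat), ("sat", params_sat_q)):
            pv = as_variant(p, ModelVariant.INTERMEDIATE)
            curves[name] = scan_response(
                response_family(ModelVariant.INTERMEDIATE, pv), n_points=80)
        assert (r_at_level(curves["sat"], 0.5)
                > 3 * r_at_level(curves["unsat"], 0.5))

    def test_full_s_total_monotone_decreasing(self, params_unsat):
        fam = response_family(ModelVariant.FULL, params_unsat, "s_total")
        curve = scan_response(fam, n_points=80)
        assert np.all(np.diff(curve.response) <= 1e-6 * 1000.0)
        assert curve.response[0] == pytest.approx(1000.0, rel=1e-2)
        assert curve.response[-1] == pytest.approx(100.0, rel=3e-2)

    def test_warm_and_cold_starts_agree(self, params_unsat):
        fam = response_family(ModelVariant.FULL, params_unsat)
        curve = scan_response(fam, n_points=40)
        for i in (5, 20, 35):  # fresh solves, no warm start
            m = fam.build(curve.r_grid[i])
            cold = find_steady_state(m, enzyme_warning=False)
            assert fam.observe(cold.state) == pytest.approx(
                curve.response[i], rel=1e-6, abs=1e-9)

    def test_grid_refinement_stability(self, params_unsat):
        from ptmcycle.response_metrics import r_at_level

        p = as_variant(params_unsat, ModelVariant.INTERMEDIATE)
        fam = response_family(ModelVariant.INTERMEDIATE, p)
        r50 = {n: r_at_level(scan_response(fam, n_points=n), 0.5)
               for n in (60, 120)}
        assert abs(r50[120] - r50[60]) / r50[60] < 0.01

    def test_endpoint_uniqueness_guard(self, params_unsat):
        fam = response_family(ModelVariant.FULL, params_unsat)
        scan_response(fam, n_points=30, endpoint_check=True)  # must not raise

    def test_invalid_grid_rejected(self, params_unsat):
        fam = response_family(ModelVariant.FULL, params_unsat)
        with pytest.raises(ValueError):
            scan_response(fam, r_grid=np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            scan_response(fam, r_grid=np.array([]))


class TestResponseCurveSerialization:
    def test_csv_round_trip(self, tmp_path, params_unsat):
        fam = response_family(ModelVariant.FULL, params_unsat)
        curve = scan_response(fam, n_points=30)
        path = tmp_path / "curve.csv"
        curve.save(path)
        loaded = ResponseCurve.load(path)
        assert np.allclose(loaded.r_grid, curve.r_grid)
        assert np.allclose(loaded.response, curve.response)
        assert loaded.observable_tag == curve.observable_tag
        assert loaded.asymptote_low == curve.asymptote_low

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            ResponseCurve(r_grid=np.array([1.0, 0.5]),
                          response=np.array([0.1, 0.9]),
                          observable_tag="sstar_fraction",
                          asymptote_low=0.0, asymptote_high=1.0)
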