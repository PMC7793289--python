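"""Polyubiquitin-chain models across E3/DUB mechanisms."""
import numpy as np
import pytest

from ptmcycle.multisite import (ChainModelParams, DubMode, E3Mode,
                                MechanismSpec, REPRESENTATIVE, all_mechanisms,
                                build_chain_model, chain_response_family,
                                choose_truncation, modified_fraction_chain)
from ptmcycle.response_metrics import compute_metrics, r_at_level
from ptmcycle.single_site import (ModelVariant, build_single_site,
                                  response_family, with_input_ratio)
from ptmcycle.steady_state import find_steady_state, scan_response


class TestConstruction:
    def test_six_mechanisms(self):
        assert len(all_mechanisms()) == 6
        assert REPRESENTATIVE in all_mechanisms()

    def test_parameter_validation(self, params_unsat):
        with pytest.raises(ValueError, match="ell"):
            ChainModelParams(rates=params_unsat, ell=2,
                             degradation_threshold=4)
        with pytest.raises(ValueError, match="delta2 > delta1"):
            ChainModelParams(
                rates=params_unsat.replace(delta2=params_unsat.delta1),
                ell=10)

    def test_enzyme_conservation_rows(self, params_unsat):
        p = ChainModelParams(rates=with_input_ratio(params_unsat, 5.0), ell=6,
                             degradation_threshold=4)
        m = build_chain_model(REPRESENTATIVE, p)
        res = find_steady_state(m, enzyme_warning=False)
        totals = m.conserved_totals(res.state)
        assert totals[0] == pytest.approx(p.rates.M_total, abs=1e-9)
        assert totals[1] == pytest.approx(p.rates.D_total, abs=1e-9)


class TestSingleStateReduction:
    """ell = 1, threshold = 1 with a distributive E3 is the Full model."""

    @pytest.mark.parametrize("dub", [DubMode.DISTRIBUTIVE_SEQUENTIAL,
                                     DubMode.DISTRIBUTIVE_BASE])
    def test_rhs_identical(self, dub, params_unsat):
        p = with_input_ratio(params_unsat, 2.0)
        chain = build_chain_model(
            MechanismSpec(E3Mode.DISTRIBUTIVE, dub),
            ChainModelParams(rates=p, ell=1, degradation_threshold=1))
        full = build_single_site(ModelVariant.FULL, p)
        rng = np.random.default_rng(0)
        for _ in range(20):
            s, sstar, ms, ds = rng.uniform(0, 1e3, 4)
            ms = min(ms, p.M_total)
            ds = min(ds, p.D_total)
            y_full = np.array([s, sstar, ms, ds,
                               p.M_total - ms, p.D_total - ds])
            y_chain = np.array([s, sstar, ms, 0.0, 0.0, ds,
                                p.M_total - ms, p.D_total - ds])
            d_full = full.rhs(0.0, y_full)
            d_chain = chain.rhs(0.0, y_chain)
            mapped = np.array([d_chain[0], d_chain[1], d_chain[2],
                               d_chain[5], d_chain[6], d_chain[7]])
            assert np.allclose(mapped, d_full, rtol=1e-12, atol=1e-12)
            assert d_chain[3] == 0.0 and d_chain[4] == 0.0


class TestModifiedFraction:
    def test_all_below_threshold(self):
        y = np.zeros(3 * 9 + 2)
        y[0] = 100.0
        assert modified_fraction_chain(y, 4, 8) == 0.0

    def test_all_at_cap(self):
        y = np.zeros(3 * 9 + 2)
        y[8] = 50.0  # S_free at k = 8 >= 4
        assert modified_fraction_chain(y, 4, 8) == 1.0

    def test_mixed_split_counts_bound_forms(self):
        y = np.zeros(3 * 9 + 2)
        y[1] = 400.0           # S_free, k=1: below
        y[9 + 2] = 200.0       # MS, k=2: below
        y[5] = 250.0           # S_free, k=5: above
        y[18 + 6] = 150.0      # DS, k=6: above
        assert modified_fraction_chain(y, 4, 8) == pytest.approx(0.4)

    def test_empty_is_missing(self):
        assert np.isnan(modified_fraction_chain(np.zeros(3 * 9 + 2), 4, 8))


class TestTruncation:
    def test_choose_truncation_converges_fast_turnover(self, fast_turnover):
        params = ChainModelParams(rates=fast_turnover, ell=8,
                                  degradation_threshold=4)
        mech = MechanismSpec(E3Mode.DISTRIBUTIVE,
                             DubMode.DISTRIBUTIVE_SEQUENTIAL)
        ell = choose_truncation(mech, params, tol=0.01, n_points=50)
        assert ell <= 64
        # insensitivity: metrics at ell and 2 ell agree to tolerance
        m = {}
        for e in (ell, 2 * ell):
            fam = chain_response_family(
                mech, ChainModelParams(rates=fast_turnover, ell=e,
                                       degradation_threshold=4))
            m[e] = compute_metrics(scan_response(fam, n_points=50))
        assert m[2 * ell].r50 == pytest.approx(m[ell].r50, rel=0.02)
        assert m[2 * ell].n_eff == pytest.approx(m[ell].n_eff, rel=0.02)

    def test_top_state_mass_negligible_distributive(self, fast_turnover):
        """With a distributive E3, chains rarely reach the cap."""
        p = ChainModelParams(rates=with_input_ratio(fast_turnover, 100.0),
                             ell=30, degradation_threshold=4)
        mech = MechanismSpec(E3Mode.DISTRIBUTIVE,
                             DubMode.DISTRIBUTIVE_SEQUENTIAL)
        m = build_chain_model(mech, p)
        y = find_steady_state(m, enzyme_warning=False).state
        top = y[30] + y[31 + 30] + y[62 + 30]
        assert top < 1e-6 * m.substrate_total(y)


class TestQualitativeBehaviour:
    def test_chains_require_more_ligase_than_full(self, params_unsat,
                                                  params_sat_q):
        """r50 of the chain model exceeds the single-site Full model, and
        the saturation-induced shift is more pronounced with chains."""
        r50 = {}
        for name, p in (("unsat", params_unsat), ("sat", params_sat_q)):
            full = scan_response(
                response_family(ModelVariant.FULL, p), n_points=60)
            cp = ChainModelParams(rates=p, ell=16, degradation_threshold=4)
            chain = scan_response(
                chain_response_family(REPRESENTATIVE, cp), n_points=60)
            r50[name] = (r_at_level(full, 0.5), r_at_level(chain, 0.5))
        assert r50["unsat"][1] > r50["unsat"][0]
        assert r50["sat"][1] > r50["sat"][0]
        # rightward shift under saturation exceeds the single-site case
        assert (r50["sat"][1] / r50["unsat"][1]
                > r50["sat"][0] / r50["unsat"][0])

    @pytest.mark.parametrize("mech", all_mechanisms(), ids=str)
    def test_saturation_raises_r50_all_mechanisms(self, mech, params_unsat,
                                                  params_sat_q):
        """Every E3 x DUB combination loses sensitivity under saturation."""
        r50 = {}
        for name, rates in (("unsat", params_unsat), ("sat", params_sat_q)):
            cp = ChainModelParams(rates=rates, ell=12,
                                  degradation_threshold=4)
            curve = scan_response(chain_response_family(mech, cp),
                                  n_points=50)
            r50[name] = r_at_level(curve, 0.5)
        assert r50["sat"] > r50["unsat"]
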