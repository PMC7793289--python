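"""Cross-cutting oracles tying the numerical pipeline to known results.

Each oracle recomputes a quantity two independent ways — closed form vs
scan-and-extract, truncated ODE vs unbounded stochastic simulation,
N-substrate vs single-substrate — and reports the comparison. The full
suite at default tolerances is the package's self-check (`ptm validate`).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import analytics
from .io import reference_parameters
from .multisite import (ChainModelParams, REPRESENTATIVE, build_chain_model,
                        chain_response_family, choose_truncation,
                        modified_fraction_chain)
from .multisubstrate import (build_multisubstrate_model, coupling_scan,
                             multisubstrate_response_family,
                             substrate_i_total, two_substrate_params)
from .response_metrics import compute_metrics, r_at_level
from .single_site import (ModelVariant, as_variant, build_single_site,
                          response_family, with_input_ratio)
from .steady_state import find_steady_state, scan_response
from .stochastic_sim import replicate_sstar_means

__all__ = ["OracleReport", "run_oracles", "ORACLES"]


@dataclass(frozen=True)
class OracleReport:
    check_id: str
    computed: float
    reference: float
    tolerance: float
    comparison: str  # "rel" | "abs" | "le"
    passed: bool
    detail: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _report(check_id, computed, reference, tol, comparison="rel", detail=""):
    if comparison == "rel":
        ok = abs(computed - reference) <= tol * abs(reference)
    elif comparison == "abs":
        ok = abs(computed - reference) <= tol
    elif comparison == "le":
        ok = computed <= reference + tol
    else:
        raise ValueError(comparison)
    return OracleReport(check_id, float(computed), float(reference), tol,
                        comparison, bool(ok), detail)


def closed_form_vs_numeric_r50() -> OracleReport:
    """Intermediate r50: steady-state scan vs the closed-form expression."""
    p = as_variant(reference_parameters("unsaturated"), ModelVariant.INTERMEDIATE)
    curve = scan_response(response_family(ModelVariant.INTERMEDIATE, p),
                          n_points=120)
    numeric = r_at_level(curve, 0.5)
    closed = analytics.r50_intermediate_closed_form(
        p.kcat_D, p.delta1, p.Q, p.K_M_D, p.D_total)
    return _report("closed_form_vs_numeric_r50", numeric, closed, 0.01,
                   detail="reference parameters, unsaturated")


def gk_symmetry_r50() -> OracleReport:
    """Symmetric GK loop: r50 = 1 exactly."""
    p = as_variant(reference_parameters("unsaturated"), ModelVariant.GK)
    curve = scan_response(response_family(ModelVariant.GK, p, S_total=1e3),
                          n_points=120)
    return _report("gk_symmetry_r50", r_at_level(curve, 0.5), 1.0, 1e-3)


def intermediate_mass_balance() -> OracleReport:
    """Steady-state [S]_T = Q/delta1 for the Intermediate model, any r."""
    p = as_variant(reference_parameters("unsaturated"), ModelVariant.INTERMEDIATE)
    worst = 0.0
    for r in (0.1, 1.0, 10.0, 1000.0):
        m = build_single_site(ModelVariant.INTERMEDIATE, with_input_ratio(p, r))
        res = find_steady_state(m, enzyme_warning=False)
        worst = max(worst, abs(m.substrate_total(res.state) - p.Q / p.delta1))
    return _report("intermediate_mass_balance", p.Q / p.delta1 + worst,
                   p.Q / p.delta1, 1e-6, detail="max deviation over r grid")


def full_model_bounds() -> OracleReport:
    """Full-model [S]_T stays inside [Q/delta2, Q/delta1]."""
    p = reference_parameters("unsaturated")
    lo, hi = p.Q / p.delta2, p.Q / p.delta1
    worst = 0.0
    for r in (1e-3, 1.0, 1e2, 1e6):
        m = build_single_site(ModelVariant.FULL, with_input_ratio(p, r))
        st = m.substrate_total(find_steady_state(m, enzyme_warning=False).state)
        worst = max(worst, lo - st, st - hi)
    return _report("full_model_bounds", worst, 0.0, 1e-6 * hi, comparison="le",
                   detail=f"bounds [{lo:g}, {hi:g}] nM")


def _neff_at_Q(variant: ModelVariant, Q: float) -> float:
    p = as_variant(reference_parameters("unsaturated").replace(Q=Q), variant)
    curve = scan_response(response_family(variant, p), n_points=120)
    return compute_metrics(curve).n_eff


def intermediate_largeQ_neff() -> OracleReport:
    """n_eff of the Intermediate S* response approaches 2 as Q grows."""
    seq = [_neff_at_Q(ModelVariant.INTERMEDIATE, Q) for Q in (20.0, 200.0, 2000.0)]
    gaps = [abs(v - 2.0) for v in seq]
    ok_monotone = all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))
    rep = _report("intermediate_largeQ_neff", seq[-1], 2.0, 0.01,
                  detail=f"sequence {np.round(seq, 4).tolist()}")
    return replace(rep, passed=rep.passed and ok_monotone)


def full_largeQ_neff() -> OracleReport:
    """n_eff of the Full S* response approaches the closed-form limit."""
    p = reference_parameters("unsaturated")
    limit = analytics.neff_full_largeQ_limit(p.delta1, p.delta2)
    seq = [_neff_at_Q(ModelVariant.FULL, Q) for Q in (200.0, 2000.0, 20000.0)]
    gaps = [abs(v - limit) for v in seq]
    ok_monotone = all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))
    rep = _report("full_largeQ_neff", seq[-1], limit, 0.01,
                  detail=f"sequence {np.round(seq, 4).tolist()}")
    return replace(rep, passed=rep.passed and ok_monotone)


def chain_truncation_convergence() -> OracleReport:
    """r50/n_eff of the representative chain model converge by ell = 50."""
    p = reference_parameters("unsaturated")
    cp = ChainModelParams(rates=p, ell=8, degradation_threshold=4)
    ell = choose_truncation(REPRESENTATIVE, cp, tol=0.01, n_points=60)
    return _report("chain_truncation_convergence", ell, 50, 0.0,
                   comparison="le", detail="converged truncation length")


# scaled-turnover conditions for the stochastic cross-check: hundredfold
# faster turnover shortens the relaxation time while keeping [S]_T and the
# saturation level; the E3 release rate for the processive mode is raised
# so chains stay well inside the deterministic truncation
def _stochastic_conditions(e3_mode: str):
    base = reference_parameters("unsaturated").replace(
        delta1=2e-3, delta2=2e-2, Q=2.0, D_total=1.0)
    if e3_mode == "processive":
        return base.replace(k_minus_M=0.1), 60
    return base, 30


def stochastic_ode_equivalence(n_seeds: int = 6) -> OracleReport:
    """Unbounded-chain SSA matches the truncated ODE within 3 SE."""
    rates, ell = _stochastic_conditions(REPRESENTATIVE.e3_mode.value)
    pr = with_input_ratio(rates, 200.0)
    cp = ChainModelParams(rates=pr, ell=ell, degradation_threshold=4)
    res = find_steady_state(build_chain_model(REPRESENTATIVE, cp),
                            enzyme_warning=False)
    ode = modified_fraction_chain(res.state, 4, ell)
    means = replicate_sstar_means(REPRESENTATIVE, cp, omega=10.0,
                                  seeds=range(101, 101 + n_seeds))
    sem = means.std(ddof=1) / np.sqrt(len(means))
    rep = _report("stochastic_ode_equivalence", float(means.mean()), ode,
                  3.0 * sem, comparison="abs",
                  detail=f"{n_seeds} replicates, omega=10, 3*SEM={3 * sem:.2g}")
    return rep


def two_substrate_reduction() -> OracleReport:
    """With Q2 = 0 the shared-enzyme pair reduces to one Full model."""
    p = with_input_ratio(reference_parameters("unsaturated"), 10.0)
    multi = build_multisubstrate_model(two_substrate_params(p, Q2=0.0))
    single = build_single_site(ModelVariant.FULL, p)
    st_multi = substrate_i_total(
        find_steady_state(multi, enzyme_warning=False).state, 1)
    st_single = single.substrate_total(
        find_steady_state(single, enzyme_warning=False).state)
    return _report("two_substrate_reduction", st_multi, st_single, 1e-6)


def semianalytic_r50_overlay() -> OracleReport:
    """Large-Q2 r50([S1]_T) from full scans matches the alpha2 formula."""
    p = reference_parameters("unsaturated")
    params = two_substrate_params(p, Q2=0.0)
    q2 = 5000.0 * p.Q  # deep in the linear regime
    scan = coupling_scan(params, np.array([q2]), fixed_r=100.0)
    s1 = params.substrates[0]
    semi = analytics.r50_multisubstrate_largeQ2(
        s1.delta1, s1.delta2, p.kcat_D * p.D_total,
        float(scan.alpha2[0]), q2)
    return _report("semianalytic_r50_overlay", float(scan.r50_S1T[0]), semi,
                   0.05, detail=f"Q2 = {q2:g} nM/s, alpha2 = {scan.alpha2[0]:.4f}")


ORACLES = {
    "closed_form_vs_numeric_r50": closed_form_vs_numeric_r50,
    "gk_symmetry_r50": gk_symmetry_r50,
    "intermediate_mass_balance": intermediate_mass_balance,
    "full_model_bounds": full_model_bounds,
    "intermediate_largeQ_neff": intermediate_largeQ_neff,
    "full_largeQ_neff": full_largeQ_neff,
    "chain_truncation_convergence": chain_truncation_convergence,
    "stochastic_ode_equivalence": stochastic_ode_equivalence,
    "two_substrate_reduction": two_substrate_reduction,
    "semianalytic_r50_overlay": semianalytic_r50_overlay,
}


def run_oracles(selection=None) -> list[OracleReport]:
    """Run the named oracles (all of them by default)."""
    if selection is None:
        selection = list(ORACLES)
    if not selection:
        raise ValueError("selection must be non-empty")
    reports = []
    for name in selection:
        if name not in ORACLES:
            raise KeyError(f"unknown oracle {name!r}")
        try:
            reports.append(ORACLES[name]())
        except Exception as exc:  # noqa: BLE001 - reported, not raised
            reports.append(OracleReport(
                check_id=name, computed=float("nan"), reference=float("nan"),
                tolerance=0.0, comparison="rel", passed=False,
                detail=f"{type(exc).__name__}: {exc}"))
    return reports
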