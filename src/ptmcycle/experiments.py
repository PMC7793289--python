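"""End-to-end computational experiments and their summary tables.

Each experiment composes the model modules into one of the package's
headline analyses and writes plain CSV/JSON outputs (plus an optional
quick line plot) into an output directory:

* ``fig2_saturation`` — GK/Intermediate/Full dose-response metrics in the
  unsaturated vs saturated regimes, saturating either through the
  synthesis rate Q or through the Michaelis constant K_M;
* ``fig3_chain``     — Full vs representative chain model across a Q ladder;
* ``fig4_crosstalk`` — overexpression coupling through a shared E3/DUB pair;
* ``limits_table``   — closed-form limits next to their numeric approach;
* ``robustness_sweep`` — metric signs over a log-uniform parameter ensemble;
* ``db_stats``       — substrate-load statistics of a synthetic network.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytics
from .io import reference_parameters
from .multisite import (ChainModelParams, REPRESENTATIVE,
                        chain_response_family)
from .multisubstrate import coupling_scan, two_substrate_params
from .response_metrics import compute_metrics
from .single_site import ModelVariant, as_variant, response_family
from .steady_state import scan_response
from .synthetic_data import (ParameterEnsemble, generate_network,
                             load_statistics, sample_ensemble, substrate_load)

__all__ = ["ExperimentSpec", "run_experiment", "EXPERIMENT_TAGS"]

EXPERIMENT_TAGS = ("fig2_saturation", "fig3_chain", "fig4_crosstalk",
                   "limits_table", "robustness_sweep", "db_stats")


@dataclass(frozen=True)
class ExperimentSpec:
    tag: str
    out_dir: Path = Path("ptm_results")
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tag not in EXPERIMENT_TAGS:
            raise ValueError(f"unknown experiment {self.tag!r}; "
                             f"choose from {EXPERIMENT_TAGS}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))


def _metrics_row(variant, params, observable, n_points, **extra) -> dict:
    fam = response_family(variant, params, observable)
    m = compute_metrics(scan_response(fam, n_points=n_points))
    return {"variant": ModelVariant(variant).value, "observable": observable,
            "Q": params.Q, "K_M": params.K_M_D,
            "r50": m.r50, "n_eff": m.n_eff, **extra}


def _fig2_saturation(spec: ExperimentSpec) -> dict:
    n_points = int(spec.overrides.get("n_points", 120))
    rows = []
    for regime in ("unsaturated", "saturated_Q", "saturated_KM"):
        p = reference_parameters(regime)
        s_total = 1e5 if regime == "saturated_Q" else 1e3
        for variant in ModelVariant:
            pv = as_variant(p, variant)
            if variant is ModelVariant.GK:
                fam = response_family(variant, pv, S_total=s_total)
                m = compute_metrics(scan_response(fam, n_points=n_points))
                rows.append({"variant": variant.value,
                             "observable": "sstar_fraction", "Q": p.Q,
                             "K_M": p.K_M_D, "r50": m.r50, "n_eff": m.n_eff,
                             "regime": regime})
            else:
                rows.append(_metrics_row(variant, pv, "sstar_fraction",
                                         n_points, regime=regime))
    return {"metrics": pd.DataFrame(rows)}


def _fig3_chain(spec: ExperimentSpec) -> dict:
    n_points = int(spec.overrides.get("n_points", 100))
    q_ladder = spec.overrides.get("q_ladder", (2e-2, 2e-1, 2.0))
    ell = int(spec.overrides.get("ell", 16))
    rows = []
    for Q in q_ladder:
        p = reference_parameters("unsaturated").replace(Q=Q)
        for obs in ("sstar_fraction", "s_total"):
            rows.append({**_metrics_row(ModelVariant.FULL, p, obs, n_points),
                         "model": "full"})
            cp = ChainModelParams(rates=p, ell=ell, degradation_threshold=4)
            fam = chain_response_family(REPRESENTATIVE, cp, obs)
            m = compute_metrics(scan_response(fam, n_points=n_points))
            rows.append({"variant": "CHAIN", "observable": obs, "Q": Q,
                         "K_M": p.K_M_D, "r50": m.r50, "n_eff": m.n_eff,
                         "model": str(REPRESENTATIVE)})
    return {"metrics": pd.DataFrame(rows)}


def _fig4_crosstalk(spec: ExperimentSpec) -> dict:
    p = reference_parameters("unsaturated")
    fixed_r = float(spec.overrides.get("fixed_r", 100.0))
    # single-substrate analogue: [S]_T against its own synthesis rate
    from .single_site import build_single_site, with_input_ratio
    from .steady_state import find_steady_state
    q_grid = np.geomspace(1e-3, 1e3, int(spec.overrides.get("n_q", 25))) * p.Q
    st = []
    for q in q_grid:
        m = build_single_site(ModelVariant.FULL,
                              with_input_ratio(p.replace(Q=q), fixed_r))
        st.append(m.substrate_total(
            find_steady_state(m, enzyme_warning=False).state))
    single = pd.DataFrame({"Q": q_grid, "S_total": st})
    # two substrates sharing the E3/DUB pair
    q2_grid = np.geomspace(1e-2, 1e3, int(spec.overrides.get("n_q2", 7))) * p.Q
    scan = coupling_scan(two_substrate_params(p, Q2=0.0), q2_grid,
                         fixed_r=fixed_r)
    coupling = scan.to_frame()
    coupling["r50_semianalytic"] = scan.semianalytic_r50(
        p.kcat_D * p.D_total, p.delta1, p.delta2)
    return {"single_substrate": single, "coupling": coupling}


def _limits_table(spec: ExperimentSpec) -> dict:
    p = reference_parameters("unsaturated")
    pi = as_variant(p, ModelVariant.INTERMEDIATE)
    from .response_metrics import r_at_level
    from .steady_state import scan_response as scan
    n_points = int(spec.overrides.get("n_points", 120))
    big_Q = float(spec.overrides.get("big_Q", 2000.0))

    def neff(variant, Q):
        pv = as_variant(p.replace(Q=Q), variant)
        return compute_metrics(
            scan(response_family(variant, pv), n_points=n_points)).n_eff

    curve_i = scan(response_family(ModelVariant.INTERMEDIATE, pi),
                   n_points=n_points)
    rows = [
        {"quantity": "r50_intermediate_closed_form",
         "analytic": analytics.r50_intermediate_closed_form(
             p.kcat_D, p.delta1, p.Q, p.K_M_D, p.D_total),
         "numeric": r_at_level(curve_i, 0.5)},
        {"quantity": "r50_intermediate_km_limit",
         "analytic": analytics.r50_intermediate_km_limit(
             p.kcat_D, p.delta1, p.Q, p.D_total),
         "numeric": float("nan")},
        {"quantity": "neff_intermediate_largeQ",
         "analytic": analytics.neff_intermediate_largeQ_limit,
         "numeric": neff(ModelVariant.INTERMEDIATE, big_Q)},
        {"quantity": "neff_full_largeQ",
         "analytic": analytics.neff_full_largeQ_limit(p.delta1, p.delta2),
         "numeric": neff(ModelVariant.FULL, big_Q)},
    ]
    return {"limits": pd.DataFrame(rows)}


def _robustness_sweep(spec: ExperimentSpec) -> dict:
    n = int(spec.overrides.get("n", 8))
    n_points = int(spec.overrides.get("n_points", 80))
    base = reference_parameters("unsaturated")
    ens = sample_ensemble(ParameterEnsemble(base=base, n=n, seed=spec.seed))
    rows = []
    for i, draw in enumerate(ens):
        for obs in ("sstar_fraction", "s_total"):
            m_un = compute_metrics(scan_response(
                response_family(ModelVariant.FULL, draw, obs),
                n_points=n_points))
            m_sat = compute_metrics(scan_response(
                response_family(ModelVariant.FULL,
                                draw.replace(Q=100.0 * draw.Q), obs),
                n_points=n_points))
            rows.append({"draw": i, "observable": obs,
                         "K_M": draw.K_M_D, "delta1": draw.delta1,
                         "delta2": draw.delta2,
                         "r50_unsat": m_un.r50, "r50_sat": m_sat.r50,
                         "saturation_raises_r50": m_sat.r50 > m_un.r50})
    return {"sweep": pd.DataFrame(rows)}


def _db_stats(spec: ExperimentSpec) -> dict:
    n_ligases = int(spec.overrides.get("n_ligases", 415))
    table = generate_network(n_ligases, seed=spec.seed)
    stats = load_statistics(table)
    stats["printed_load_e3net"] = substrate_load(873, 415)
    stats["printed_load_hubiquitome"] = substrate_load(279, 138)
    return {"network": table.edges,
            "stats": pd.DataFrame([stats])}


_RUNNERS = {
    "fig2_saturation": _fig2_saturation,
    "fig3_chain": _fig3_chain,
    "fig4_crosstalk": _fig4_crosstalk,
    "limits_table": _limits_table,
    "robustness_sweep": _robustness_sweep,
    "db_stats": _db_stats,
}


def run_experiment(spec: ExperimentSpec) -> dict:
    """Run one experiment; write its tables under ``spec.out_dir``.

    Returns the result tables keyed by name; a failure in a stage marks
    the written bundle as partial with the diagnostic recorded.
    """
    spec.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"tag": spec.tag, "seed": spec.seed,
                "overrides": {k: repr(v) for k, v in spec.overrides.items()},
                "status": "complete", "tables": []}
    tables: dict[str, pd.DataFrame] = {}
    try:
        tables = _RUNNERS[spec.tag](spec)
        for name, frame in tables.items():
            path = spec.out_dir / f"{spec.tag}_{name}.csv"
            frame.to_csv(path, index=False)
            manifest["tables"].append(path.name)
    except Exception as exc:  # noqa: BLE001 - recorded in the bundle
        manifest["status"] = "partial"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        (spec.out_dir / f"{spec.tag}_manifest.json").write_text(
            json.dumps(manifest, indent=2))
    return tables
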