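"""Several substrates sharing one E3/DUB pair: crosstalk through competition.

Each substrate is a Full-model cycle (one modification state, synthesis
Q_i, degradation delta1_i/delta2_i) but all substrates compete for the
same free M and D pools; a substrate molecule is occupied by at most one
enzyme at a time. The headline question: how do substrate 1's total level
and its sensitivity r50 respond when substrate 2 is overexpressed (its
synthesis rate Q2 raised)?
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._model import Conservation, ReactionModel
from .analytics import r50_multisubstrate_largeQ2
from .response_metrics import compute_metrics, r_at_level
from .single_site import RateConstants
from .steady_state import ResponseFamily, find_steady_state, scan_response

__all__ = [
    "SubstrateKinetics",
    "MultiSubstrateParams",
    "CouplingScanResult",
    "build_multisubstrate_model",
    "multisubstrate_response_family",
    "two_substrate_params",
    "coupling_scan",
    "substrate_i_total",
    "modified_fraction_i",
]


@dataclass(frozen=True)
class SubstrateKinetics:
    """Per-substrate kinetic constants (shared-enzyme totals live outside)."""

    k_plus_M: float
    k_minus_M: float
    kcat_M: float
    k_plus_D: float
    k_minus_D: float
    kcat_D: float
    Q: float
    delta1: float
    delta2: float

    def __post_init__(self):
        if not self.delta2 > self.delta1 > 0:
            raise ValueError("each substrate requires delta2 > delta1 > 0")
        if self.Q < 0:
            raise ValueError("Q must be >= 0")

    @classmethod
    def from_rates(cls, rates: RateConstants, Q: float | None = None) -> "SubstrateKinetics":
        return cls(
            k_plus_M=rates.k_plus_M, k_minus_M=rates.k_minus_M, kcat_M=rates.kcat_M,
            k_plus_D=rates.k_plus_D, k_minus_D=rates.k_minus_D, kcat_D=rates.kcat_D,
            Q=rates.Q if Q is None else Q,
            delta1=rates.delta1, delta2=rates.delta2,
        )


@dataclass(frozen=True)
class MultiSubstrateParams:
    substrates: tuple[SubstrateKinetics, ...]
    M_total: float
    D_total: float

    def __post_init__(self):
        if len(self.substrates) < 1:
            raise ValueError("at least one substrate is required")
        if self.M_total < 0 or self.D_total < 0:
            raise ValueError("enzyme totals must be >= 0")

    @property
    def N(self) -> int:
        return len(self.substrates)

    def input_ratio(self) -> float:
        """r = kcat_M [M]_T / (kcat_D [D]_T), using substrate 1's catalytic rates."""
        s1 = self.substrates[0]
        return s1.kcat_M * self.M_total / (s1.kcat_D * self.D_total)

    def with_input_ratio(self, r: float) -> "MultiSubstrateParams":
        s1 = self.substrates[0]
        return replace(self, M_total=r * s1.kcat_D * self.D_total / s1.kcat_M)

    def with_Q(self, i: int, Q: float) -> "MultiSubstrateParams":
        subs = list(self.substrates)
        subs[i] = replace(subs[i], Q=Q)
        return replace(self, substrates=tuple(subs))


def two_substrate_params(
    rates: RateConstants, Q2: float, Q1: float | None = None
) -> MultiSubstrateParams:
    """Two identical substrates (the display case), differing only in Q."""
    s1 = SubstrateKinetics.from_rates(rates, Q=Q1)
    s2 = SubstrateKinetics.from_rates(rates, Q=Q2)
    return MultiSubstrateParams(
        substrates=(s1, s2), M_total=rates.M_total, D_total=rates.D_total
    )


def build_multisubstrate_model(params: MultiSubstrateParams) -> ReactionModel:
    """Compile the shared-enzyme model.

    State layout: ``[S_i, Sstar_i, MS_i, DSstar_i] for i = 1..N`` followed
    by ``[M_free, D_free]``. Reactions per substrate are exactly those of
    the Full single-site model; with N = 1 the system reduces to it.
    """
    N = params.N
    iMF, iDF = 4 * N, 4 * N + 1
    subs = params.substrates

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        Mf = y[iMF]
        Df = y[iDF]
        out = np.empty_like(y)
        dMf = 0.0
        dDf = 0.0
        for i, p in enumerate(subs):
            S, Sstar, MS, DS = y[4 * i: 4 * i + 4]
            bM = p.k_plus_M * S * Mf
            uM = p.k_minus_M * MS
            cM = p.kcat_M * MS
            bD = p.k_plus_D * Sstar * Df
            uD = p.k_minus_D * DS
            cD = p.kcat_D * DS
            out[4 * i] = p.Q - bM + uM + cD - p.delta1 * S
            out[4 * i + 1] = cM - bD + uD - p.delta2 * Sstar
            out[4 * i + 2] = bM - uM - cM - p.delta1 * MS
            out[4 * i + 3] = bD - uD - cD - p.delta2 * DS
            dMf += -bM + uM + cM + p.delta1 * MS
            dDf += -bD + uD + cD + p.delta2 * DS
        out[iMF] = dMf
        out[iDF] = dDf
        return out

    cM = np.zeros(4 * N + 2)
    cM[2:4 * N:4] = 1.0
    cM[iMF] = 1.0
    cD = np.zeros(4 * N + 2)
    cD[3:4 * N:4] = 1.0
    cD[iDF] = 1.0
    y0 = np.zeros(4 * N + 2)
    y0[iMF] = params.M_total
    y0[iDF] = params.D_total

    species = tuple(
        f"{name}_{i + 1}"
        for i in range(N)
        for name in ("S", "Sstar", "MS", "DSstar")
    ) + ("M_free", "D_free")
    return ReactionModel(
        rhs=rhs,
        species=species,
        conservations=(Conservation(cM, pivot=iMF), Conservation(cD, pivot=iDF)),
        default_initial=y0,
        substrate_indices=np.arange(4 * N),
        enzyme_totals=(params.M_total, params.D_total),
        meta={"params": params},
    )


def substrate_i_total(y: np.ndarray, i: int) -> float:
    """[S_i]_T = S_i + S*_i + MS_i + DS*_i (1-based substrate index)."""
    i -= 1
    return float(np.asarray(y, dtype=float)[4 * i: 4 * i + 4].sum())


def modified_fraction_i(y: np.ndarray, i: int) -> float:
    """Modified molar fraction of substrate i: [S*_i]/[S_i]_T (free species)."""
    tot = substrate_i_total(y, i)
    if tot <= 1e-12:  # empty up to solver dust
        return float("nan")
    return float(np.asarray(y, dtype=float)[4 * (i - 1) + 1] / tot)


def multisubstrate_response_family(
    params: MultiSubstrateParams, observable: str = "s1_total"
) -> ResponseFamily:
    """[S1]_T (or substrate 1's S* fraction) against the shared input ratio r."""
    s1 = params.substrates[0]

    def build(r: float) -> ReactionModel:
        return build_multisubstrate_model(params.with_input_ratio(r))

    if observable == "s1_total":
        observe = lambda y: substrate_i_total(y, 1)
        asym = (s1.Q / s1.delta1, s1.Q / s1.delta2)
        tag = "s_total"
    elif observable == "s1_star":
        observe = lambda y: modified_fraction_i(y, 1)
        asym = (0.0, 1.0)
        tag = "sstar_fraction"
    else:
        raise ValueError("observable must be 's1_total' or 's1_star'")
    return ResponseFamily(build=build, observe=observe, asymptotes=asym,
                          observable_tag=tag)


@dataclass
class CouplingScanResult:
    """Crosstalk summary: substrate 1's level and sensitivity vs Q2."""

    Q2_grid: np.ndarray
    S1_total: np.ndarray       # at the fixed input ratio, nM
    r50_S1T: np.ndarray        # r50 of the [S1]_T transition per Q2
    alpha2: np.ndarray         # modified fraction of S2 at the r50 point
    fixed_r: float
    meta: dict = field(default_factory=dict)

    def semianalytic_r50(self, Vmax_D: float, delta1: float, delta2: float) -> np.ndarray:
        """Semi-analytic r50 curve from the measured alpha2 values."""
        return np.array([
            r50_multisubstrate_largeQ2(delta1, delta2, Vmax_D, a, q2)
            for a, q2 in zip(self.alpha2, self.Q2_grid)
        ])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Q2": self.Q2_grid, "S1_total": self.S1_total,
            "r50_S1T": self.r50_S1T, "alpha2": self.alpha2,
        })

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {"fixed_r": self.fixed_r,
                   "meta": {k: repr(v) for k, v in self.meta.items()}}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))


def coupling_scan(
    params: MultiSubstrateParams,
    Q2_grid: np.ndarray,
    fixed_r: float = 100.0,
    *,
    extract_r50: bool = True,
    n_points: int = 120,
) -> CouplingScanResult:
    """Crosstalk scan over the competitor's synthesis rate Q2.

    For each Q2: (a) solve the shared-enzyme steady state at ``fixed_r``
    and record [S1]_T; (b) independently scan r to extract the r50 of the
    [S1]_T transition (dynamic-range normalization) and the modified
    fraction alpha2 of substrate 2 at that point.
    """
    Q2_grid = np.asarray(Q2_grid, dtype=float)
    if np.any(np.diff(Q2_grid) <= 0):
        raise ValueError("Q2_grid must be ascending")
    s1tot = np.empty_like(Q2_grid)
    r50s = np.full_like(Q2_grid, np.nan)
    alpha2 = np.full_like(Q2_grid, np.nan)
    for j, q2 in enumerate(Q2_grid):
        pj = params.with_Q(1, q2).with_input_ratio(fixed_r)
        res = find_steady_state(build_multisubstrate_model(pj),
                                enzyme_warning=False)
        s1tot[j] = substrate_i_total(res.state, 1)
        if extract_r50:
            fam = multisubstrate_response_family(params.with_Q(1, q2))
            curve = scan_response(fam, n_points=n_points)
            r50 = r_at_level(curve, 0.5)
            r50s[j] = r50
            state = find_steady_state(
                build_multisubstrate_model(
                    params.with_Q(1, q2).with_input_ratio(r50)),
                enzyme_warning=False,
            ).state
            alpha2[j] = modified_fraction_i(state, 2)
    return CouplingScanResult(
        Q2_grid=Q2_grid, S1_total=s1tot, r50_S1T=r50s, alpha2=alpha2,
        fixed_r=fixed_r, meta={"params": params},
    )
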