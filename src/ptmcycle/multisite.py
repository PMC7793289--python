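"""Polyubiquitin-chain models: one substrate, many modification states.

A substrate carries a chain of k = 0..ell ubiquitins. The E3 ligase (M)
extends chains, the DUB (D) shortens them, and the proteasome degrades
every form — slowly (delta1) below the recognition threshold (four
ubiquitins by default) and fast (delta2) at or above it. Enzyme
mechanisms combine freely:

* E3: ``processive`` (stays bound while adding ubiquitins one catalytic
  step at a time) or ``distributive`` (releases the substrate after each
  addition);
* DUB: ``distributive_sequential`` (removes one ubiquitin, releases),
  ``processive_sequential`` (trims the chain stepwise while bound), or
  ``distributive_base`` (cleaves at the base, removing the whole chain).

Chain growth is truncated at a maximum length ell; ``choose_truncation``
doubles ell until the extracted r50 and n_eff stop moving, and the
stochastic simulator (no truncation) provides an independent check.
Catalytic rates are chain-length independent.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from ._model import Conservation, ReactionModel
from .single_site import RateConstants, with_input_ratio
from .steady_state import ResponseFamily, scan_response
from .response_metrics import compute_metrics

__all__ = [
    "E3Mode",
    "DubMode",
    "MechanismSpec",
    "ChainModelParams",
    "build_chain_model",
    "modified_fraction_chain",
    "substrate_total_chain",
    "chain_response_family",
    "choose_truncation",
    "all_mechanisms",
]


class E3Mode(str, enum.Enum):
    PROCESSIVE = "processive"
    DISTRIBUTIVE = "distributive"


class DubMode(str, enum.Enum):
    DISTRIBUTIVE_SEQUENTIAL = "distributive_sequential"
    PROCESSIVE_SEQUENTIAL = "processive_sequential"
    DISTRIBUTIVE_BASE = "distributive_base"


@dataclass(frozen=True)
class MechanismSpec:
    """Selector for the E3 mode x DUB mode combination."""

    e3_mode: E3Mode = E3Mode.PROCESSIVE
    dub_mode: DubMode = DubMode.DISTRIBUTIVE_SEQUENTIAL

    def __post_init__(self):
        object.__setattr__(self, "e3_mode", E3Mode(self.e3_mode))
        object.__setattr__(self, "dub_mode", DubMode(self.dub_mode))

    def __str__(self) -> str:
        return f"{self.e3_mode.value}+{self.dub_mode.value}"


#: the representative, experimentally best-supported case
REPRESENTATIVE = MechanismSpec(E3Mode.PROCESSIVE, DubMode.DISTRIBUTIVE_SEQUENTIAL)


def all_mechanisms() -> list[MechanismSpec]:
    """All six E3 x DUB mechanism combinations."""
    return [MechanismSpec(e, d) for e in E3Mode for d in DubMode]


@dataclass(frozen=True)
class ChainModelParams:
    """Chain-model parameters: base kinetics plus chain geometry.

    ``degradation_threshold`` is the chain length at which fast (delta2)
    degradation begins; states below it degrade at delta1. ``ell`` is the
    truncation length of the deterministic model.
    """

    rates: RateConstants
    ell: int = 50
    degradation_threshold: int = 4

    def __post_init__(self):
        if self.degradation_threshold < 1:
            raise ValueError("degradation_threshold must be >= 1")
        if self.ell < self.degradation_threshold:
            raise ValueError("ell must be >= degradation_threshold")
        if not self.rates.delta2 > self.rates.delta1 > 0:
            raise ValueError("chain models require delta2 > delta1 > 0")
        if self.rates.Q < 0:
            raise ValueError("Q must be >= 0")

    def with_input_ratio(self, r: float) -> "ChainModelParams":
        return replace(self, rates=with_input_ratio(self.rates, r))


def _indices(ell: int):
    n = ell + 1
    return n, slice(0, n), slice(n, 2 * n), slice(2 * n, 3 * n), 3 * n, 3 * n + 1


def build_chain_model(
    mech: MechanismSpec,
    params: ChainModelParams,
    *,
    complex_degradation: str = "state",
) -> ReactionModel:
    """Compile a chain model into a :class:`ReactionModel`.

    State layout: ``[S_0..S_ell, MS_0..MS_ell, DS_0..DS_ell, M_free,
    D_free]``. The E3 binds free substrate with k < ell (the cap carries
    no further extension), the DUB binds free substrate with k > 0; each
    substrate molecule is bound by at most one enzyme at a time.
    Degradation of any form removes the substrate at the rate of its chain
    state and frees a bound enzyme.
    """
    if not isinstance(mech, MechanismSpec):
        mech = MechanismSpec(*mech)
    if complex_degradation not in ("state", "uniform"):
        raise ValueError("complex_degradation must be 'state' or 'uniform'")
    p = params.rates
    ell, thr = params.ell, params.degradation_threshold
    n, sS, sMS, sDS, iMF, iDF = _indices(ell)

    kpM, kmM, kcM = p.k_plus_M, p.k_minus_M, p.kcat_M
    kpD, kmD, kcD = p.k_plus_D, p.k_minus_D, p.kcat_D
    Q = p.Q
    deg = np.where(np.arange(n) < thr, p.delta1, p.delta2)
    deg_c = deg if complex_degradation == "state" else np.full(n, p.delta1)
    e3_processive = mech.e3_mode is E3Mode.PROCESSIVE
    dub = mech.dub_mode

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        S = y[sS]
        MS = y[sMS]
        DS = y[sDS]
        Mf = y[iMF]
        Df = y[iDF]

        bindM = kpM * Mf * S
        bindM[ell] = 0.0  # no extension from the cap
        bindD = kpD * Df * S
        bindD[0] = 0.0    # nothing to remove from a bare substrate
        unbM = kmM * MS
        unbD = kmD * DS
        catM = kcM * MS
        catM[ell] = 0.0
        catD = kcD * DS
        catD[0] = 0.0

        dS = -bindM - bindD + unbM + unbD - deg * S
        dS[0] += Q
        dMS = bindM - unbM - deg_c * MS - catM
        dDS = bindD - unbD - deg_c * DS - catD
        dMf = -bindM.sum() + unbM.sum() + deg_c @ MS
        dDf = -bindD.sum() + unbD.sum() + deg_c @ DS

        if e3_processive:
            dMS[1:] += catM[:-1]
        else:
            dS[1:] += catM[:-1]
            dMf += catM.sum()

        if dub is DubMode.DISTRIBUTIVE_SEQUENTIAL:
            dS[:-1] += catD[1:]
            dDf += catD.sum()
        elif dub is DubMode.PROCESSIVE_SEQUENTIAL:
            dDS[:-1] += catD[1:]
        else:  # DISTRIBUTIVE_BASE: whole-chain removal
            dS[0] += catD.sum()
            dDf += catD.sum()

        out = np.empty(3 * n + 2)
        out[sS] = dS
        out[sMS] = dMS
        out[sDS] = dDS
        out[iMF] = dMf
        out[iDF] = dDf
        return out

    cM = np.zeros(3 * n + 2)
    cM[sMS] = 1.0
    cM[iMF] = 1.0
    cD = np.zeros(3 * n + 2)
    cD[sDS] = 1.0
    cD[iDF] = 1.0

    y0 = np.zeros(3 * n + 2)
    y0[iMF] = p.M_total
    y0[iDF] = p.D_total

    species = (
        tuple(f"S_{k}" for k in range(n))
        + tuple(f"MS_{k}" for k in range(n))
        + tuple(f"DS_{k}" for k in range(n))
        + ("M_free", "D_free")
    )
    return ReactionModel(
        rhs=rhs,
        species=species,
        conservations=(
            Conservation(cM, pivot=iMF),
            Conservation(cD, pivot=iDF),
        ),
        default_initial=y0,
        substrate_indices=np.arange(3 * n),
        enzyme_totals=(p.M_total, p.D_total),
        meta={"mechanism": mech, "params": params,
              "complex_degradation": complex_degradation},
    )


def substrate_total_chain(y: np.ndarray, ell: int) -> float:
    return float(np.asarray(y, dtype=float)[: 3 * (ell + 1)].sum())


def modified_fraction_chain(y: np.ndarray, threshold: int, ell: int | None = None) -> float:
    """S* = sum over chain lengths k >= threshold of all forms / [S]_T.

    Counts every substrate molecule by its chain length — free and
    enzyme-bound alike. Returns nan (missing) for an empty system.
    """
    y = np.asarray(y, dtype=float)
    if ell is None:
        ell = (len(y) - 2) // 3 - 1
    n = ell + 1
    total = y[: 3 * n].sum()
    if total <= 1e-12:  # empty up to solver dust
        return float("nan")
    mask = np.arange(n) >= threshold
    above = y[:n][mask].sum() + y[n:2 * n][mask].sum() + y[2 * n:3 * n][mask].sum()
    return float(above / total)


def chain_response_family(
    mech: MechanismSpec,
    params: ChainModelParams,
    observable_tag: str = "sstar_fraction",
    **model_kw,
) -> ResponseFamily:
    """Dose-response family (observable vs r) for a chain model.

    ``sstar_fraction``: modified fraction (asymptotes 0 and 1);
    ``s_total``: total substrate (asymptotes Q/delta1 and Q/delta2).
    """
    p = params.rates
    ell, thr = params.ell, params.degradation_threshold

    def build(r: float) -> ReactionModel:
        return build_chain_model(mech, params.with_input_ratio(r), **model_kw)

    if observable_tag == "sstar_fraction":
        observe = lambda y: modified_fraction_chain(y, thr, ell)
        asym = (0.0, 1.0)
    elif observable_tag == "s_total":
        observe = lambda y: substrate_total_chain(y, ell)
        asym = (p.Q / p.delta1, p.Q / p.delta2)
    else:
        raise ValueError("observable_tag must be 'sstar_fraction' or 's_total'")
    fam = ResponseFamily(build=build, observe=observe, asymptotes=asym,
                         observable_tag=observable_tag)
    fam.meta = {"mechanism": str(mech), "ell": ell, "threshold": thr}
    return fam


def choose_truncation(
    mech: MechanismSpec,
    params: ChainModelParams,
    *,
    tol: float = 0.01,
    max_ell: int = 1024,
    n_points: int = 80,
    observable_tag: str = "sstar_fraction",
) -> int:
    """Smallest chain truncation at which r50 and n_eff have converged.

    Doubles ell upward from the degradation threshold until both metrics
    change by less than ``tol`` (relative) between successive truncations.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ell = max(2 * params.degradation_threshold, 8)
    prev = None
    while ell <= max_ell:
        pp = replace(params, ell=ell)
        curve = scan_response(
            chain_response_family(mech, pp, observable_tag), n_points=n_points
        )
        m = compute_metrics(curve)
        if prev is not None:
            dr = abs(m.r50 - prev.r50) / prev.r50
            dn = abs(m.n_eff - prev.n_eff) / prev.n_eff
            if dr < tol and dn < tol:
                return ell
        prev = m
        ell *= 2
    raise RuntimeError(
        f"chain truncation did not converge by ell = {max_ell} "
        f"(last r50 = {prev.r50:.4g}, n_eff = {prev.n_eff:.4g})"
    )
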