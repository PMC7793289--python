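"""Single-substrate, single-modification-state PTM cycle models.

Three nested model variants of a covalent-modification cycle in which a
modifying enzyme M (e.g. a kinase or an E3 ligase) converts substrate S to
S* and a demodifying enzyme D (a phosphatase or a DUB) reverses it, with
binding, dissociation and catalysis treated explicitly:

* ``GK`` — the classic Goldbeter–Koshland loop: no synthesis, no
  degradation; total substrate is conserved.
* ``INTERMEDIATE`` — adds synthesis of S at a constant rate Q (nM/s) and
  first-order degradation of every substrate-containing form at delta1.
  At steady state total substrate is pinned at Q/delta1.
* ``FULL`` — the modification tags the substrate for faster turnover:
  modified forms degrade at delta2 > delta1, so total substrate moves
  between Q/delta1 (low M activity) and Q/delta2 (high M activity).

Degradation of an enzyme-substrate complex removes only the substrate and
releases the free enzyme; enzymes themselves are neither synthesized nor
degraded. Units are nM and seconds throughout.
"""
from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._model import Conservation, ReactionModel

__all__ = [
    "ModelVariant",
    "RateConstants",
    "SingleSiteState",
    "VariantConstraintError",
    "build_single_site",
    "input_ratio",
    "michaelis_constant",
    "observables",
    "response_family",
    "as_variant",
    "with_input_ratio",
    "SPECIES",
]

#: state-vector order shared by every single-site model
SPECIES = ("S_free", "Sstar_free", "MS_complex", "DSstar_complex", "M_free", "D_free")
_S, _SSTAR, _MS, _DS, _MF, _DF = range(6)


class ModelVariant(str, enum.Enum):
    GK = "GK"
    INTERMEDIATE = "INTERMEDIATE"
    FULL = "FULL"


class VariantConstraintError(ValueError):
    """Parameter set violates the constraint pattern of a model variant."""


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the single-site models.

    Association rates ``k_plus_*`` are bimolecular (nM^-1 s^-1);
    dissociation ``k_minus_*`` and catalytic ``kcat_*`` rates are s^-1.
    ``Q`` is the zeroth-order substrate synthesis rate (nM/s), ``delta1``
    and ``delta2`` the degradation rates (s^-1) of unmodified and modified
    forms, and ``M_total``/``D_total`` the conserved enzyme pools (nM).
    """

    k_plus_M: float
    k_minus_M: float
    kcat_M: float
    k_plus_D: float
    k_minus_D: float
    kcat_D: float
    Q: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0
    M_total: float = 0.0
    D_total: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def K_M_M(self) -> float:
        return michaelis_constant(self.k_plus_M, self.k_minus_M, self.kcat_M)

    @property
    def K_M_D(self) -> float:
        return michaelis_constant(self.k_plus_D, self.k_minus_D, self.kcat_D)

    @property
    def Vmax_M(self) -> float:
        return self.kcat_M * self.M_total

    @property
    def Vmax_D(self) -> float:
        return self.kcat_D * self.D_total

    def replace(self, **kw) -> "RateConstants":
        return replace(self, **kw)


# SingleSiteState is just a named view over the 6-vector; models operate on
# raw numpy arrays for speed.
@dataclass(frozen=True)
class SingleSiteState:
    S_free: float
    Sstar_free: float
    MS_complex: float
    DSstar_complex: float
    M_free: float
    D_free: float

    @classmethod
    def from_array(cls, y) -> "SingleSiteState":
        return cls(*np.asarray(y, dtype=float))

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.S_free, self.Sstar_free, self.MS_complex,
             self.DSstar_complex, self.M_free, self.D_free]
        )


def michaelis_constant(k_plus: float, k_minus: float, kcat: float) -> float:
    """K_M = (k_minus + kcat) / k_plus, in nM."""
    if k_plus <= 0:
        raise ValueError("k_plus must be > 0 for a finite Michaelis constant")
    return (k_minus + kcat) / k_plus


def input_ratio(params: RateConstants) -> float:
    """The signal axis r = kcat_M * [M]_T / (kcat_D * [D]_T) = Vmax_M / Vmax_D."""
    denom = params.kcat_D * params.D_total
    if denom <= 0:
        raise ValueError("input ratio undefined: kcat_D * D_total must be > 0")
    return params.kcat_M * params.M_total / denom


def with_input_ratio(params: RateConstants, r: float) -> RateConstants:
    """Return a copy with M_total adjusted so that input_ratio(result) == r."""
    if r < 0:
        raise ValueError("r must be >= 0")
    if params.kcat_M <= 0:
        raise ValueError("cannot set the input ratio when kcat_M = 0")
    m_total = r * params.kcat_D * params.D_total / params.kcat_M
    return replace(params, M_total=m_total)


def as_variant(params: RateConstants, variant: ModelVariant) -> RateConstants:
    """Project a parameter set onto a variant's constraint pattern.

    GK zeroes all turnover; INTERMEDIATE sets delta2 = delta1; FULL is
    returned unchanged.
    """
    variant = ModelVariant(variant)
    if variant is ModelVariant.GK:
        return replace(params, Q=0.0, delta1=0.0, delta2=0.0)
    if variant is ModelVariant.INTERMEDIATE:
        return replace(params, delta2=params.delta1)
    return params


def _validate(variant: ModelVariant, p: RateConstants) -> None:
    if variant is ModelVariant.GK:
        if not (p.Q == 0 and p.delta1 == 0 and p.delta2 == 0):
            raise VariantConstraintError(
                "GK loop has no protein turnover: requires Q = delta1 = delta2 = 0"
            )
    elif variant is ModelVariant.INTERMEDIATE:
        if p.delta2 != p.delta1:
            raise VariantConstraintError(
                "Intermediate model degrades all forms uniformly: requires "
                f"delta2 == delta1 (got delta1={p.delta1}, delta2={p.delta2})"
            )
        if p.Q <= 0 or p.delta1 <= 0:
            raise VariantConstraintError(
                "Intermediate model requires Q > 0 and delta1 > 0"
            )
    elif variant is ModelVariant.FULL:
        if not (p.delta2 > p.delta1 > 0):
            raise VariantConstraintError(
                "Full model tags for faster degradation: requires "
                f"delta2 > delta1 > 0 (got delta1={p.delta1}, delta2={p.delta2})"
            )
        if p.Q <= 0:
            raise VariantConstraintError("Full model requires Q > 0")


def build_single_site(
    variant: ModelVariant,
    params: RateConstants,
    *,
    S_total: float | None = None,
    complex_degradation: str = "state",
) -> ReactionModel:
    """Compile a single-site variant into a :class:`ReactionModel`.

    Parameters
    ----------
    S_total
        Total substrate, required for the closed GK loop (which conserves
        it); ignored by the turnover variants, whose default initial state
        is the empty system.
    complex_degradation
        ``"state"`` (default): a complex degrades at the rate of the
        substrate state it carries (MS at delta1, DS* at delta2).
        ``"uniform"``: both complexes degrade at delta1.
    """
    variant = ModelVariant(variant)
    _validate(variant, params)
    if complex_degradation not in ("state", "uniform"):
        raise ValueError("complex_degradation must be 'state' or 'uniform'")

    p = params
    kpM, kmM, kcM = p.k_plus_M, p.k_minus_M, p.kcat_M
    kpD, kmD, kcD = p.k_plus_D, p.k_minus_D, p.kcat_D
    Q, d1, d2 = p.Q, p.delta1, p.delta2
    d_ms = d1
    d_ds = d2 if complex_degradation == "state" else d1

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        S, Sstar, MS, DS, Mf, Df = y
        bM = kpM * S * Mf
        uM = kmM * MS
        cM = kcM * MS
        bD = kpD * Sstar * Df
        uD = kmD * DS
        cD = kcD * DS
        return np.array([
            Q - bM + uM + cD - d1 * S,
            cM - bD + uD - d2 * Sstar,
            bM - uM - cM - d_ms * MS,
            bD - uD - cD - d_ds * DS,
            -bM + uM + cM + d_ms * MS,
            -bD + uD + cD + d_ds * DS,
        ])

    cons = [
        Conservation(np.array([0, 0, 1.0, 0, 1.0, 0]), pivot=_MF),
        Conservation(np.array([0, 0, 0, 1.0, 0, 1.0]), pivot=_DF),
    ]
    y0 = np.zeros(6)
    y0[_MF] = p.M_total
    y0[_DF] = p.D_total
    if variant is ModelVariant.GK:
        if S_total is None or S_total <= 0:
            raise VariantConstraintError(
                "GK loop conserves total substrate: S_total > 0 is required"
            )
        cons.append(Conservation(np.array([1.0, 1.0, 1.0, 1.0, 0, 0]), pivot=_S))
        y0[_S] = S_total
        if max(p.M_total, p.D_total) > 0.1 * S_total:
            warnings.warn(
                "enzyme totals exceed 10% of total substrate; the models "
                "assume the enzyme-limited (Michaelis-Menten) regime",
                stacklevel=2,
            )

    return ReactionModel(
        rhs=rhs,
        species=SPECIES,
        conservations=tuple(cons),
        default_initial=y0,
        substrate_indices=np.array([_S, _SSTAR, _MS, _DS]),
        enzyme_totals=(p.M_total, p.D_total),
        meta={"variant": variant.value, "params": p,
              "complex_degradation": complex_degradation},
    )


def response_family(
    variant: ModelVariant,
    params: RateConstants,
    observable_tag: str = "sstar_fraction",
    *,
    S_total: float | None = None,
    **model_kw,
):
    """Dose-response family (observable vs input ratio r) for a variant.

    ``sstar_fraction`` runs between 0 and 1 for every variant;
    ``s_total`` (Full model) runs from Q/delta1 down to Q/delta2.
    """
    from .steady_state import ResponseFamily  # local import: avoid cycle

    variant = ModelVariant(variant)
    p = params

    def build(r: float):
        return build_single_site(variant, with_input_ratio(p, r),
                                 S_total=S_total, **model_kw)

    if observable_tag == "sstar_fraction":
        observe = lambda y: observables(y)["Sstar_fraction"]
        asym = (0.0, 1.0)
    elif observable_tag == "s_total":
        if variant is ModelVariant.GK:
            raise ValueError("the GK loop conserves total substrate")
        asym = (p.Q / p.delta1, p.Q / p.delta2)
        observe = lambda y: observables(y)["S_total"]
    else:
        raise ValueError("observable_tag must be 'sstar_fraction' or 's_total'")
    fam = ResponseFamily(build=build, observe=observe, asymptotes=asym,
                         observable_tag=observable_tag)
    fam.meta = {"variant": variant.value}
    return fam


def observables(state) -> dict:
    """Total substrate and the modified molar fraction S* = [S*]/[S]_T.

    The numerator is the free modified species, following the literal
    definition; the enzyme-bound fraction is negligible in the supported
    enzyme-limited regime. Returns ``Sstar_fraction = nan`` (missing) when
    the system is empty.
    """
    if isinstance(state, SingleSiteState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    s_total = float(y[[_S, _SSTAR, _MS, _DS]].sum())
    frac = float(y[_SSTAR] / s_total) if s_total > 1e-12 else float("nan")
    return {"S_total": s_total, "Sstar_fraction": frac}
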