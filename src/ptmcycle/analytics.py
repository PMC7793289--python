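"""Closed-form sensitivity and ultrasensitivity expressions.

These are the analytic results for the turnover-coupled modification
cycle with equal modifying/demodifying kinetics; the numerical pipeline
uses them both as results in their own right and as oracles for the
scan-and-extract machinery.
"""
from __future__ import annotations

import math

__all__ = [
    "r50_gk",
    "r50_intermediate_closed_form",
    "r50_intermediate_km_limit",
    "neff_intermediate_largeQ_limit",
    "neff_full_largeQ_limit",
    "r50_multisubstrate_largeQ2",
]

#: r50 of the symmetric Goldbeter-Koshland loop (no turnover)
r50_gk = 1.0

#: large-Q limit of the effective Hill coefficient of the Intermediate
#: model's S*-vs-r response: log(81)/log(9) = 2, independent of all other
#: parameters
neff_intermediate_largeQ_limit = 2.0


def _require_positive(**kw: float) -> None:
    for name, v in kw.items():
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v!r}")


def r50_intermediate_closed_form(
    kcat_D: float, delta1: float, Q: float, K_M: float, D_total: float
) -> float:
    """r50 of the Intermediate model (equal M/D kinetics).

        r50 = (1 + delta1/kcat_D) + Q/(2 kcat_D [D]_T) + delta1 K_M/(kcat_D [D]_T)

    Affine and increasing in Q, so sensitivity is lost without bound as the
    synthesis rate grows; reduces to the GK value 1 when Q = delta1 = 0.
    """
    _require_positive(kcat_D=kcat_D, D_total=D_total)
    return (
        1.0
        + delta1 / kcat_D
        + Q / (2.0 * kcat_D * D_total)
        + delta1 * K_M / (kcat_D * D_total)
    )


def r50_intermediate_km_limit(
    kcat_D: float, delta1: float, Q: float, D_total: float
) -> float:
    """K_M -> 0 limit of the Intermediate r50: a finite constant.

        r50 -> 1 + (delta1 + Q/(2 [D]_T)) / kcat_D

    Strictly larger than the GK value 1 for any positive Q or delta1:
    saturating the enzymes by shrinking K_M cannot restore GK sensitivity.
    """
    _require_positive(kcat_D=kcat_D, D_total=D_total)
    return 1.0 + (delta1 + Q / (2.0 * D_total)) / kcat_D


def neff_full_largeQ_limit(delta1: float, delta2: float) -> float:
    """Large-Q limit of n_eff for the Full model's S*-vs-r response.

        n_eff -> log(81) / [log(9) + log((9 delta1 + delta2)/(9 delta2 + delta1))]

    Requires delta2 > delta1 > 0 (otherwise the denominator loses its
    sign); tends to 2 as delta2/delta1 -> 1, matching the Intermediate
    limit, and grows with the degradation-rate contrast.
    """
    _require_positive(delta1=delta1)
    if not delta2 > delta1:
        raise ValueError(
            f"requires delta2 > delta1 (got delta1={delta1}, delta2={delta2})"
        )
    ratio = (9.0 * delta1 + delta2) / (9.0 * delta2 + delta1)
    return math.log(81.0) / (math.log(9.0) + math.log(ratio))


def r50_multisubstrate_largeQ2(
    delta1: float, delta2: float, Vmax_D: float, alpha2: float, Q2: float
) -> float:
    """Large-Q2 asymptote of r50([S1]_T) for two substrates sharing an E3/DUB.

        r50 = [delta2 / (Vmax_D ((1/alpha2 - 1) delta1 + delta2))] * Q2

    linear in the competitor's synthesis rate Q2. ``alpha2`` is the
    modified molar fraction of substrate 2 at the point where [S1]_T is
    half-maximal.
    """
    _require_positive(Vmax_D=Vmax_D)
    if not 0.0 < alpha2 < 1.0:
        raise ValueError(f"alpha2 must lie in (0, 1), got {alpha2!r}")
    return delta2 / (Vmax_D * ((1.0 / alpha2 - 1.0) * delta1 + delta2)) * Q2
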