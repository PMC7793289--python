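"""Sensitivity (r50) and ultrasensitivity (n_eff) of dose-response curves.

r50 is the input ratio at which the response is half-maximal; the
effective Hill coefficient is the standard two-point measure

    n_eff = log(81) / log(r90 / r10),

which equals the Hill exponent exactly for a true Hill curve and measures
the steepness of the 10%-90% transition for anything else.

Normalization convention: for the modified molar fraction S* the levels
0.1/0.5/0.9 are absolute molar fractions; for total substrate [S]_T (whose
asymptotes are Q/delta1 and Q/delta2 rather than 0 and 1) they are
fractions of the dynamic range, measured as the fraction of the drop from
the low-r asymptote. Every metric record carries this convention tag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .steady_state import ResponseCurve

__all__ = [
    "LevelNotAttainedError",
    "ResponseMetrics",
    "r_at_level",
    "hill_coefficient",
    "compute_metrics",
]


class LevelNotAttainedError(ValueError):
    """The requested response level lies outside the curve's attained range."""


@dataclass(frozen=True)
class ResponseMetrics:
    r50: float
    r10: float
    r90: float
    n_eff: float
    normalization: str  # "absolute_fraction" | "dynamic_range"
    observable_tag: str = ""

    def to_dict(self) -> dict:
        return {
            "r50": self.r50, "r10": self.r10, "r90": self.r90,
            "n_eff": self.n_eff, "normalization": self.normalization,
            "observable_tag": self.observable_tag,
        }


def _normalization_tag(curve: ResponseCurve) -> str:
    lo, hi = sorted((curve.asymptote_low, curve.asymptote_high))
    return "absolute_fraction" if (lo, hi) == (0.0, 1.0) else "dynamic_range"


def r_at_level(
    curve: ResponseCurve,
    level: float,
    *,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """Locate the r at which the normalized response crosses ``level``.

    The crossing is bracketed on the scan grid, estimated by log-linear
    interpolation, and — when the curve carries a steady-state resolver —
    refined by bisection on fresh steady-state solves until the normalized
    response is within ``tol`` of the level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly inside (0, 1)")
    if not curve.all_converged:
        raise ValueError("refusing metric extraction on a flagged curve")
    u = curve.normalized()
    if level < u.min() or level > u.max():
        raise LevelNotAttainedError(
            f"level {level} outside attained normalized range "
            f"[{u.min():.4g}, {u.max():.4g}]"
        )
    # first bracketing interval (u is monotone up to solver noise)
    idx = np.nonzero((u[:-1] - level) * (u[1:] - level) <= 0)[0]
    i = int(idx[0])
    r_lo, r_hi = curve.r_grid[i], curve.r_grid[i + 1]
    u_lo, u_hi = u[i], u[i + 1]
    if u_hi == u_lo:
        return float(math.sqrt(r_lo * r_hi))
    # log-linear interpolation
    f = (level - u_lo) / (u_hi - u_lo)
    r_est = float(r_lo * (r_hi / r_lo) ** f)
    if curve.resolver is None:
        return r_est

    for _ in range(max_iter):
        r_mid = math.sqrt(r_lo * r_hi)
        u_mid = curve.normalize_value(curve.resolver(r_mid))
        if abs(u_mid - level) <= tol:
            return r_mid
        if (u_mid - level) * (u_hi - level) <= 0:
            r_lo, u_lo = r_mid, u_mid
        else:
            r_hi, u_hi = r_mid, u_mid
        if r_hi / r_lo < 1.0 + 1e-14:
            return math.sqrt(r_lo * r_hi)
    return math.sqrt(r_lo * r_hi)


def hill_coefficient(curve: ResponseCurve, *, tol: float = 1e-4) -> float:
    """n_eff = log(81)/log(r90/r10); nan if either level is unattained."""
    try:
        r10 = r_at_level(curve, 0.1, tol=tol)
        r90 = r_at_level(curve, 0.9, tol=tol)
    except LevelNotAttainedError:
        return float("nan")
    return math.log(81.0) / math.log(r90 / r10)


def compute_metrics(curve: ResponseCurve, *, tol: float = 1e-4) -> ResponseMetrics:
    r10 = r_at_level(curve, 0.1, tol=tol)
    r50 = r_at_level(curve, 0.5, tol=tol)
    r90 = r_at_level(curve, 0.9, tol=tol)
    n_eff = math.log(81.0) / math.log(r90 / r10)
    return ResponseMetrics(
        r50=r50, r10=r10, r90=r90, n_eff=n_eff,
        normalization=_normalization_tag(curve),
        observable_tag=curve.observable_tag,
    )
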