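"""Steady-state solving and dose-response scanning.

All analyses in this package are performed at steady state. A state is
accepted as stationary when every component of the time derivative
satisfies ``|dy_i/dt| <= atol + rtol * |y_i|``; the solver first relaxes
the system with a stiff integrator (LSODA) over geometrically growing
time windows and then polishes the result by damped root-finding on the
right-hand side, with the rows of conserved quantities (enzyme totals,
and total substrate for closed models) replacing their redundant ODE rows.

Dose-response curves sample a steady-state observable against the input
ratio r on a log-spaced grid whose bounds are widened automatically until
the response covers the requested fraction of its asymptotic range.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import json
import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._model import ReactionModel

__all__ = [
    "SteadyStateError",
    "ScanError",
    "SteadyStateResult",
    "ResponseCurve",
    "ResponseFamily",
    "find_steady_state",
    "scan_response",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12  # nM / s


class SteadyStateError(RuntimeError):
    pass


class ScanError(RuntimeError):
    pass


@dataclass
class SteadyStateResult:
    state: np.ndarray
    converged: bool
    residual_norm: float  # max |dy/dt| at termination, nM/s
    t_final: float        # total integration horizon used, s


def _stationary(model: ReactionModel, y: np.ndarray, rtol: float, atol: float):
    dy = model.rhs(0.0, y)
    ok = np.all(np.abs(dy) <= atol + rtol * np.abs(y))
    return bool(ok), float(np.max(np.abs(dy)))


def _refine_root(model: ReactionModel, y: np.ndarray, totals: np.ndarray):
    """Polish y by root-finding on the rhs with conservation rows pinned."""
    pivots = [c.pivot for c in model.conservations]

    def fun(x):
        r = model.rhs(0.0, x)
        for c, tot in zip(model.conservations, totals):
            r[c.pivot] = c.coeffs @ x - tot
        return r

    scale = np.maximum(np.abs(y), 1e-30)
    sol = root(fun, y, method="hybr", options={"xtol": 1e-13, "diag": 1.0 / scale})
    x = sol.x
    # reject spurious roots: meaningful negativity or drifted conservation
    if np.any(x < -1e-9 * max(1.0, np.max(np.abs(x)))):
        return None
    x = np.clip(x, 0.0, None)
    for c, tot in zip(model.conservations, totals):
        if abs(c.coeffs @ x - tot) > 1e-6 * max(1.0, abs(tot)):
            return None
    return x


def find_steady_state(
    model: ReactionModel,
    initial: np.ndarray | None = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_max: float = 1e14,
    try_root_first: bool = False,
    enzyme_warning: bool = True,
) -> SteadyStateResult:
    """Relax ``model`` to steady state from ``initial``.

    By default the initial condition is the model's canonical one (for the
    turnover models: empty system, all enzyme free). ``try_root_first``
    skips straight to root polishing — useful when warm-starting from a
    neighbouring solution along a scan.
    """
    # Conserved totals are fixed by the model's parameters (encoded in its
    # default initial state); a caller-supplied initial is projected onto
    # them by adjusting the pivot species, so that warm starts taken from a
    # neighbouring parameter set (e.g. different M_total along a scan)
    # remain consistent.
    totals = model.conserved_totals(model.default_initial)
    if initial is None:
        y = model.default_initial.copy()
    else:
        y = np.asarray(initial, dtype=float).copy()
        if y.shape != model.default_initial.shape:
            raise ValueError("initial state has wrong dimension")
        if np.any(y < 0):
            raise ValueError("initial state must be non-negative")
        for c, tot in zip(model.conservations, totals):
            rest = c.coeffs @ y - c.coeffs[c.pivot] * y[c.pivot]
            y[c.pivot] = max(tot - rest, 0.0)

    t_done = 0.0
    converged = False
    residual = np.inf

    if try_root_first:
        x = _refine_root(model, y, totals)
        if x is not None:
            ok, residual = _stationary(model, x, rtol, atol)
            if ok:
                y, converged = x, True

    if not converged:
        window = 1e2
        while t_done < t_max:
            window = min(window, t_max - t_done)
            sol = solve_ivp(model.rhs, (0.0, window), y, method="LSODA",
                            rtol=1e-8, atol=1e-10)
            if not sol.success:
                raise SteadyStateError(f"integration failed: {sol.message}")
            y = sol.y[:, -1]
            if not np.all(np.isfinite(y)):
                raise SteadyStateError("state diverged to non-finite values")
            y = np.clip(y, 0.0, None)
            t_done += window
            window *= 10.0
            ok, residual = _stationary(model, y, rtol, atol)
            x = _refine_root(model, y, totals)
            if x is not None:
                ok2, res2 = _stationary(model, x, rtol, atol)
                if ok2:
                    y, converged, residual = x, True, res2
                    break
            if ok:
                converged = True
                break

    if enzyme_warning and converged:
        st = model.substrate_total(y)
        if st > 0 and max(model.enzyme_totals) > 0.1 * st:
            warnings.warn(
                "enzyme totals exceed 10% of steady-state substrate; results "
                "are outside the supported enzyme-limited regime",
                stacklevel=2,
            )
    return SteadyStateResult(state=y, converged=converged,
                             residual_norm=residual, t_final=t_done)


@dataclass
class ResponseFamily:
    """A one-parameter family of models indexed by the input ratio r.

    ``build(r)`` compiles the model at signal level r; ``observe(y)``
    extracts the scalar response from a steady state; ``asymptotes`` are
    the limiting response values as r -> 0 and r -> infinity.
    """

    build: Callable[[float], ReactionModel]
    observe: Callable[[np.ndarray], float]
    asymptotes: tuple[float, float]  # (r -> 0, r -> inf)
    observable_tag: str

    @property
    def increasing(self) -> bool:
        return self.asymptotes[1] >= self.asymptotes[0]

    def normalize(self, value: float) -> float:
        """Map a response value onto [0, 1] between the asymptotes.

        For decreasing observables (total substrate in the Full model)
        this measures the fraction of the drop from the high-r... low-r
        asymptote, so the normalized response is increasing in r for every
        observable.
        """
        lo, hi = self.asymptotes
        if hi == lo:
            raise ScanError("degenerate observable: equal asymptotes")
        return (value - lo) / (hi - lo)


@dataclass
class ResponseCurve:
    """A monotone sampling of a steady-state observable against r."""

    r_grid: np.ndarray
    response: np.ndarray
    observable_tag: str
    asymptote_low: float   # response as r -> 0
    asymptote_high: float  # response as r -> inf
    converged: np.ndarray = None
    meta: dict = field(default_factory=dict)
    #: fresh steady-state resolver r -> response, set by scan_response and
    #: used by metric extraction for bisection refinement (not serialized)
    resolver: Callable[[float], float] | None = None

    def __post_init__(self):
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.converged is None:
            self.converged = np.ones(self.r_grid.shape, dtype=bool)
        if self.r_grid.ndim != 1 or np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be one-dimensional, strictly increasing")
        if self.r_grid.shape != self.response.shape:
            raise ValueError("r_grid and response must have equal length")

    @property
    def all_converged(self) -> bool:
        return bool(np.all(self.converged))

    def normalized(self) -> np.ndarray:
        """Response mapped to [0, 1] between the asymptotes, increasing in r."""
        lo, hi = self.asymptote_low, self.asymptote_high
        if hi == lo:
            raise ScanError("degenerate curve: equal asymptotes")
        return (self.response - lo) / (hi - lo)

    def normalize_value(self, value: float) -> float:
        lo, hi = self.asymptote_low, self.asymptote_high
        return (value - lo) / (hi - lo)

    def save(self, path: str | Path) -> None:
        """Write a two-column CSV (r, response) plus a JSON metadata sidecar."""
        path = Path(path)
        arr = np.column_stack([self.r_grid, self.response])
        header = f"r,{self.observable_tag}"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        sidecar = {
            "observable_tag": self.observable_tag,
            "asymptote_low": self.asymptote_low,
            "asymptote_high": self.asymptote_high,
            "all_converged": self.all_converged,
            "meta": {k: repr(v) for k, v in self.meta.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ResponseCurve":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            r_grid=arr[:, 0], response=arr[:, 1],
            observable_tag=sidecar["observable_tag"],
            asymptote_low=sidecar["asymptote_low"],
            asymptote_high=sidecar["asymptote_high"],
        )


def _make_resolver(family: ResponseFamily, rtol: float, atol: float):
    """Steady-state solver r -> response with warm-starting across calls."""
    cache = {"r": None, "y": None}

    def resolve(r: float, return_state: bool = False):
        model = family.build(r)
        warm = cache["y"] is not None
        res = find_steady_state(
            model,
            initial=cache["y"] if warm else None,
            rtol=rtol, atol=atol,
            try_root_first=warm,
            enzyme_warning=False,
        )
        if not res.converged:
            raise SteadyStateError(f"steady state did not converge at r = {r}")
        cache["r"], cache["y"] = r, res.state
        if return_state:
            return res.state
        return family.observe(res.state)

    return resolve


def scan_response(
    family: ResponseFamily,
    r_grid: np.ndarray | None = None,
    *,
    n_points: int = 200,
    r_start: float = 1.0,
    coverage: float = 0.99,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    endpoint_check: bool = False,
    monotone_tol: float = 1e-3,
) -> ResponseCurve:
    """Scan a steady-state observable over a grid of input ratios.

    If ``r_grid`` is omitted, bounds are found automatically by expanding
    from ``r_start`` in decade steps until the normalized response covers
    at least ``coverage`` of the asymptotic range, then filled with
    ``n_points`` log-spaced points. Successive points reuse the previous
    steady state as a warm start. ``endpoint_check`` re-solves the grid
    endpoints from a second, substrate-loaded initial condition to guard
    the steady-state-uniqueness assumption.
    """
    resolve = _make_resolver(family, rtol, atol)
    slack = (1.0 - coverage) / 2.0
    flat_tol = 1e-4  # normalized change per decade counted as "flat"

    if r_grid is None:
        # Expand each bound by decades until the response either nears its
        # theoretical asymptote or has flattened for three consecutive
        # decades (chain models do not reach S* = 1 exactly: molecules in
        # sub-threshold transit keep a residual unmodified population).
        r_lo = r_hi = float(r_start)
        u = family.normalize(resolve(r_lo))
        flat = 0
        for _ in range(60):
            if u <= slack or flat >= 3:
                break
            r_lo /= 10.0
            u_new = family.normalize(resolve(r_lo))
            flat = flat + 1 if abs(u - u_new) <= flat_tol else 0
            u = u_new
        else:
            raise ScanError("could not bracket the low-r asymptote")
        u = family.normalize(resolve(r_hi))
        flat = 0
        for _ in range(60):
            if u >= 1.0 - slack or flat >= 3:
                break
            r_hi *= 10.0
            u_new = family.normalize(resolve(r_hi))
            flat = flat + 1 if abs(u - u_new) <= flat_tol else 0
            u = u_new
        else:
            raise ScanError("could not bracket the high-r asymptote")
        r_grid = np.geomspace(r_lo, r_hi, n_points)
    else:
        r_grid = np.asarray(r_grid, dtype=float)
        if r_grid.ndim != 1 or len(r_grid) == 0:
            raise ValueError("r_grid must be a non-empty 1-d array")
        if np.any(np.diff(r_grid) <= 0) or np.any(r_grid < 0):
            raise ValueError("r_grid must be ascending and non-negative")

    # fresh resolver so the scan itself runs low-to-high warm-started
    resolve = _make_resolver(family, rtol, atol)
    response = np.empty_like(r_grid)
    conv = np.ones(r_grid.shape, dtype=bool)
    states = {}
    for i, r in enumerate(r_grid):
        try:
            y = resolve(r, return_state=True)
        except SteadyStateError:
            conv[i] = False
            response[i] = np.nan
            continue
        states[i] = y
        response[i] = family.observe(y)

    if not np.all(conv):
        bad = r_grid[~conv]
        raise ScanError(f"non-converged scan points at r = {bad}")

    if endpoint_check:
        for i in (0, len(r_grid) - 1):
            model = family.build(r_grid[i])
            alt = model.default_initial.copy()
            st = model.substrate_total(states[i])
            alt[model.substrate_indices[0]] += 2.0 * max(st, 1.0)
            res = find_steady_state(model, initial=alt, rtol=rtol, atol=atol,
                                    enzyme_warning=False)
            span = abs(family.asymptotes[1] - family.asymptotes[0])
            if abs(family.observe(res.state) - response[i]) > 1e-3 * span:
                raise ScanError(
                    f"steady state at r = {r_grid[i]} depends on the initial "
                    "condition; uniqueness assumption violated"
                )

    lo, hi = family.asymptotes
    u = (response - lo) / (hi - lo)
    if np.any(np.diff(u) < -monotone_tol):
        raise ScanError("response is not monotone in r beyond tolerance")

    return ResponseCurve(
        r_grid=r_grid,
        response=response,
        observable_tag=family.observable_tag,
        asymptote_low=lo,
        asymptote_high=hi,
        converged=conv,
        meta=dict(getattr(family, "meta", {}) or {}),
        resolver=_make_resolver(family, rtol, atol),
    )
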