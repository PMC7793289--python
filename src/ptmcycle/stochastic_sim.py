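"""Agent-based stochastic simulation of the chain models.

Each substrate molecule carries an explicit ubiquitin chain length (a
non-negative integer, unbounded by construction) and a binding status
(free, bound to the E3, or bound to the DUB). Since agents of equal
chain length and status are exchangeable, the population is stored as
counts per (status, chain length) class; the dynamics are simulated with
the exact direct stochastic simulation algorithm (no tau-leaping), so a
seed fully determines the event sequence.

The volume factor omega (copies per nM) maps deterministic concentrations
onto copy numbers: unimolecular rate constants carry over unchanged,
bimolecular association rates are divided by omega, and the zeroth-order
synthesis rate is multiplied by omega. In the large-omega limit the
time-averaged copy-number fractions converge to the truncated ODE steady
state, which is how the deterministic chain truncation is validated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .multisite import ChainModelParams, DubMode, E3Mode, MechanismSpec

__all__ = [
    "StochasticRates",
    "AgentSystem",
    "SimResult",
    "convert_rates",
    "simulate",
    "replicate_sstar_means",
]

#: capacity of the chain-length buffer; the chain length itself is
#: unbounded and the kernel aborts loudly if the buffer would overflow
_KCAP = 4096


@dataclass(frozen=True)
class StochasticRates:
    """Propensity constants (per second, per copy or copy pair)."""

    a_syn: float       # synthesis events /s (= Q * omega)
    b_plus_M: float    # per M-substrate pair /s (= k_plus_M / omega)
    b_plus_D: float
    k_minus_M: float
    k_minus_D: float
    kcat_M: float
    kcat_D: float
    delta1: float
    delta2: float
    threshold: int
    omega: float


def convert_rates(params: ChainModelParams, omega: float) -> StochasticRates:
    """Map deterministic chain-model parameters onto stochastic propensities."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    p = params.rates
    return StochasticRates(
        a_syn=p.Q * omega,
        b_plus_M=p.k_plus_M / omega,
        b_plus_D=p.k_plus_D / omega,
        k_minus_M=p.k_minus_M,
        k_minus_D=p.k_minus_D,
        kcat_M=p.kcat_M,
        kcat_D=p.kcat_D,
        delta1=p.delta1,
        delta2=p.delta2,
        threshold=params.degradation_threshold,
        omega=omega,
    )


@dataclass
class AgentSystem:
    """Copy-number state: substrate counts per (status, chain length).

    ``S[k]``, ``MS[k]``, ``DS[k]`` count free, E3-bound and DUB-bound
    substrate molecules with chain length k; chain lengths are unbounded
    (the arrays grow logically with the longest chain seen).
    """

    omega: float
    M_total: int
    D_total: int
    S: np.ndarray = field(default_factory=lambda: np.zeros(_KCAP, dtype=np.int64))
    MS: np.ndarray = field(default_factory=lambda: np.zeros(_KCAP, dtype=np.int64))
    DS: np.ndarray = field(default_factory=lambda: np.zeros(_KCAP, dtype=np.int64))

    @classmethod
    def empty(cls, params: ChainModelParams, omega: float) -> "AgentSystem":
        p = params.rates
        return cls(omega=omega,
                   M_total=int(round(p.M_total * omega)),
                   D_total=int(round(p.D_total * omega)))

    @property
    def M_free(self) -> int:
        return self.M_total - int(self.MS.sum())

    @property
    def D_free(self) -> int:
        return self.D_total - int(self.DS.sum())


@dataclass
class SimResult:
    """Sampled trajectory and terminal chain-length histogram."""

    times: np.ndarray
    sstar_count: np.ndarray    # copies with chain length >= threshold
    total_count: np.ndarray    # all substrate copies
    histogram: np.ndarray      # terminal counts per chain length (all forms)
    omega: float
    seed: int
    n_events: int

    @property
    def sstar_fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total_count > 0,
                            self.sstar_count / self.total_count, np.nan)

    def steady_mean(self, burn_in: float) -> tuple[float, float]:
        """Time-averaged (S* fraction, total copies) after ``burn_in`` s."""
        sel = self.times >= burn_in
        if not np.any(sel):
            raise ValueError("burn_in longer than the trajectory")
        return (float(np.nanmean(self.sstar_fraction[sel])),
                float(self.total_count[sel].mean()))


@njit(cache=True)
def _ssa_kernel(seed, t_end, sample_dt,
                S, MS, DS, M_free, D_free,
                a_syn, bM, bD, uM, uD, cM, cD, d1, d2, thr,
                e3_proc, dub_mode,
                out_sstar, out_total):
    np.random.seed(seed)
    kcap = S.shape[0]
    n_samples = out_sstar.shape[0]
    t = 0.0
    isample = 0
    kmax = 0
    n_events = 0
    sstar = 0
    total = 0
    for k in range(kcap):
        if S[k] > 0 or MS[k] > 0 or DS[k] > 0:
            if k > kmax:
                kmax = k
            c = S[k] + MS[k] + DS[k]
            total += c
            if k >= thr:
                sstar += c

    while isample < n_samples:
        # total propensity
        a_tot = a_syn
        for k in range(kmax + 1):
            dk = d1 if k < thr else d2
            a_tot += bM * M_free * S[k] + uM * MS[k] + cM * MS[k]
            a_tot += dk * (S[k] + MS[k] + DS[k])
            if k > 0:
                a_tot += bD * D_free * S[k] + cD * DS[k]
            a_tot += uD * DS[k]
        if a_tot <= 0.0:
            # frozen system: emit remaining samples and stop
            while isample < n_samples:
                out_sstar[isample] = sstar
                out_total[isample] = total
                isample += 1
            break
        tau = -np.log(np.random.random()) / a_tot
        # record samples crossed by this waiting interval
        while isample < n_samples and (isample + 1) * sample_dt <= t + tau:
            out_sstar[isample] = sstar
            out_total[isample] = total
            isample += 1
        t += tau
        if isample >= n_samples:
            break

        # select the channel
        target = np.random.random() * a_tot
        acc = a_syn
        if target < acc:
            S[0] += 1
            total += 1
            if thr == 0:
                sstar += 1
            n_events += 1
            continue
        fired = False
        for k in range(kmax + 1):
            dk = d1 if k < thr else d2
            a = bM * M_free * S[k]
            if target < acc + a:
                S[k] -= 1
                MS[k] += 1
                M_free -= 1
                fired = True
                break
            acc += a
            a = uM * MS[k]
            if target < acc + a:
                MS[k] -= 1
                S[k] += 1
                M_free += 1
                fired = True
                break
            acc += a
            a = cM * MS[k]
            if target < acc + a:
                # E3 catalysis: extend the chain by one
                if k + 2 >= kcap:
                    return -1, n_events, t  # buffer overflow (unreachable)
                MS[k] -= 1
                if e3_proc == 1:
                    MS[k + 1] += 1
                else:
                    S[k + 1] += 1
                    M_free += 1
                if k + 1 > kmax:
                    kmax = k + 1
                if k + 1 == thr:
                    sstar += 1
                fired = True
                break
            acc += a
            a = dk * S[k]
            if target < acc + a:
                S[k] -= 1
                total -= 1
                if k >= thr:
                    sstar -= 1
                fired = True
                break
            acc += a
            a = dk * MS[k]
            if target < acc + a:
                MS[k] -= 1
                M_free += 1
                total -= 1
                if k >= thr:
                    sstar -= 1
                fired = True
                break
            acc += a
            a = dk * DS[k]
            if target < acc + a:
                DS[k] -= 1
                D_free += 1
                total -= 1
                if k >= thr:
                    sstar -= 1
                fired = True
                break
            acc += a
            if k > 0:
                a = bD * D_free * S[k]
                if target < acc + a:
                    S[k] -= 1
                    DS[k] += 1
                    D_free -= 1
                    fired = True
                    break
                acc += a
                a = cD * DS[k]
                if target < acc + a:
                    # DUB catalysis: shorten (or strip) the chain
                    DS[k] -= 1
                    if dub_mode == 0:    # distributive, sequential
                        S[k - 1] += 1
                        D_free += 1
                        if k == thr:
                            sstar -= 1
                    elif dub_mode == 1:  # processive, sequential
                        DS[k - 1] += 1
                        if k == thr:
                            sstar -= 1
                    else:                # distributive, base: whole chain off
                        S[0] += 1
                        D_free += 1
                        if k >= thr and thr > 0:
                            sstar -= 1
                    fired = True
                    break
                acc += a
            a = uD * DS[k]
            if target < acc + a:
                DS[k] -= 1
                S[k] += 1
                D_free += 1
                fired = True
                break
            acc += a
        if not fired:
            # numerical slack in the cumulative sum: re-draw
            continue
        n_events += 1
        # let kmax shrink when the top classes empty out
        while kmax > 0 and S[kmax] == 0 and MS[kmax] == 0 and DS[kmax] == 0:
            kmax -= 1
    return 0, n_events, t


def simulate(
    system: AgentSystem,
    mech: MechanismSpec,
    params: ChainModelParams,
    t_end: float,
    seed: int,
    *,
    sample_dt: float | None = None,
) -> SimResult:
    """Run the exact SSA from ``system``'s state for ``t_end`` seconds.

    Identical (seed, parameters, initial state) reproduce identical event
    sequences. The state arrays in ``system`` are updated in place;
    ``sample_dt`` (default: t_end/2000) sets the trajectory sampling grid.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if not isinstance(mech, MechanismSpec):
        mech = MechanismSpec(*mech)
    rates = convert_rates(params, system.omega)
    if sample_dt is None:
        sample_dt = t_end / 2000.0
    n_samples = int(round(t_end / sample_dt))
    out_sstar = np.zeros(n_samples, dtype=np.int64)
    out_total = np.zeros(n_samples, dtype=np.int64)
    dub_code = {
        DubMode.DISTRIBUTIVE_SEQUENTIAL: 0,
        DubMode.PROCESSIVE_SEQUENTIAL: 1,
        DubMode.DISTRIBUTIVE_BASE: 2,
    }[mech.dub_mode]
    status, n_events, t_final = _ssa_kernel(
        seed, float(t_end), float(sample_dt),
        system.S, system.MS, system.DS,
        system.M_free, system.D_free,
        rates.a_syn, rates.b_plus_M, rates.b_plus_D,
        rates.k_minus_M, rates.k_minus_D,
        rates.kcat_M, rates.kcat_D,
        rates.delta1, rates.delta2, rates.threshold,
        1 if mech.e3_mode is E3Mode.PROCESSIVE else 0,
        dub_code,
        out_sstar, out_total,
    )
    if status != 0:
        raise RuntimeError(
            "chain-length buffer exhausted; this indicates runaway chain "
            "growth (check that degradation and DUB rates are positive)"
        )
    hist = system.S + system.MS + system.DS
    last = int(np.max(np.nonzero(hist)[0])) if hist.any() else 0
    return SimResult(
        times=(np.arange(1, n_samples + 1)) * sample_dt,
        sstar_count=out_sstar,
        total_count=out_total,
        histogram=hist[: last + 1].copy(),
        omega=system.omega,
        seed=seed,
        n_events=n_events,
    )


def replicate_sstar_means(
    mech: MechanismSpec,
    params: ChainModelParams,
    omega: float,
    seeds,
    *,
    t_end: float | None = None,
    burn_in: float | None = None,
) -> np.ndarray:
    """Steady-state S* fraction from independent replicate runs.

    Each replicate starts from the empty system, discards a burn-in of
    five mean substrate lifetimes (5/delta1) and time-averages the rest.
    """
    d1 = params.rates.delta1
    if burn_in is None:
        burn_in = 5.0 / d1
    if t_end is None:
        t_end = 2.0 * burn_in
    out = []
    for seed in seeds:
        sys_ = AgentSystem.empty(params, omega)
        res = simulate(sys_, mech, params, t_end, int(seed))
        out.append(res.steady_mean(burn_in)[0])
    return np.array(out)
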