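"""Synthetic inputs: parameter ensembles and ligase-substrate networks.

Two generators cover everything the pipeline consumes that is not a plain
parameter set:

* log-uniform kinetic-parameter ensembles spanning a configurable number
  of decades around a base set, for robustness sweeps;
* bipartite E3-ligase -> substrate edge tables with a zero-inflated,
  power-law-tailed substrate-load distribution, emulating the curated
  interaction databases (most annotated ligases have no listed substrate;
  of the rest, about half act on two or more, and a heavy tail acts on
  tens). The table format is two-column TSV (ligase_id, substrate_id).

Both are fully reproducible from their (spec, seed) pair.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .single_site import RateConstants

__all__ = [
    "ParameterEnsemble",
    "LigaseSubstrateTable",
    "sample_ensemble",
    "generate_network",
    "load_statistics",
    "substrate_load",
]

_VARIABLE = ("K_M", "delta1", "delta2")


@dataclass(frozen=True)
class ParameterEnsemble:
    """Log-uniform sampling plan around a base parameter set.

    Each symbol in ``varied_symbols`` is drawn log-uniformly over
    ``[base / 10^(span/2), base * 10^(span/2)]``. K_M variation rescales
    the association rates of both enzymes jointly (k_minus and kcat kept
    fixed), preserving equal M/D kinetics; draws violating
    delta2 >= delta1 are rejected and redrawn. If the base set has
    delta2 == delta1 (Intermediate pattern) and delta2 is not itself
    varied, delta2 tracks the drawn delta1.
    """

    base: RateConstants
    varied_symbols: tuple[str, ...] = ("K_M", "delta1", "delta2")
    span_decades: float = 2.0
    n: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("ensemble size n must be >= 1")
        if self.span_decades < 0:
            raise ValueError("span_decades must be >= 0")
        if not self.varied_symbols:
            raise ValueError("varied_symbols must be non-empty")
        unknown = set(self.varied_symbols) - set(_VARIABLE)
        if unknown:
            raise ValueError(f"unknown symbols {sorted(unknown)}; "
                             f"choose from {_VARIABLE}")


def sample_ensemble(spec: ParameterEnsemble) -> list[RateConstants]:
    """Draw the ensemble deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    half = spec.span_decades / 2.0
    intermediate_base = (
        spec.base.delta2 == spec.base.delta1
        and "delta2" not in spec.varied_symbols
    )

    def factor() -> float:
        return float(10.0 ** rng.uniform(-half, half))

    out: list[RateConstants] = []
    while len(out) < spec.n:
        kw = {}
        if "K_M" in spec.varied_symbols:
            f = factor()
            kw["k_plus_M"] = spec.base.k_plus_M / f
            kw["k_plus_D"] = spec.base.k_plus_D / f
        if "delta1" in spec.varied_symbols:
            kw["delta1"] = spec.base.delta1 * factor()
        if "delta2" in spec.varied_symbols:
            kw["delta2"] = spec.base.delta2 * factor()
        d1 = kw.get("delta1", spec.base.delta1)
        if intermediate_base:
            kw["delta2"] = d1
        elif kw.get("delta2", spec.base.delta2) < d1:
            continue  # reject: modified forms must not outlive unmodified
        out.append(replace(spec.base, **kw))
    return out


@dataclass
class LigaseSubstrateTable:
    """Bipartite ligase -> substrate edge list."""

    edges: pd.DataFrame  # columns: ligase_id, substrate_id
    n_ligases: int | None = None  # total annotated ligases incl. zero-degree

    def __post_init__(self):
        cols = list(self.edges.columns)
        if cols != ["ligase_id", "substrate_id"]:
            raise ValueError("edges needs columns [ligase_id, substrate_id]")
        if self.edges.duplicated().any():
            raise ValueError("duplicate ligase-substrate edges")
        if (self.edges == "").any().any():
            raise ValueError("empty identifiers are not allowed")

    def degrees(self) -> pd.Series:
        return self.edges.groupby("ligase_id").size()

    def write_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path,
                 n_ligases: int | None = None) -> "LigaseSubstrateTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str), n_ligases=n_ligases)


#: tail exponent giving ~11% of non-zero-degree ligases more than 10
#: substrates under truncation at the largest observed degree (92)
DEFAULT_TAIL_EXPONENT = 1.7
DEFAULT_MAX_DEGREE = 92


def generate_network(
    n_ligases: int,
    mean_load: float = 2.1,
    tail_exponent: float = DEFAULT_TAIL_EXPONENT,
    seed: int = 0,
    *,
    max_degree: int = DEFAULT_MAX_DEGREE,
) -> LigaseSubstrateTable:
    """Sample a ligase-substrate table with a heavy-tailed load distribution.

    Per-ligase substrate counts are zero-inflated: with probability p0 a
    ligase has no annotated substrate, otherwise its degree follows a
    truncated power law ``P(k) ~ k^-tail_exponent`` on 1..max_degree. p0
    is set so the expected load over all ligases (total substrates /
    total ligases) equals ``mean_load``; (mean_load, tail_exponent) pairs
    demanding p0 outside [0, 1) are rejected as infeasible.
    """
    if n_ligases < 1:
        raise ValueError("n_ligases must be >= 1")
    if mean_load <= 0 or tail_exponent <= 0:
        raise ValueError("mean_load and tail_exponent must be > 0")
    k = np.arange(1, max_degree + 1)
    pmf = k ** (-float(tail_exponent))
    pmf /= pmf.sum()
    mean_nonzero = float(k @ pmf)
    p_zero = 1.0 - mean_load / mean_nonzero
    if not 0.0 <= p_zero < 1.0:
        raise ValueError(
            f"infeasible (mean_load={mean_load}, tail_exponent={tail_exponent}): "
            f"non-zero-degree mean is {mean_nonzero:.3f}"
        )
    rng = np.random.default_rng(seed)
    degrees = np.where(
        rng.random(n_ligases) < p_zero,
        0,
        rng.choice(k, size=n_ligases, p=pmf),
    )
    rows = [
        (f"E3_{i:04d}", f"SUB_{i:04d}_{j:03d}")
        for i, d in enumerate(degrees)
        for j in range(int(d))
    ]
    edges = pd.DataFrame(rows, columns=["ligase_id", "substrate_id"])
    return LigaseSubstrateTable(edges=edges, n_ligases=n_ligases)


def substrate_load(n_substrates: int, n_ligases: int) -> float:
    """Average substrate load: total substrates / total ligases."""
    if n_ligases <= 0:
        raise ValueError("n_ligases must be > 0")
    return n_substrates / n_ligases


def load_statistics(table: LigaseSubstrateTable,
                    total_ligases: int | None = None) -> dict:
    """Database-style crosstalk statistics of a ligase-substrate table.

    ``mean_load`` divides the total substrate count by ``total_ligases``
    (which may exceed the number of ligases with edges — annotated
    ligases without listed substrates count toward the denominator);
    the ``frac_*_of_nonzero`` fractions are taken over ligases that have
    at least one substrate.
    """
    if total_ligases is None:
        total_ligases = table.n_ligases
    if total_ligases is None or total_ligases <= 0:
        raise ValueError("total_ligases must be a positive integer")
    deg = table.degrees()
    if len(deg) > total_ligases:
        raise ValueError("total_ligases smaller than ligases with edges")
    n_sub = int(table.edges["substrate_id"].nunique())
    n_nonzero = int(len(deg))
    return {
        "mean_load": substrate_load(n_sub, total_ligases),
        "frac_zero": 1.0 - n_nonzero / total_ligases,
        "frac_ge2_of_nonzero": float((deg >= 2).mean()) if n_nonzero else 0.0,
        "frac_gt10_of_nonzero": float((deg > 10).mean()) if n_nonzero else 0.0,
        "max_degree": int(deg.max()) if n_nonzero else 0,
        "mean_load_nonzero": float(deg.mean()) if n_nonzero else 0.0,
    }
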