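"""Shared container for mass-action reaction models.

Every model family in the package (single-site, polyubiquitin chain,
multi-substrate) compiles down to a :class:`ReactionModel`: a plain
time-derivative function plus the structural metadata the steady-state
machinery needs (conserved linear combinations, a default initial state,
which components count toward total substrate).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["Conservation", "ReactionModel"]


@dataclass(frozen=True)
class Conservation:
    """A linear quantity ``coeffs @ y`` that is constant along trajectories.

    ``pivot`` names the state component whose ODE row is replaced by the
    conservation residual during steady-state root refinement (the Jacobian
    of the raw right-hand side is singular along conserved directions).
    """

    coeffs: np.ndarray
    pivot: int

    def residual(self, y: np.ndarray, total: float) -> float:
        return float(self.coeffs @ y) - total


@dataclass
class ReactionModel:
    """Mass-action ODE system ``dy/dt = rhs(t, y)`` with metadata.

    Parameters
    ----------
    rhs
        Time-derivative function ``rhs(t, y) -> dy``.
    species
        Component names, in state-vector order.
    conservations
        Linear invariants (enzyme totals, and total substrate for closed
        systems such as the Goldbeter–Koshland loop).
    default_initial
        The canonical starting state. For models with synthesis this is the
        empty system (zero substrate, all enzyme free) so synthesis fills
        the system; closed models start substrate-loaded.
    substrate_indices
        Indices of components that count toward total substrate.
    enzyme_totals
        (M_total, D_total), used for the enzyme-limited-regime check.
    """

    rhs: Callable[[float, np.ndarray], np.ndarray]
    species: tuple[str, ...]
    conservations: tuple[Conservation, ...]
    default_initial: np.ndarray
    substrate_indices: np.ndarray
    enzyme_totals: tuple[float, float]
    meta: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def substrate_total(self, y: Sequence[float]) -> float:
        y = np.asarray(y, dtype=float)
        return float(y[self.substrate_indices].sum())

    def conserved_totals(self, y0: Sequence[float]) -> np.ndarray:
        y0 = np.asarray(y0, dtype=float)
        return np.array([c.coeffs @ y0 for c in self.conservations])
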