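"""Equilibrium census along a migration-rate sweep.

The scan applies a common migration rate ``c1 = c2 = c`` to a template
system, re-enumerates and classifies the equilibria at every grid value and
tabulates the counts. ``c = 0`` is treated as an exact special case (the
decoupled product enumeration) rather than a limit of the general solver.
No branch continuation is attempted: each grid point is an independent
enumeration, and threshold locations are reported as bracketing intervals
between grid points where a count changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .equilibria import EquilibriumSet, enumerate_equilibria
from .model import DomainError, TwoPatchSystem
from .stability import classify_all

__all__ = ["BifurcationRow", "default_c_grid", "scan", "detect_thresholds"]

log = logging.getLogger(__name__)

COUNT_FIELDS = ("n_total", "n_stable", "n_unstable", "n_marginal", "n_interior")


@dataclass(frozen=True)
class BifurcationRow:
    """Equilibrium census at one migration-rate value."""

    c: float
    n_total: int
    n_stable: int
    n_unstable: int
    n_marginal: int
    n_interior: int

    def counts(self) -> tuple[int, ...]:
        return tuple(getattr(self, f) for f in COUNT_FIELDS)

    def to_dict(self) -> dict:
        return {"c": self.c, **{f: getattr(self, f) for f in COUNT_FIELDS}}


def with_migration(sys: TwoPatchSystem, c: float) -> TwoPatchSystem:
    """The template system with both migration rates set to ``c``."""
    return TwoPatchSystem(
        sys.gameA, sys.gameB,
        replace(sys.env1, c_out=c), replace(sys.env2, c_out=c),
    )


def default_c_grid(c_max: float = 0.05, n: int = 100) -> np.ndarray:
    """Zero plus ``n`` log-spaced migration rates up to ``c_max``."""
    return np.concatenate([[0.0], np.logspace(-4, np.log10(c_max), n)])


def census_at(sys: TwoPatchSystem, c: float, grid: int = 201) -> tuple[BifurcationRow, EquilibriumSet]:
    eqset = classify_all(with_migration(sys, c), enumerate_equilibria(with_migration(sys, c), grid=grid))
    row = BifurcationRow(
        c=float(c),
        n_total=eqset.n_total,
        n_stable=eqset.n_stable,
        n_unstable=eqset.n_unstable,
        n_marginal=eqset.n_marginal,
        n_interior=eqset.n_interior,
    )
    if row.n_marginal:
        log.warning("marginal equilibria at c=%.6g: counts near a bifurcation", c)
    return row, eqset


def scan(
    sys: TwoPatchSystem,
    c_values=None,
    grid: int = 201,
    densify_step: float = 5e-4,
    densify: bool = True,
) -> list[BifurcationRow]:
    """Equilibrium censuses over a sorted grid of common migration rates.

    After the first pass, any interval between consecutive grid points whose
    counts differ is refilled at ``densify_step`` resolution so that count
    thresholds are bracketed tightly without continuation machinery.
    """
    if c_values is None:
        c_values = default_c_grid()
    c_values = np.asarray(sorted(set(float(c) for c in c_values)))
    if c_values.size and c_values[-1] >= min(sys.alpha1, sys.alpha2):
        raise DomainError("migration rates must stay below min(alpha1, alpha2)")
    rows = {float(c): census_at(sys, c, grid=grid)[0] for c in c_values}
    if densify:
        extra: list[float] = []
        cs = sorted(rows)
        for lo, hi in zip(cs[:-1], cs[1:]):
            if rows[lo].counts() != rows[hi].counts() and hi - lo > densify_step:
                extra.extend(np.arange(lo + densify_step, hi, densify_step))
        for c in extra:
            c = float(c)
            if c not in rows:
                rows[c] = census_at(sys, c, grid=grid)[0]
    return [rows[c] for c in sorted(rows)]


def detect_thresholds(rows: list[BifurcationRow]) -> list[dict]:
    """Consecutive grid intervals across which any census count changes.

    Returns one record per changing interval with the bracketing rates and
    the per-count before/after values. Refining the grid can only narrow
    these brackets.
    """
    if len(rows) < 3:
        raise ValueError("threshold detection needs at least three rows")
    out = []
    for a, b in zip(rows[:-1], rows[1:]):
        changes = {
            f: (getattr(a, f), getattr(b, f))
            for f in COUNT_FIELDS
            if getattr(a, f) != getattr(b, f)
        }
        if changes:
            out.append({"c_low": a.c, "c_high": b.c, "changes": changes})
    return out
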