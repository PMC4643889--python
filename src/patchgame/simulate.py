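"""Numerical integration of the dynamics and the basin-of-attraction census.

Trajectories are always integrated in abundance coordinates, where the
vector field is smooth up to the boundary of the positive orthant (the
frequency form divides by patch densities and is singular near extinction).
Convergence to an attractor is declared when the vector-field norm stays
below a threshold at consecutive check points, which guards against false
positives during slow passages near saddle points.

The basin census samples random initial conditions (frequencies uniform on
the open unit square, densities log-uniform below the carrying-capacity
scale), integrates each one and matches converged end states to a
previously enumerated equilibrium set. A converged trajectory that matches
no known equilibrium is surfaced as an "unexplained attractor" -- the
signal that the enumeration missed something.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import EquilibriumSet, _scaled_distance
from .model import (
    FREQUENCY,
    SystemState,
    TwoPatchSystem,
    abundance_to_frequency,
    vector_field_abundance,
)

__all__ = ["Trajectory", "BasinCensus", "integrate", "basin_census", "match_equilibrium"]

log = logging.getLogger(__name__)

CONV_TOL = 1e-8
MATCH_TOL = 1e-4


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (len(times), 4) abundance coordinates
    converged: bool
    attractor: int | None = None  # index into the matched EquilibriumSet

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class BasinCensus:
    n_starts: int
    seed: int
    hits: dict[int, int] = field(default_factory=dict)
    unresolved: int = 0
    unexplained: list[np.ndarray] = field(default_factory=list)

    @property
    def attractors(self) -> set[int]:
        return set(self.hits)

    def to_dict(self) -> dict:
        return {
            "n_starts": self.n_starts,
            "seed": self.seed,
            "hits": {str(k): v for k, v in sorted(self.hits.items())},
            "unresolved": self.unresolved,
            "n_unexplained": len(self.unexplained),
        }


def _initial_array(initial) -> np.ndarray:
    if isinstance(initial, SystemState):
        if initial.rep == FREQUENCY:
            initial = initial.convert("abundance")
        return initial.array
    return np.asarray(initial, dtype=float)


def integrate(
    sys: TwoPatchSystem,
    initial,
    horizon: float = 2000.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    conv_tol: float = CONV_TOL,
    early_exit: bool = True,
    chunk: float = 50.0,
    t_eval=None,
) -> Trajectory:
    """Integrate the abundance dynamics from a non-negative initial state.

    With ``early_exit`` the horizon is cut short once the vector-field
    max-norm has been below ``conv_tol`` at two consecutive chunk
    boundaries. Pass ``t_eval`` for a densely sampled trajectory over the
    full horizon (disables early exit).
    """
    u0 = _initial_array(initial)
    if np.any(u0 < 0):
        raise ValueError("initial abundances must be non-negative")

    def rhs(t, u):
        return vector_field_abundance(sys, np.maximum(u, 0.0))

    if t_eval is not None:
        sol = solve_ivp(rhs, (0.0, horizon), u0, method="LSODA",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        states = np.maximum(sol.y.T, 0.0)
        conv = float(np.max(np.abs(rhs(0.0, states[-1])))) < conv_tol
        return Trajectory(sol.t, states, conv)

    times = [0.0]
    states = [u0]
    t, u = 0.0, u0
    below = 1 if float(np.max(np.abs(rhs(0.0, u0)))) < conv_tol else 0
    converged = False
    while t < horizon:
        t_next = min(t + chunk, horizon)
        sol = solve_ivp(rhs, (t, t_next), u, method="LSODA", rtol=rtol, atol=atol)
        t, u = sol.t[-1], np.maximum(sol.y[:, -1], 0.0)
        times.append(t)
        states.append(u)
        if float(np.max(np.abs(rhs(t, u)))) < conv_tol:
            below += 1
        else:
            below = 0
        if early_exit and below >= 2:
            converged = True
            break
    else:
        converged = float(np.max(np.abs(rhs(t, u)))) < conv_tol
    return Trajectory(np.array(times), np.array(states), converged)


def match_equilibrium(
    sys: TwoPatchSystem, u_abund: np.ndarray, eqset: EquilibriumSet,
    tol: float = MATCH_TOL,
) -> int | None:
    """Index of the equilibrium nearest to an abundance state, or None if
    nothing lies within the matching tolerance (scaled max-norm on
    frequencies and relative densities)."""
    n1 = u_abund[0] + u_abund[1]
    n2 = u_abund[2] + u_abund[3]
    if n1 <= 0 or n2 <= 0:
        return None
    v = abundance_to_frequency(u_abund)
    best, best_d = None, np.inf
    for i, eq in enumerate(eqset):
        d = _scaled_distance(sys, v, eq.state)
        if d < best_d:
            best, best_d = i, d
    return best if best_d < tol else None


def basin_census(
    sys: TwoPatchSystem,
    eqset: EquilibriumSet,
    n_starts: int = 500,
    seed: int = 0,
    horizon: float = 2000.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    match_tol: float = MATCH_TOL,
) -> BasinCensus:
    """Attractor census from random initial conditions, deterministic under
    the seed.

    Initial frequencies are uniform on (0, 1) (boundary frequencies span
    invariant manifolds and would bias a census of interior basins);
    initial densities are log-uniform over two decades below the
    carrying-capacity scale of each patch.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = sys.density_scale()
    P = rng.uniform(0.0, 1.0, size=n_starts)
    Q = rng.uniform(0.0, 1.0, size=n_starts)
    N1 = s1 * 10.0 ** rng.uniform(-2.0, 0.0, size=n_starts)
    N2 = s2 * 10.0 ** rng.uniform(-2.0, 0.0, size=n_starts)
    census = BasinCensus(n_starts=n_starts, seed=seed)
    for p, q, n1, n2 in zip(P, Q, N1, N2):
        u0 = np.array([p * n1, (1 - p) * n1, q * n2, (1 - q) * n2])
        traj = integrate(sys, u0, horizon=horizon, rtol=rtol, atol=atol)
        if not traj.converged:
            census.unresolved += 1
            continue
        idx = match_equilibrium(sys, traj.final, eqset, tol=match_tol)
        if idx is None:
            census.unexplained.append(traj.final)
            log.warning("unexplained attractor at abundance state %s", traj.final)
            continue
        census.hits[idx] = census.hits.get(idx, 0) + 1
    return census
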