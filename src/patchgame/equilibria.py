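"""Enumeration of the stationary states of the two-patch dynamics.

The enumeration splits into three routes chosen by the migration rates:

* ``c1 = c2 = 0`` -- the patches decouple; stationary states are the
  Cartesian product of the per-patch replicator/logistic equilibria.
* exactly one rate positive (the source-sink case) -- patch-1 dynamics are
  autonomous; for each rest frequency ``p`` of patch 1 the patch-2
  frequency must zero an explicit scalar function on [0, 1], whose roots
  are found by dense sampling plus bracketed root polishing.
* both rates positive -- interior equilibria are roots of two residual
  surfaces on the open unit square obtained by substituting the unique
  positive solution of the density subsystem; sign-change cells of a dense
  grid seed a damped Newton iteration on the full four-dimensional
  stationarity system.

All routes return :class:`Equilibrium` records in frequency coordinates
with a vector-field residual certificate. The empty state (both patches
extinct) is always stationary but never part of the census: it is unstable
whenever ``alpha_i > c_i`` and the analysis concerns positive equilibria.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from .games import classify_game, interior_rest_point
from .model import (
    DomainError,
    TwoPatchSystem,
    frequency_jacobian,
    vector_field_frequency,
)

__all__ = [
    "Equilibrium",
    "EquilibriumSet",
    "solve_density",
    "density_grid",
    "symmetric_equilibria",
    "case1_equilibria",
    "decoupled_equilibria",
    "general_equilibria",
    "enumerate_equilibria",
    "CurveIntersection",
    "curve_intersections",
]

log = logging.getLogger(__name__)

SNAP_TOL = 1e-9          # boundary frequencies within this are snapped to 0/1
DEDUP_RADIUS = 1e-6      # max-norm radius (densities scaled) for dedup
RESIDUAL_TOL = 1e-9      # certificate: stationarity residual must beat this


@dataclass
class Equilibrium:
    """A stationary point of the dynamics in frequency coordinates.

    ``eigenvalues`` and ``stability`` are filled by the stability module;
    ``branch`` records the patch-1 rest frequency that generated a
    source-sink (one-way migration) equilibrium.
    """

    p: float
    q: float
    n1: float
    n2: float
    kind: str
    residual: float
    branch: float | None = None
    eigenvalues: np.ndarray | None = field(default=None, repr=False)
    stability: str = "unset"

    @property
    def state(self) -> np.ndarray:
        return np.array([self.p, self.q, self.n1, self.n2])

    @property
    def is_interior(self) -> bool:
        return 0.0 < self.p < 1.0 and 0.0 < self.q < 1.0

    @property
    def max_re_eig(self) -> float:
        if self.eigenvalues is None:
            return math.nan
        return float(np.max(np.real(self.eigenvalues)))

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "q": self.q,
            "n1": self.n1,
            "n2": self.n2,
            "kind": self.kind,
            "residual": self.residual,
            "max_re_eig": self.max_re_eig,
            "stability": self.stability,
        }


@dataclass
class EquilibriumSet:
    """Deduplicated collection of equilibria with census counts."""

    equilibria: list[Equilibrium]

    def __iter__(self):
        return iter(self.equilibria)

    def __len__(self) -> int:
        return len(self.equilibria)

    def __getitem__(self, i: int) -> Equilibrium:
        return self.equilibria[i]

    @property
    def n_total(self) -> int:
        return len(self.equilibria)

    @property
    def n_interior(self) -> int:
        return sum(e.is_interior for e in self.equilibria)

    @property
    def n_stable(self) -> int:
        return sum(e.stability == "stable" for e in self.equilibria)

    @property
    def n_unstable(self) -> int:
        return sum(e.stability == "unstable" for e in self.equilibria)

    @property
    def n_marginal(self) -> int:
        return sum(e.stability == "marginal" for e in self.equilibria)

    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability == "stable"]

    def interior(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.is_interior]


def _scaled_distance(sys: TwoPatchSystem, a: np.ndarray, b: np.ndarray) -> float:
    s1, s2 = sys.density_scale()
    w = np.array([1.0, 1.0, 1.0 / s1, 1.0 / s2])
    return float(np.max(np.abs((a - b) * w)))


def _dedup(sys: TwoPatchSystem, eqs: list[Equilibrium]) -> list[Equilibrium]:
    # first occurrence wins: structural kinds (symmetric/case-specific) are
    # inserted before grid-search duplicates and carry the better labels
    kept: list[Equilibrium] = []
    for e in eqs:
        if any(_scaled_distance(sys, e.state, k.state) <= DEDUP_RADIUS for k in kept):
            log.debug("dedup merge at p=%.6f q=%.6f", e.p, e.q)
            continue
        kept.append(e)
    return kept


def _snap(v: float) -> float:
    if abs(v) < SNAP_TOL:
        return 0.0
    if abs(v - 1.0) < SNAP_TOL:
        return 1.0
    return v


def _residual(sys: TwoPatchSystem, u: np.ndarray) -> float:
    return float(np.max(np.abs(vector_field_frequency(sys, u))))


# ---------------------------------------------------------------------------
# density subsystem
# ---------------------------------------------------------------------------

def _density_rhs(sys: TwoPatchSystem, p: float, q: float, n1: float, n2: float):
    fbar = sys.gameA.mean_payoff(p)
    gbar = sys.gameB.mean_payoff(q)
    return (
        (fbar + sys.alpha1 - sys.beta1 * n1) * n1 - sys.c1 * n1 + sys.c2 * n2,
        (gbar + sys.alpha2 - sys.beta2 * n2) * n2 - sys.c2 * n2 + sys.c1 * n1,
    )


def solve_density(sys: TwoPatchSystem, p: float, q: float) -> tuple[float, float]:
    """Unique positive equilibrium ``(n1, n2)`` of the density subsystem at
    fixed frequencies ``(p, q)``.

    The trivial root (0, 0) is excluded. With both migration rates positive
    the problem reduces to one dimension: expressing ``n2`` through the
    patch-1 balance turns the patch-2 balance into a scalar function of
    ``n1`` that is positive at the left end of the admissible interval and
    eventually negative, so a bracketed root always exists and, by
    uniqueness of the positive intersection, is the solution. The bracketed
    root is then polished by Newton iterations on the 2-D system.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise DomainError("frequencies must lie in [0, 1]")
    fbar = sys.gameA.mean_payoff(p)
    gbar = sys.gameB.mean_payoff(q)
    a1 = fbar + sys.alpha1 - sys.c1   # > 0 by alpha > c and payoffs >= 0
    a2 = gbar + sys.alpha2 - sys.c2
    b1, b2 = sys.beta1, sys.beta2
    c1, c2 = sys.c1, sys.c2

    if c1 == 0.0 and c2 == 0.0:
        return a1 / b1, a2 / b2
    if c2 == 0.0:
        n1 = a1 / b1
        n2 = (a2 + math.sqrt(a2 * a2 + 4.0 * b2 * c1 * n1)) / (2.0 * b2)
        return n1, n2
    if c1 == 0.0:
        n2 = a2 / b2
        n1 = (a1 + math.sqrt(a1 * a1 + 4.0 * b1 * c2 * n2)) / (2.0 * b1)
        return n1, n2

    # general case: n2(n1) from the patch-1 balance, root in n1
    k1 = a1 / b1

    def n2_of(n1: float) -> float:
        return n1 * (b1 * n1 - a1) / c2

    def resid(n1: float) -> float:
        n2 = n2_of(n1)
        return a2 * n2 - b2 * n2 * n2 + c1 * n1

    lo = k1
    step = max(k1, 1.0 / b1)
    hi = lo + step
    for _ in range(200):
        if resid(hi) < 0.0:
            break
        hi += step
        step *= 2.0
    else:  # pragma: no cover - cannot happen for valid parameters
        raise RuntimeError("density solver failed to bracket the positive root")
    n1 = brentq(resid, lo, hi, xtol=1e-13, rtol=1e-15)
    n2 = n2_of(n1)

    # Newton polish on the full 2-D balance
    for _ in range(5):
        r1, r2 = _density_rhs(sys, p, q, n1, n2)
        j11 = fbar + sys.alpha1 - 2.0 * b1 * n1 - c1
        j22 = gbar + sys.alpha2 - 2.0 * b2 * n2 - c2
        det = j11 * j22 - c1 * c2
        if det == 0.0:
            break
        dn1 = (r1 * j22 - c2 * r2) / det
        dn2 = (j11 * r2 - c1 * r1) / det
        n1, n2 = n1 - dn1, n2 - dn2
        if max(abs(r1), abs(r2)) < 1e-13 * max(1.0, a1 * n1, a2 * n2):
            break
    if n1 <= 0 or n2 <= 0:  # pragma: no cover
        raise RuntimeError("density solver left the positive quadrant")
    return float(n1), float(n2)


def density_grid(sys: TwoPatchSystem, P: np.ndarray, Q: np.ndarray):
    """Vectorized positive density solution on arrays of (p, q).

    Uses the same 1-D reduction as :func:`solve_density`, with vectorized
    bracketing and bisection. Requires both migration rates positive.
    """
    if sys.c1 <= 0 or sys.c2 <= 0:
        raise DomainError("density_grid requires c1 > 0 and c2 > 0")
    A, B = sys.gameA, sys.gameB
    f1 = P * A.a11 + (1 - P) * A.a12
    f2 = P * A.a21 + (1 - P) * A.a22
    fbar = P * f1 + (1 - P) * f2
    g1 = Q * B.a11 + (1 - Q) * B.a12
    g2 = Q * B.a21 + (1 - Q) * B.a22
    gbar = Q * g1 + (1 - Q) * g2
    a1 = fbar + sys.alpha1 - sys.c1
    a2 = gbar + sys.alpha2 - sys.c2
    b1, b2, c1, c2 = sys.beta1, sys.beta2, sys.c1, sys.c2

    def resid(n1):
        n2 = n1 * (b1 * n1 - a1) / c2
        return a2 * n2 - b2 * n2 * n2 + c1 * n1

    lo = a1 / b1
    step = np.maximum(lo, 1.0 / b1)
    hi = lo + step
    for _ in range(200):
        mask = resid(hi) >= 0.0
        if not mask.any():
            break
        step = np.where(mask, step * 2.0, step)
        hi = np.where(mask, hi + step, hi)
    else:  # pragma: no cover
        raise RuntimeError("vectorized density bracketing failed")
    lo = lo.copy() if isinstance(lo, np.ndarray) else np.full_like(hi, lo)
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        pos = resid(mid) > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    n1 = 0.5 * (lo + hi)
    n2 = n1 * (b1 * n1 - a1) / c2
    return n1, np.maximum(n2, 1e-300)


# ---------------------------------------------------------------------------
# per-patch rest frequencies
# ---------------------------------------------------------------------------

def _rest_frequencies(game, stable_only: bool) -> list[float]:
    """Rest points of the single-patch replicator dynamics; optionally only
    those that are asymptotically stable (the pure ESSs / interior ESS)."""
    rep = classify_game(game)
    if not stable_only:
        out = [0.0, 1.0]
        if rep.interior_candidate is not None:
            out.append(rep.interior_candidate)
        return out
    out = []
    if rep.r2_pure_ess:
        out.append(0.0)
    if rep.r1_pure_ess:
        out.append(1.0)
    if rep.interior_is_ess:
        out.append(rep.interior_candidate)
    return out


# ---------------------------------------------------------------------------
# symmetric equilibria
# ---------------------------------------------------------------------------

def _make_equilibrium(
    sys: TwoPatchSystem, p: float, q: float, n1: float, n2: float,
    kind: str, branch: float | None = None,
) -> Equilibrium:
    u = np.array([p, q, n1, n2])
    return Equilibrium(p, q, n1, n2, kind, _residual(sys, u), branch=branch)


def symmetric_equilibria(sys: TwoPatchSystem) -> list[Equilibrium]:
    """The two monomorphic symmetric boundary equilibria (always present)
    plus the symmetric interior equilibrium in the special case where the
    two games share the same interior rest frequency."""
    out = []
    for v in (1.0, 0.0):
        n1, n2 = solve_density(sys, v, v)
        out.append(_make_equilibrium(sys, v, v, n1, n2, "symmetric-boundary"))
    ps = interior_rest_point(sys.gameA)
    qs = interior_rest_point(sys.gameB)
    if ps is not None and qs is not None and abs(ps - qs) < 1e-12:
        n1, n2 = solve_density(sys, ps, qs)
        out.append(_make_equilibrium(sys, ps, ps, n1, n2, "symmetric-interior"))
    return out


# ---------------------------------------------------------------------------
# one-way migration (source-sink) case: c1 > 0, c2 = 0
# ---------------------------------------------------------------------------

def _case1_freq_residual(sys: TwoPatchSystem, p_hat: float, n1_hat: float, q):
    """Stationarity residual for the patch-2 frequency when migration is
    one-way: q(1-q)(g1-g2) + ((p_hat - q)/2) * (sqrt((alpha2+gbar)^2 +
    4 beta2 c1 n1_hat) - (alpha2+gbar)).

    The square-root term is the influx correction c1*n1/n2 evaluated at the
    positive root of the patch-2 density balance; the mean payoff gbar is a
    function of q, so the whole expression is an explicit scalar function
    whose zeros in [0, 1] are the admissible patch-2 rest frequencies.
    """
    B = sys.gameB
    q = np.asarray(q, dtype=float)
    g1 = q * B.a11 + (1 - q) * B.a12
    g2 = q * B.a21 + (1 - q) * B.a22
    gbar = q * g1 + (1 - q) * g2
    a2 = sys.alpha2 + gbar
    root = np.sqrt(a2 * a2 + 4.0 * sys.beta2 * sys.c1 * n1_hat)
    return q * (1 - q) * (g1 - g2) + 0.5 * (p_hat - q) * (root - a2)


def _case1_n2(sys: TwoPatchSystem, n1_hat: float, q: float) -> float:
    gbar = sys.gameB.mean_payoff(q)
    a2 = sys.alpha2 + gbar
    return (a2 + math.sqrt(a2 * a2 + 4.0 * sys.beta2 * sys.c1 * n1_hat)) / (
        2.0 * sys.beta2
    )


def case1_equilibria(
    sys: TwoPatchSystem,
    branches: str = "stable",
    n_scan: int = 4001,
) -> EquilibriumSet:
    """All equilibria when migration is one-way (``c1 > 0``, ``c2 = 0``).

    Patch 1 evolves autonomously, so its frequency settles at a rest point
    ``p_hat`` in {0, 1, p*}; for each such branch the patch-2 frequency must
    zero the explicit residual of :func:`_case1_freq_residual`. By default
    only branches with ``p_hat`` asymptotically stable in patch 1 are
    enumerated (boundary roots q = 0/1 occur exactly when p_hat is the same
    boundary, reproducing the symmetric boundary equilibria, which are added
    unconditionally); ``branches="all"`` also enumerates the equilibria
    hanging off an unstable patch-1 rest point.
    """
    if sys.c2 != 0.0 or sys.c1 <= 0.0:
        raise DomainError(
            "case1_equilibria requires c1 > 0 and c2 = 0; use "
            "enumerate_equilibria for automatic routing"
        )
    if branches not in ("stable", "all"):
        raise ValueError("branches must be 'stable' or 'all'")

    eqs = symmetric_equilibria(sys)
    for p_hat in _rest_frequencies(sys.gameA, stable_only=branches == "stable"):
        n1_hat = (sys.alpha1 + sys.gameA.mean_payoff(p_hat) - sys.c1) / sys.beta1
        qs = np.linspace(1e-9, 1.0 - 1e-9, n_scan)
        r = _case1_freq_residual(sys, p_hat, n1_hat, qs)
        sign = np.sign(r)
        q_roots = [
            brentq(
                lambda q: float(_case1_freq_residual(sys, p_hat, n1_hat, q)),
                qs[i], qs[i + 1], xtol=1e-14, rtol=1e-15,
            )
            for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        ]
        # exact zeros on the grid (possible for round payoff values)
        q_roots.extend(float(qs[i]) for i in np.nonzero(r == 0.0)[0])
        for q_hat in q_roots:
            q_hat = _snap(q_hat)
            n2_hat = _case1_n2(sys, n1_hat, q_hat)
            if q_hat in (0.0, 1.0):
                kind = "symmetric-boundary"
            elif abs(p_hat - q_hat) < SNAP_TOL:
                kind = "symmetric-interior"
            elif p_hat in (0.0, 1.0):
                kind = "case1-boundary-q"
            else:
                kind = "case1-interior"
            eqs.append(
                _make_equilibrium(sys, p_hat, q_hat, n1_hat, n2_hat, kind, branch=p_hat)
            )
    return EquilibriumSet(_dedup(sys, eqs))


# ---------------------------------------------------------------------------
# decoupled case: c1 = c2 = 0
# ---------------------------------------------------------------------------

def decoupled_equilibria(sys: TwoPatchSystem) -> EquilibriumSet:
    """Product enumeration for isolated patches: every pair of per-patch
    rest frequencies, each with its own logistic carrying density."""
    if sys.c1 != 0.0 or sys.c2 != 0.0:
        raise DomainError("decoupled_equilibria requires c1 = c2 = 0")
    eqs = []
    for p_hat in _rest_frequencies(sys.gameA, stable_only=False):
        for q_hat in _rest_frequencies(sys.gameB, stable_only=False):
            n1 = (sys.alpha1 + sys.gameA.mean_payoff(p_hat)) / sys.beta1
            n2 = (sys.alpha2 + sys.gameB.mean_payoff(q_hat)) / sys.beta2
            if p_hat == q_hat and p_hat in (0.0, 1.0):
                kind = "symmetric-boundary"
            elif abs(p_hat - q_hat) < SNAP_TOL:
                kind = "symmetric-interior"
            else:
                kind = "decoupled"
            eqs.append(_make_equilibrium(sys, p_hat, q_hat, n1, n2, kind))
    return EquilibriumSet(_dedup(sys, eqs))


# ---------------------------------------------------------------------------
# general two-way migration case: c1, c2 > 0
# ---------------------------------------------------------------------------

def _newton_polish(
    sys: TwoPatchSystem, u: np.ndarray, max_iter: int = 60
) -> np.ndarray | None:
    """Damped Newton iteration on the 4-D stationarity system using the
    analytic Jacobian; returns None on failure to converge."""
    u = u.copy()
    r = vector_field_frequency(sys, np.clip(u, [0, 0, 1e-12, 1e-12], [1, 1, np.inf, np.inf]))
    rnorm = np.max(np.abs(r))
    for _ in range(max_iter):
        if rnorm < 1e-12 * max(1.0, np.max(np.abs(u))):
            return u
        try:
            J = frequency_jacobian(sys, u)
            step = np.linalg.solve(J, r)
        except (np.linalg.LinAlgError, DomainError):
            return None
        lam = 1.0
        for _ in range(40):
            v = u - lam * step
            v[:2] = np.clip(v[:2], 0.0, 1.0)
            if v[2] <= 0 or v[3] <= 0:
                lam *= 0.5
                continue
            rv = vector_field_frequency(sys, v)
            rvnorm = np.max(np.abs(rv))
            if rvnorm < rnorm:
                u, r, rnorm = v, rv, rvnorm
                break
            lam *= 0.5
        else:
            return u if rnorm < RESIDUAL_TOL else None
    return u if rnorm < RESIDUAL_TOL else None


def general_equilibria(sys: TwoPatchSystem, grid: int = 201) -> EquilibriumSet:
    """All equilibria with two-way migration (``c1, c2 > 0``).

    Boundary equilibria are the two symmetric monomorphic states only
    (asymmetric boundary states are impossible: at p = 0 < q the immigration
    term makes dp/dt > 0). Interior equilibria are located by evaluating the
    two frequency stationarity residuals on a ``grid x grid`` mesh with
    densities from the density subsystem; cells where both residuals change
    sign seed a damped Newton polish of the full system. When both games
    have interior rest points, cells violating the sign identity
    ``Delta1 Delta2 p(1-p)q(1-q)(p-p*)(q-q*) <= 0`` are skipped.
    """
    if sys.c1 <= 0.0 or sys.c2 <= 0.0:
        raise DomainError(
            "general_equilibria requires c1 > 0 and c2 > 0; use "
            "enumerate_equilibria for automatic routing"
        )
    eqs = symmetric_equilibria(sys)

    ps = np.linspace(0.0, 1.0, grid)
    P, Q = np.meshgrid(ps, ps, indexing="ij")
    N1, N2 = density_grid(sys, P, Q)
    A, B = sys.gameA, sys.gameB
    f1 = P * A.a11 + (1 - P) * A.a12
    f2 = P * A.a21 + (1 - P) * A.a22
    g1 = Q * B.a11 + (1 - Q) * B.a12
    g2 = Q * B.a21 + (1 - Q) * B.a22
    R1 = P * (1 - P) * (f1 - f2) + sys.c2 * (Q - P) * N2 / N1
    R2 = Q * (1 - Q) * (g1 - g2) + sys.c1 * (P - Q) * N1 / N2

    def corner_sign_change(R):
        s = np.sign(R)
        mx = np.maximum.reduce([s[:-1, :-1], s[1:, :-1], s[:-1, 1:], s[1:, 1:]])
        mn = np.minimum.reduce([s[:-1, :-1], s[1:, :-1], s[:-1, 1:], s[1:, 1:]])
        return mx != mn

    cells = corner_sign_change(R1) & corner_sign_change(R2)

    p_star = interior_rest_point(A)
    q_star = interior_rest_point(B)
    if p_star is not None and q_star is not None:
        lhs = (
            A.delta * B.delta
            * P * (1 - P) * Q * (1 - Q) * (P - p_star) * (Q - q_star)
        )
        admissible = np.minimum.reduce(
            [lhs[:-1, :-1], lhs[1:, :-1], lhs[:-1, 1:], lhs[1:, 1:]]
        ) <= 1e-12
        cells &= admissible

    n_polished = 0
    for i, j in zip(*np.nonzero(cells)):
        u0 = np.array(
            [
                0.5 * (ps[i] + ps[i + 1]),
                0.5 * (ps[j] + ps[j + 1]),
                0.25 * (N1[i, j] + N1[i + 1, j] + N1[i, j + 1] + N1[i + 1, j + 1]),
                0.25 * (N2[i, j] + N2[i + 1, j] + N2[i, j + 1] + N2[i + 1, j + 1]),
            ]
        )
        u = _newton_polish(sys, u0)
        n_polished += 1
        if u is None:
            log.debug("non-convergent polish from cell (%d, %d) dropped", i, j)
            continue
        p_hat, q_hat = _snap(u[0]), _snap(u[1])
        if p_hat in (0.0, 1.0) or q_hat in (0.0, 1.0):
            continue  # converged onto a symmetric boundary state, already listed
        if u[2] <= 0 or u[3] <= 0:
            continue
        res = _residual(sys, u)
        if res > RESIDUAL_TOL:
            continue
        eqs.append(
            Equilibrium(float(u[0]), float(u[1]), float(u[2]), float(u[3]),
                        "general-interior", res)
        )
    log.info(
        "general enumeration: grid=%d, %d candidate cells, %d equilibria",
        grid, n_polished, len(eqs),
    )
    return EquilibriumSet(_dedup(sys, eqs))


# ---------------------------------------------------------------------------
# reduced-curve intersections (two-way migration)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveIntersection:
    """An intersection of the two reduced stationarity curves on the
    (p, q) plane, with the patch densities implied by the reduction.

    Eliminating n1 via the patch-1 equations and n2 via the patch-2
    equations turns the 4-D stationarity system into two polynomial curves
    in (p, q); every positive equilibrium is an intersection, but an
    intersection need not be an equilibrium: the implied density of a patch
    can come out negative (or zero, the extinct state). ``positive`` flags
    the intersections that are genuine positive equilibria.
    """

    p: float
    q: float
    n1: float
    n2: float
    positive: bool


def _reduced_curves(sys: TwoPatchSystem, P, Q):
    """Polynomial residuals (G1, G2) of the two reduced stationarity curves
    and the implied densities; poles at p = q are cleared by multiplying
    through by (p - q)^2."""
    A, B = sys.gameA, sys.gameB
    f1 = P * A.a11 + (1 - P) * A.a12
    f2 = P * A.a21 + (1 - P) * A.a22
    g1 = Q * B.a11 + (1 - Q) * B.a12
    g2 = Q * B.a21 + (1 - Q) * B.a22
    fbar = P * f1 + (1 - P) * f2
    gbar = Q * g1 + (1 - Q) * g2
    X = P * (1 - P) * (f1 - f2)
    Y = Q * (1 - Q) * (g1 - g2)
    u = P - Q
    a1f = fbar + sys.alpha1 - sys.c1
    a2g = gbar + sys.alpha2 - sys.c2
    t1 = (a1f * u + X) / sys.beta1       # = u * n1
    t2 = (a2g * u - Y) / sys.beta2       # = u * n2
    G1 = -X * t1 + sys.c2 * t2 * u       # = u^2 * (patch-1 density balance)
    G2 = Y * t2 + sys.c1 * t1 * u        # = u^2 * (patch-2 density balance)
    with np.errstate(divide="ignore", invalid="ignore"):
        N1 = t1 / u
        N2 = t2 / u
    return G1, G2, N1, N2


def curve_intersections(
    sys: TwoPatchSystem, grid: int = 1501
) -> list[CurveIntersection]:
    """All intersections of the reduced stationarity curves in the open
    unit square (``c1, c2 > 0``).

    This reproduces the planar construction used to visualize and count
    equilibrium candidates with two-way migration: sign-change cells of the
    two polynomial residuals seed a 2-D Newton polish. Intersections whose
    implied densities are not both positive are retained but flagged
    ``positive=False`` -- they are artifacts of the algebraic reduction
    (including the extinct state), not equilibria of the dynamics.
    """
    if sys.c1 <= 0.0 or sys.c2 <= 0.0:
        raise DomainError("curve_intersections requires c1 > 0 and c2 > 0")
    ps = np.linspace(0.0, 1.0, grid)
    P, Q = np.meshgrid(ps, ps, indexing="ij")
    G1, G2, _, _ = _reduced_curves(sys, P, Q)

    def corner_change(R):
        s = np.sign(R)
        mx = np.maximum.reduce([s[:-1, :-1], s[1:, :-1], s[:-1, 1:], s[1:, 1:]])
        mn = np.minimum.reduce([s[:-1, :-1], s[1:, :-1], s[:-1, 1:], s[1:, 1:]])
        return mx != mn

    cells = corner_change(G1) & corner_change(G2)
    out: list[CurveIntersection] = []

    def resid(v):
        g1v, g2v, _, _ = _reduced_curves(sys, v[0], v[1])
        return np.array([float(g1v), float(g2v)])

    cell_scale = np.maximum.reduce(
        [np.abs(G1[:-1, :-1]), np.abs(G1[1:, 1:]), np.abs(G2[:-1, :-1]), np.abs(G2[1:, 1:])]
    )
    for i, j in zip(*np.nonzero(cells)):
        v0 = np.array([0.5 * (ps[i] + ps[i + 1]), 0.5 * (ps[j] + ps[j + 1])])
        v, info, ier, _ = fsolve(resid, v0, full_output=True, xtol=1e-13)
        if ier != 1:
            continue
        if np.max(np.abs(info["fvec"])) > 1e-9 * max(1.0, cell_scale[i, j]):
            continue
        p_hat, q_hat = float(v[0]), float(v[1])
        if not (SNAP_TOL < p_hat < 1 - SNAP_TOL and SNAP_TOL < q_hat < 1 - SNAP_TOL):
            continue
        if abs(p_hat - q_hat) < 1e-8:
            continue  # cleared-pole artifact on the diagonal
        if any(abs(p_hat - c.p) < 1e-7 and abs(q_hat - c.q) < 1e-7 for c in out):
            continue
        _, _, N1, N2 = _reduced_curves(sys, np.array(p_hat), np.array(q_hat))
        n1, n2 = float(N1), float(N2)
        positive = n1 > 0.0 and n2 > 0.0
        if positive:
            res = _residual(sys, np.array([p_hat, q_hat, n1, n2]))
            positive = res < 1e-6
        out.append(CurveIntersection(p_hat, q_hat, n1, n2, positive))
    return sorted(out, key=lambda c: (c.p, c.q))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def enumerate_equilibria(
    sys: TwoPatchSystem,
    grid: int = 201,
    case1_branches: str = "stable",
) -> EquilibriumSet:
    """Enumerate all positive equilibria, routing on the migration pattern.

    ``c1 = c2 = 0`` uses the exact per-patch product; exactly one positive
    rate uses the one-way (source-sink) construction (patches are swapped
    and swapped back when the flow runs 2 -> 1); both positive uses the
    grid-seeded Newton search.
    """
    if sys.c1 == 0.0 and sys.c2 == 0.0:
        return decoupled_equilibria(sys)
    if sys.c2 == 0.0:
        return case1_equilibria(sys, branches=case1_branches)
    if sys.c1 == 0.0:
        swapped = case1_equilibria(sys.swapped_patches(), branches=case1_branches)
        out = []
        for e in swapped:
            kind = e.kind.replace("-q", "-p") if "case1" in e.kind else e.kind
            out.append(
                Equilibrium(e.q, e.p, e.n2, e.n1, kind,
                            e.residual, branch=e.branch)
            )
        return EquilibriumSet(out)
    return general_equilibria(sys, grid=grid)
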