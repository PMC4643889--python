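"""Spectral stability classification of equilibria.

Each equilibrium is classified by the eigenvalues of the Jacobian of the
frequency-form dynamics (p, q, n1, n2). The Jacobian is available in closed
form everywhere both densities are positive; a central finite-difference
Jacobian serves as an independent cross-check. The empty state (both
patches extinct) is handled separately through the growth block of the
density equations, where the frequency form is singular.

An equilibrium is labelled ``stable`` when the spectral abscissa (largest
real part) is below ``-tol``, ``unstable`` above ``+tol`` and ``marginal``
in between; marginal spectra indicate a bifurcation point and are reported
as such rather than forced into a binary label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .equilibria import Equilibrium, EquilibriumSet
from .model import TwoPatchSystem, frequency_jacobian, vector_field_frequency

__all__ = [
    "StabilityReport",
    "analytic_jacobian",
    "numeric_jacobian",
    "case1_jacobian",
    "classify_stability",
    "classify_all",
]

log = logging.getLogger(__name__)

MARGINAL_TOL = 1e-8
CROSS_CHECK_TOL = 1e-6


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray
    max_real_part: float
    label: str
    source: str


def analytic_jacobian(sys: TwoPatchSystem, eq: Equilibrium | np.ndarray) -> np.ndarray:
    """Closed-form Jacobian of the frequency dynamics at an equilibrium (or
    any point with positive densities)."""
    u = eq.state if isinstance(eq, Equilibrium) else np.asarray(eq, dtype=float)
    return frequency_jacobian(sys, u)


def numeric_jacobian(
    sys: TwoPatchSystem, eq: Equilibrium | np.ndarray, rel_step: float = 1e-6
) -> np.ndarray:
    """Finite-difference Jacobian of the frequency dynamics.

    Central differences in the interior; second-order one-sided stencils
    toward the interior at boundary frequencies (first-order one-sided steps
    would leave O(h) truncation errors far above the agreement tolerance
    with the analytic Jacobian).
    """
    u = eq.state if isinstance(eq, Equilibrium) else np.asarray(eq, dtype=float)
    f = lambda v: vector_field_frequency(sys, v)  # noqa: E731
    J = np.empty((4, 4))
    for k in range(4):
        h = rel_step * (1.0 + abs(u[k]))
        if k < 2:
            lo_ok = u[k] - h >= 0.0
            hi_ok = u[k] + h <= 1.0
        else:
            lo_ok = u[k] - h > 0.0
            hi_ok = True

        def shifted(m: float) -> np.ndarray:
            v = u.copy()
            v[k] += m * h
            return v

        if lo_ok and hi_ok:
            J[:, k] = (f(shifted(1)) - f(shifted(-1))) / (2 * h)
        elif hi_ok:
            J[:, k] = (-3 * f(u) + 4 * f(shifted(1)) - f(shifted(2))) / (2 * h)
        else:
            J[:, k] = (3 * f(u) - 4 * f(shifted(-1)) + f(shifted(-2))) / (2 * h)
    return J


def case1_jacobian(sys: TwoPatchSystem, eq: Equilibrium) -> np.ndarray:
    """2x2 Jacobian of the autonomous patch-2 subsystem (q, n2) in the
    one-way migration case, evaluated at an equilibrium of that subsystem.

    Entries: [[d/dq of the q-equation - c1 n1/n2, -(p - q) c1 n1 / n2^2],
    [n2 dgbar/dq, -c1 n1/n2 - beta2 n2]].
    """
    B = sys.gameB
    p, q, n1, n2 = eq.state
    g1 = q * B.a11 + (1 - q) * B.a12
    g2 = q * B.a21 + (1 - q) * B.a22
    t = g1 - g2
    dgbar = t + q * (B.a11 - B.a12) + (1 - q) * (B.a21 - B.a22)
    d_repl = (1 - 2 * q) * t + q * (1 - q) * B.delta
    return np.array(
        [
            [d_repl - sys.c1 * n1 / n2, -(p - q) * sys.c1 * n1 / n2**2],
            [dgbar * n2, -sys.c1 * n1 / n2 - sys.beta2 * n2],
        ]
    )


def case1_interior_stable(sys: TwoPatchSystem, eq: Equilibrium) -> bool:
    """Trace/determinant stability conditions for an interior rest point of
    the patch-2 subsystem under one-way migration (negative trace and
    positive determinant of the 2x2 Jacobian)."""
    J = case1_jacobian(sys, eq)
    return float(np.trace(J)) < 0.0 and float(np.linalg.det(J)) > 0.0


def _origin_eigenvalues(sys: TwoPatchSystem, p: float, q: float) -> np.ndarray:
    """Eigenvalues of the density growth block at the empty state: the
    linearization of (n1, n2) around (0, 0) at frozen frequencies. Its trace
    is positive whenever alpha_i > c_i, so the empty state is unstable."""
    fbar = sys.gameA.mean_payoff(p)
    gbar = sys.gameB.mean_payoff(q)
    M = np.array(
        [
            [fbar + sys.alpha1 - sys.c1, sys.c2],
            [sys.c1, gbar + sys.alpha2 - sys.c2],
        ]
    )
    return np.linalg.eigvals(M)


def classify_stability(
    sys: TwoPatchSystem,
    eq: Equilibrium,
    tol: float = MARGINAL_TOL,
    cross_check: bool = True,
) -> StabilityReport:
    """Fill and return the spectral stability report for one equilibrium.

    The analytic Jacobian provides the spectrum; when ``cross_check`` is on,
    the finite-difference Jacobian must agree entrywise within 1e-6 (scaled
    by the matrix magnitude), in which case the source is recorded as
    "both".
    """
    if eq.kind == "origin":
        eigs = _origin_eigenvalues(sys, eq.p, eq.q)
        report = StabilityReport(eigs, float(np.max(np.real(eigs))), "unstable", "analytic")
        eq.eigenvalues = eigs
        eq.stability = report.label
        return report

    J = analytic_jacobian(sys, eq)
    source = "analytic"
    if cross_check:
        Jn = numeric_jacobian(sys, eq)
        scale = max(1.0, float(np.max(np.abs(J))))
        if np.max(np.abs(J - Jn)) <= CROSS_CHECK_TOL * scale:
            source = "both"
        else:  # pragma: no cover - indicates a defect, surfaced loudly
            log.warning(
                "analytic and numeric Jacobians disagree at p=%.6g q=%.6g "
                "(max diff %.3g)", eq.p, eq.q, float(np.max(np.abs(J - Jn))),
            )
    eigs = np.linalg.eigvals(J)
    max_re = float(np.max(np.real(eigs)))
    if max_re < -tol:
        label = "stable"
    elif max_re > tol:
        label = "unstable"
    else:
        label = "marginal"
        log.warning(
            "marginal spectrum (max Re = %.3g) at p=%.6g q=%.6g: "
            "likely a bifurcation point", max_re, eq.p, eq.q,
        )
    eq.eigenvalues = eigs
    eq.stability = label
    return StabilityReport(eigs, max_re, label, source)


def classify_all(
    sys: TwoPatchSystem, eqset: EquilibriumSet, tol: float = MARGINAL_TOL,
    cross_check: bool = True,
) -> EquilibriumSet:
    """Classify every equilibrium in the set in place and return the set."""
    for eq in eqset:
        classify_stability(sys, eq, tol=tol, cross_check=cross_check)
    return eqset
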