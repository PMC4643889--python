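"""Core model: parameter types, states and the coupled replicator-migration vector fields.

The model describes a population of two phenotypes (R1, R2) living in two
habitat patches. Within each patch individuals meet in random pairwise
contests governed by a 2x2 payoff matrix (A in patch 1, B in patch 2) and
receive a density-dependent background fitness ``alpha - beta * n`` where
``n`` is the total density in the patch. Individuals move between patches
at phenotype-independent per-capita rates ``c1`` (patch 1 -> 2) and ``c2``
(patch 2 -> 1).

Two equivalent coordinate systems are provided:

* abundance coordinates ``(x1, x2, y1, y2)`` -- numbers of each phenotype
  in each patch; the vector field is smooth on the closed positive orthant
  and is the one used for numerical integration;
* frequency coordinates ``(p, q, n1, n2)`` -- frequency of R1 in each patch
  plus total patch densities; this is the replicator-like form used for
  equilibrium analysis, singular where a patch is empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Game2x2",
    "PatchEnv",
    "TwoPatchSystem",
    "SystemState",
    "DomainError",
    "patch_payoffs",
    "vector_field_abundance",
    "vector_field_frequency",
    "convert_state",
    "abundance_to_frequency",
    "frequency_to_abundance",
]


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class Game2x2:
    """A 2x2 symmetric matrix game with payoff entries ``a[i][j]`` for the
    row phenotype Ri against the column phenotype Rj.

    Entries are required to be non-negative (payoffs are fitness
    increments); pass ``allow_negative=True`` to relax this, which keeps the
    dynamics well defined but leaves the modelling assumptions.
    """

    a11: float
    a12: float
    a21: float
    a22: float
    allow_negative: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        entries = (self.a11, self.a12, self.a21, self.a22)
        if not all(np.isfinite(entries)):
            raise DomainError("payoff entries must be finite numbers")
        if min(entries) < 0:
            if not self.allow_negative:
                raise DomainError(
                    "negative payoff entries violate the non-negativity "
                    "assumption; pass allow_negative=True to override"
                )
            warnings.warn(
                "negative payoff entries: outside the model's stated "
                "assumptions, proceeding anyway",
                stacklevel=3,
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=float)

    @property
    def delta(self) -> float:
        """Gap parameter ``a11 - a12 - a21 + a22``; its sign separates
        bistable (coordination) games from hawk-dove games."""
        return self.a11 - self.a12 - self.a21 + self.a22

    @property
    def max_payoff(self) -> float:
        return max(self.a11, self.a12, self.a21, self.a22)

    def payoffs(self, freq: float) -> tuple[float, float, float]:
        """Expected payoffs ``(f1, f2)`` and the population mean payoff at
        R1-frequency ``freq``."""
        if not 0.0 <= freq <= 1.0:
            raise DomainError(f"frequency {freq} outside [0, 1]")
        f1 = freq * self.a11 + (1.0 - freq) * self.a12
        f2 = freq * self.a21 + (1.0 - freq) * self.a22
        return f1, f2, freq * f1 + (1.0 - freq) * f2

    def mean_payoff(self, freq: float) -> float:
        return self.payoffs(freq)[2]


def patch_payoffs(game: Game2x2, freq: float) -> tuple[float, float, float]:
    """Per-phenotype payoffs and mean payoff in one patch.

    ``f_i = freq * a_i1 + (1 - freq) * a_i2`` and the mean is
    ``freq * f1 + (1 - freq) * f2``.
    """
    return game.payoffs(freq)


@dataclass(frozen=True)
class PatchEnv:
    """Per-patch environment: background fitness ``alpha - beta * n`` and
    the per-capita emigration rate ``c_out`` toward the other patch.

    ``alpha > c_out`` is enforced: a nearly empty patch must still grow,
    i.e. migration losses may not exceed the intrinsic growth rate.
    """

    alpha: float
    beta: float
    c_out: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise DomainError("density-dependence coefficient beta must be > 0")
        if self.c_out < 0:
            raise DomainError("migration rate must be non-negative")
        if self.c_out >= self.alpha:
            raise DomainError(
                f"migration rate c_out={self.c_out} must be smaller than the "
                f"intrinsic growth rate alpha={self.alpha}"
            )


@dataclass(frozen=True)
class TwoPatchSystem:
    """Full parameterization: game A and environment for patch 1, game B and
    environment for patch 2."""

    gameA: Game2x2
    gameB: Game2x2
    env1: PatchEnv
    env2: PatchEnv

    @property
    def c1(self) -> float:
        return self.env1.c_out

    @property
    def c2(self) -> float:
        return self.env2.c_out

    @property
    def alpha1(self) -> float:
        return self.env1.alpha

    @property
    def alpha2(self) -> float:
        return self.env2.alpha

    @property
    def beta1(self) -> float:
        return self.env1.beta

    @property
    def beta2(self) -> float:
        return self.env2.beta

    def density_scale(self) -> tuple[float, float]:
        """Rough carrying-capacity scales ``(alpha_i + max payoff) / beta_i``
        used for non-dimensionalizing densities in distance measures."""
        return (
            (self.alpha1 + self.gameA.max_payoff) / self.beta1,
            (self.alpha2 + self.gameB.max_payoff) / self.beta2,
        )

    def swapped_patches(self) -> "TwoPatchSystem":
        """The same system with the patch labels exchanged."""
        return TwoPatchSystem(self.gameB, self.gameA, self.env2, self.env1)


ABUNDANCE = "abundance"
FREQUENCY = "frequency"


@dataclass(frozen=True)
class SystemState:
    """A point of the dynamics in either coordinate system.

    ``rep == "abundance"``: vec = (x1, x2, y1, y2), all >= 0.
    ``rep == "frequency"``: vec = (p, q, n1, n2) with p, q in [0, 1] and
    n1, n2 >= 0.
    """

    rep: str
    vec: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.rep not in (ABUNDANCE, FREQUENCY):
            raise DomainError(f"unknown representation {self.rep!r}")
        v = np.asarray(self.vec, dtype=float)
        if v.shape != (4,):
            raise DomainError("state vector must have four components")
        if self.rep == ABUNDANCE:
            if np.any(v < 0):
                raise DomainError("abundances must be non-negative")
        else:
            p, q, n1, n2 = v
            if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
                raise DomainError("frequencies must lie in [0, 1]")
            if n1 < 0 or n2 < 0:
                raise DomainError("densities must be non-negative")
        object.__setattr__(self, "vec", tuple(float(x) for x in v))

    @classmethod
    def from_abundance(cls, x1: float, x2: float, y1: float, y2: float) -> "SystemState":
        return cls(ABUNDANCE, (x1, x2, y1, y2))

    @classmethod
    def from_frequency(cls, p: float, q: float, n1: float, n2: float) -> "SystemState":
        return cls(FREQUENCY, (p, q, n1, n2))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vec, dtype=float)

    def convert(self, target: str) -> "SystemState":
        return convert_state(self, target)


def abundance_to_frequency(u: np.ndarray) -> np.ndarray:
    """Map (x1, x2, y1, y2) -> (p, q, n1, n2); requires both patches occupied."""
    x1, x2, y1, y2 = u
    n1 = x1 + x2
    n2 = y1 + y2
    if n1 <= 0 or n2 <= 0:
        raise DomainError("conversion to frequency form requires n1 > 0 and n2 > 0")
    return np.array([x1 / n1, y1 / n2, n1, n2])


def frequency_to_abundance(u: np.ndarray) -> np.ndarray:
    """Map (p, q, n1, n2) -> (x1, x2, y1, y2)."""
    p, q, n1, n2 = u
    return np.array([p * n1, (1.0 - p) * n1, q * n2, (1.0 - q) * n2])


def convert_state(state: SystemState, target: str) -> SystemState:
    if target not in (ABUNDANCE, FREQUENCY):
        raise DomainError(f"unknown representation {target!r}")
    if target == state.rep:
        raise DomainError("target representation equals the current one")
    if target == FREQUENCY:
        return SystemState(FREQUENCY, tuple(abundance_to_frequency(state.array)))
    return SystemState(ABUNDANCE, tuple(frequency_to_abundance(state.array)))


def _as_array(state, rep: str) -> np.ndarray:
    if isinstance(state, SystemState):
        if state.rep != rep:
            raise DomainError(f"state is in {state.rep} form, expected {rep}")
        return state.array
    return np.asarray(state, dtype=float)


def vector_field_abundance(sys: TwoPatchSystem, state) -> np.ndarray:
    """Time derivative of (x1, x2, y1, y2).

    dx_i/dt = (f_i + alpha1 - beta1*n1) x_i - c1 x_i + c2 y_i and the mirror
    expression in patch 2. Payoff terms for an empty patch are zero (each is
    multiplied by a zero abundance), so the field extends smoothly to the
    boundary of the orthant.
    """
    u = _as_array(state, ABUNDANCE)
    if np.any(u < 0):
        raise DomainError("abundances must be non-negative")
    x1, x2, y1, y2 = u
    n1 = x1 + x2
    n2 = y1 + y2
    p = x1 / n1 if n1 > 0 else 0.0
    q = y1 / n2 if n2 > 0 else 0.0
    f1, f2, _ = sys.gameA.payoffs(p)
    g1, g2, _ = sys.gameB.payoffs(q)
    a1 = sys.alpha1 - sys.beta1 * n1
    a2 = sys.alpha2 - sys.beta2 * n2
    c1, c2 = sys.c1, sys.c2
    return np.array(
        [
            (f1 + a1) * x1 - c1 * x1 + c2 * y1,
            (f2 + a1) * x2 - c1 * x2 + c2 * y2,
            (g1 + a2) * y1 - c2 * y1 + c1 * x1,
            (g2 + a2) * y2 - c2 * y2 + c1 * x2,
        ]
    )


def vector_field_frequency(sys: TwoPatchSystem, state) -> np.ndarray:
    """Time derivative of (p, q, n1, n2).

    dp/dt = p(1-p)(f1-f2) + c2 (q-p) n2/n1
    dq/dt = q(1-q)(g1-g2) + c1 (p-q) n1/n2
    dn1/dt = (fbar + alpha1 - beta1 n1) n1 - c1 n1 + c2 n2
    dn2/dt = (gbar + alpha2 - beta2 n2) n2 - c2 n2 + c1 n1

    Undefined where a patch is empty (the frequency there is meaningless);
    use the abundance form near extinction.
    """
    u = _as_array(state, FREQUENCY)
    p, q, n1, n2 = u
    if n1 <= 0 or n2 <= 0:
        raise DomainError("frequency form requires n1 > 0 and n2 > 0")
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise DomainError("frequencies must lie in [0, 1]")
    f1, f2, fbar = sys.gameA.payoffs(p)
    g1, g2, gbar = sys.gameB.payoffs(q)
    c1, c2 = sys.c1, sys.c2
    return np.array(
        [
            p * (1.0 - p) * (f1 - f2) + c2 * (q - p) * n2 / n1,
            q * (1.0 - q) * (g1 - g2) + c1 * (p - q) * n1 / n2,
            (fbar + sys.alpha1 - sys.beta1 * n1) * n1 - c1 * n1 + c2 * n2,
            (gbar + sys.alpha2 - sys.beta2 * n2) * n2 - c2 * n2 + c1 * n1,
        ]
    )


def frequency_jacobian(sys: TwoPatchSystem, u) -> np.ndarray:
    """Closed-form Jacobian of :func:`vector_field_frequency` at (p, q, n1, n2).

    Valid anywhere both densities are positive, including boundary
    frequencies p, q in {0, 1}. At an equilibrium of the density equations
    the diagonal density entries reduce to the classical
    ``-beta_i n_i - c_j n_j / n_i`` form.
    """
    p, q, n1, n2 = _as_array(u, FREQUENCY)
    if n1 <= 0 or n2 <= 0:
        raise DomainError("frequency-form Jacobian requires n1 > 0 and n2 > 0")
    A, B = sys.gameA, sys.gameB
    c1, c2 = sys.c1, sys.c2
    f1, f2, fbar = A.payoffs(p)
    g1, g2, gbar = B.payoffs(q)
    s = f1 - f2
    t = g1 - g2
    dfbar = s + p * (A.a11 - A.a12) + (1.0 - p) * (A.a21 - A.a22)
    dgbar = t + q * (B.a11 - B.a12) + (1.0 - q) * (B.a21 - B.a22)
    return np.array(
        [
            [
                (1.0 - 2.0 * p) * s + p * (1.0 - p) * A.delta - c2 * n2 / n1,
                c2 * n2 / n1,
                -c2 * (q - p) * n2 / n1**2,
                c2 * (q - p) / n1,
            ],
            [
                c1 * n1 / n2,
                (1.0 - 2.0 * q) * t + q * (1.0 - q) * B.delta - c1 * n1 / n2,
                c1 * (p - q) / n2,
                -c1 * (p - q) * n1 / n2**2,
            ],
            [
                dfbar * n1,
                0.0,
                fbar + sys.alpha1 - 2.0 * sys.beta1 * n1 - c1,
                c2,
            ],
            [
                0.0,
                dgbar * n2,
                c1,
                gbar + sys.alpha2 - 2.0 * sys.beta2 * n2 - c2,
            ],
        ]
    )


def coordinate_map_jacobian(u_abund: np.ndarray) -> np.ndarray:
    """Jacobian of the map (x1,x2,y1,y2) -> (p,q,n1,n2), used to push the
    abundance vector field forward onto frequency coordinates."""
    x1, x2, y1, y2 = u_abund
    n1 = x1 + x2
    n2 = y1 + y2
    if n1 <= 0 or n2 <= 0:
        raise DomainError("coordinate map is singular where a patch is empty")
    return np.array(
        [
            [x2 / n1**2, -x1 / n1**2, 0.0, 0.0],
            [0.0, 0.0, y2 / n2**2, -y1 / n2**2],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
    )
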