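"""ESS classification of 2x2 games and regime labels for game pairs.

For a 2x2 game with payoff matrix ``[[a11, a12], [a21, a22]]``:

* the pure strategy R1 is an ESS iff ``a11 > a21`` (strict);
* the pure strategy R2 is an ESS iff ``a22 > a12`` (strict);
* an interior rest point ``p* = (a12 - a22) / ((a12 - a22) + (a21 - a11))``
  exists whenever the two gaps are nonzero with the same sign, and it is an
  ESS iff both off-diagonal entries dominate (``a12 > a22`` and
  ``a21 > a11``, i.e. a hawk-dove game).

A pair of generic games then falls into one of four kinds per game
(R1-only, R2-only, bistable, hawk-dove), giving 16 regimes for the coupled
two-patch system. Regimes are labelled 1-10 with mirror sub-labels a/b so
every combination has a unique code.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .model import Game2x2, TwoPatchSystem

__all__ = [
    "GameKind",
    "ESSReport",
    "RegimePair",
    "DegenerateGameError",
    "classify_game",
    "classify_pair",
    "REGIME_TABLE",
]


class DegenerateGameError(ValueError):
    """A payoff tie makes the ESS classification ambiguous."""

    def __init__(self, report: "ESSReport"):
        self.report = report
        super().__init__(
            "degenerate game: a payoff tie (a11 == a21 or a22 == a12) "
            "prevents a generic ESS classification"
        )


class GameKind(str, Enum):
    R1_ONLY = "R1-only"        # R1 is the unique ESS
    R2_ONLY = "R2-only"        # R2 is the unique ESS
    BISTABLE = "bistable"      # both pure strategies are ESSs
    HAWK_DOVE = "hawk-dove"    # unique interior ESS
    DEGENERATE = "degenerate"  # payoff tie


@dataclass(frozen=True)
class ESSReport:
    """ESS structure of one 2x2 game."""

    r1_pure_ess: bool
    r2_pure_ess: bool
    interior_candidate: float | None
    interior_is_ess: bool
    delta: float
    degenerate: bool = False

    @property
    def kind(self) -> GameKind:
        if self.degenerate:
            return GameKind.DEGENERATE
        if self.interior_is_ess:
            return GameKind.HAWK_DOVE
        if self.r1_pure_ess and self.r2_pure_ess:
            return GameKind.BISTABLE
        if self.r1_pure_ess:
            return GameKind.R1_ONLY
        return GameKind.R2_ONLY

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "r1_pure_ess": self.r1_pure_ess,
            "r2_pure_ess": self.r2_pure_ess,
            "interior_candidate": self.interior_candidate,
            "interior_is_ess": self.interior_is_ess,
            "delta": self.delta,
            "degenerate": self.degenerate,
        }


def interior_rest_point(game: Game2x2) -> float | None:
    """The interior rest point of the single-patch replicator dynamics,
    ``p* = (a12 - a22) / ((a12 - a22) + (a21 - a11))``, or None when the two
    payoff gaps do not share a strict sign (no interior rest point)."""
    d1 = game.a12 - game.a22
    d2 = game.a21 - game.a11
    if d1 == 0.0 or d2 == 0.0 or (d1 > 0) != (d2 > 0):
        return None
    p = d1 / (d1 + d2)
    if not 0.0 < p < 1.0:
        return None
    return p


def classify_game(game: Game2x2) -> ESSReport:
    """ESS classification of one 2x2 game; ties are flagged degenerate
    rather than resolved."""
    degenerate = game.a11 == game.a21 or game.a22 == game.a12
    r1 = game.a11 > game.a21
    r2 = game.a22 > game.a12
    cand = interior_rest_point(game)
    interior_ess = cand is not None and game.a12 > game.a22 and game.a21 > game.a11
    return ESSReport(
        r1_pure_ess=r1,
        r2_pure_ess=r2,
        interior_candidate=cand,
        interior_is_ess=interior_ess,
        delta=game.delta,
        degenerate=degenerate,
    )


# (kind of game A, kind of game B) -> regime label. Labels follow the
# case-1 enumeration of equilibrium situations; mirror cases ("R1 or R2")
# carry a/b sub-labels so all 16 combinations are distinct.
REGIME_TABLE: dict[tuple[GameKind, GameKind], str] = {
    (GameKind.R1_ONLY, GameKind.R1_ONLY): "1a",
    (GameKind.R2_ONLY, GameKind.R2_ONLY): "1b",
    (GameKind.BISTABLE, GameKind.R1_ONLY): "2a",
    (GameKind.BISTABLE, GameKind.R2_ONLY): "2b",
    (GameKind.HAWK_DOVE, GameKind.R1_ONLY): "3a",
    (GameKind.HAWK_DOVE, GameKind.R2_ONLY): "3b",
    (GameKind.R2_ONLY, GameKind.R1_ONLY): "4a",
    (GameKind.R1_ONLY, GameKind.R2_ONLY): "4b",
    (GameKind.BISTABLE, GameKind.BISTABLE): "5",
    (GameKind.BISTABLE, GameKind.HAWK_DOVE): "6",
    (GameKind.HAWK_DOVE, GameKind.HAWK_DOVE): "7",
    (GameKind.HAWK_DOVE, GameKind.BISTABLE): "8",
    (GameKind.R2_ONLY, GameKind.HAWK_DOVE): "9a",
    (GameKind.R1_ONLY, GameKind.HAWK_DOVE): "9b",
    (GameKind.R2_ONLY, GameKind.BISTABLE): "10a",
    (GameKind.R1_ONLY, GameKind.BISTABLE): "10b",
}

ALL_REGIME_LABELS: tuple[str, ...] = tuple(REGIME_TABLE.values())


@dataclass(frozen=True)
class RegimePair:
    """Regime assignment of a (game A, game B) pair."""

    label: str
    essA: ESSReport
    essB: ESSReport

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "gameA": self.essA.to_dict(),
            "gameB": self.essB.to_dict(),
        }


def classify_pair(sys: TwoPatchSystem) -> RegimePair:
    """Assign the system's game pair to one of the 16 generic regimes.

    Raises :class:`DegenerateGameError` (carrying the offending report) when
    either game has a payoff tie.
    """
    essA = classify_game(sys.gameA)
    essB = classify_game(sys.gameB)
    for rep in (essA, essB):
        if rep.degenerate:
            raise DegenerateGameError(rep)
    return RegimePair(REGIME_TABLE[(essA.kind, essB.kind)], essA, essB)
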