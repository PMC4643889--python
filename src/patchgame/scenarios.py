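"""Built-in scenario registry and a regime-covering random generator.

The registry holds the parameter sets used throughout the analysis:
one-way-migration examples for all sixteen generic game-pair regimes
(fig2a..fig2p), two-way-migration examples (fig3a..fig3h), the bifurcation
template (fig4), and two density-subsystem illustrations with constant
payoffs (fig1a, fig1b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .games import ALL_REGIME_LABELS, REGIME_TABLE, GameKind, classify_game, classify_pair
from .model import Game2x2, PatchEnv, TwoPatchSystem

__all__ = ["Scenario", "SCENARIO_TABLE", "list_scenarios", "get_scenario",
           "build_system", "generate_regime_scenarios"]


@dataclass(frozen=True)
class Scenario:
    id: str
    sys: TwoPatchSystem
    provenance: str


def build_system(A, B, alpha, beta, c) -> TwoPatchSystem:
    """Assemble a validated system from row-major payoff matrices
    ``[[a11, a12], [a21, a22]]`` and per-patch parameter pairs."""
    (a11, a12), (a21, a22) = A
    (b11, b12), (b21, b22) = B
    return TwoPatchSystem(
        Game2x2(a11, a12, a21, a22),
        Game2x2(b11, b12, b21, b22),
        PatchEnv(alpha[0], beta[0], c[0]),
        PatchEnv(alpha[1], beta[1], c[1]),
    )


# One-way migration examples share beta1 = beta2 = 0.01, alpha1 = 1,
# alpha2 = 2, c1 = 0.5, c2 = 0; only the games differ.
_ONEWAY = {"alpha": (1.0, 2.0), "beta": (0.01, 0.01), "c": (0.5, 0.0)}

SCENARIO_TABLE: dict[str, dict] = {
    # density subsystem illustrations: constant payoffs so the mean payoff
    # is frequency-independent (0.25 in patch 1; 0.2 resp. 0.5 in patch 2)
    "fig1a": {
        "A": [[0.25, 0.25], [0.25, 0.25]], "B": [[0.2, 0.2], [0.2, 0.2]],
        "alpha": (0.75, 0.55), "beta": (0.01, 0.01), "c": (0.5, 0.5),
    },
    "fig1b": {
        "A": [[0.25, 0.25], [0.25, 0.25]], "B": [[0.5, 0.5], [0.5, 0.5]],
        "alpha": (0.75, 1.0), "beta": (0.01, 0.01), "c": (0.5, 0.5),
    },
    # one-way migration, one example per regime
    "fig2a": {"A": [[1.5, 1.5], [0, 0]], "B": [[5, 1], [0, 0]], **_ONEWAY},
    "fig2b": {"A": [[0, 0], [1, 1]], "B": [[0, 0], [5, 1]], **_ONEWAY},
    "fig2c": {"A": [[1, 0], [0, 1]], "B": [[3, 1], [0, 0]], **_ONEWAY},
    "fig2d": {"A": [[1, 0], [0, 1]], "B": [[0, 0], [3, 1]], **_ONEWAY},
    "fig2e": {"A": [[0, 1.25], [5, 0]], "B": [[3, 1], [0, 0]], **_ONEWAY},
    "fig2f": {"A": [[0, 1.25], [5, 0]], "B": [[0, 0], [3, 1]], **_ONEWAY},
    "fig2g": {"A": [[0, 0], [1, 1]], "B": [[3, 1], [0, 0]], **_ONEWAY},
    "fig2h": {"A": [[1, 1], [0, 0]], "B": [[0, 0], [3, 1]], **_ONEWAY},
    "fig2i": {"A": [[1, 0], [0, 1]], "B": [[2, 0], [0, 1]], **_ONEWAY},
    "fig2j": {"A": [[1, 0], [0, 1]], "B": [[0, 1], [4, 0]], **_ONEWAY},
    "fig2k": {"A": [[0, 2], [2, 0]], "B": [[0, 1], [5, 0]], **_ONEWAY},
    "fig2l": {"A": [[0, 2], [2, 0]], "B": [[1, 0], [0, 1]], **_ONEWAY},
    "fig2m": {"A": [[0, 0], [1, 1]], "B": [[0, 1], [4, 0]], **_ONEWAY},
    "fig2n": {"A": [[1.5, 1.5], [0, 0]], "B": [[0, 1], [4, 0]], **_ONEWAY},
    "fig2o": {"A": [[0, 0], [1, 1]], "B": [[2, 0], [0, 1]], **_ONEWAY},
    "fig2p": {"A": [[1, 1], [0, 0]], "B": [[2, 0], [0, 1]], **_ONEWAY},
    # two-way migration examples
    "fig3a": {"A": [[0, 1], [1, 0]], "B": [[0, 5], [5, 0]],
              "alpha": (1.25, 1.8), "beta": (0.01, 0.01), "c": (0.25, 0.8)},
    "fig3b": {"A": [[0, 1], [1, 0]], "B": [[0, 5], [5, 0]],
              "alpha": (1.125, 1.0), "beta": (0.01, 0.01), "c": (0.125, 0.8)},
    "fig3c": {"A": [[1, 0], [0, 1]], "B": [[5, 0], [0, 5]],
              "alpha": (1.4, 1.5), "beta": (0.001, 0.001), "c": (0.4, 0.5)},
    "fig3d": {"A": [[0, 1], [1, 0]], "B": [[5, 0], [0, 5]],
              "alpha": (1.5, 1.2), "beta": (0.001, 0.001), "c": (0.5, 0.2)},
    "fig3e": {"A": [[0, 5], [1, 0]], "B": [[1, 0], [0, 5]],
              "alpha": (1.5, 1.2), "beta": (0.001, 0.001), "c": (0.5, 0.2)},
    "fig3f": {"A": [[0, 5], [1, 0]], "B": [[0, 1], [5, 0]],
              "alpha": (1.5, 1.2), "beta": (0.001, 0.001), "c": (0.5, 0.2)},
    "fig3g": {"A": [[1, 0], [0, 5]], "B": [[5, 0], [0, 1]],
              "alpha": (1.4, 1.5), "beta": (0.001, 0.001), "c": (0.4, 0.5)},
    "fig3h": {"A": [[1, 0], [0, 1]], "B": [[2, 0], [0, 1]],
              "alpha": (1.75, 2.0), "beta": (0.05, 0.01), "c": (0.25, 0.01)},
    # the same bistable game pair as fig2i at a weaker one-way migration:
    # this is the parameter choice at which the one-way case attains its
    # maximal census of six equilibria with four stable
    "case1-sixeq": {"A": [[1, 0], [0, 1]], "B": [[2, 0], [0, 1]],
                    "alpha": (1.0, 2.0), "beta": (0.01, 0.01), "c": (0.1, 0.0)},
    # bifurcation template (registered at the equal migration rate 0.014;
    # the scan varies c1 = c2 = c over a grid)
    "fig4": {"A": [[1, 0], [0, 1]], "B": [[2, 0], [0, 1]],
             "alpha": (1.75, 2.0), "beta": (0.05, 0.01), "c": (0.014, 0.014)},
}

# Regimes of the sixteen one-way examples; used by the fixture audit.
FIG2_REGIMES: dict[str, str] = {
    "fig2a": "1a", "fig2b": "1b", "fig2c": "2a", "fig2d": "2b",
    "fig2e": "3a", "fig2f": "3b", "fig2g": "4a", "fig2h": "4b",
    "fig2i": "5", "fig2j": "6", "fig2k": "7", "fig2l": "8",
    "fig2m": "9a", "fig2n": "9b", "fig2o": "10a", "fig2p": "10b",
}


def list_scenarios() -> list[str]:
    return sorted(SCENARIO_TABLE)


def get_scenario(scenario_id: str) -> Scenario:
    try:
        spec = SCENARIO_TABLE[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; available: {', '.join(list_scenarios())}"
        ) from None
    sys = build_system(spec["A"], spec["B"], spec["alpha"], spec["beta"], spec["c"])
    return Scenario(scenario_id, sys, "built-in example")


_KIND_SAMPLERS_CAP = 10_000


def _sample_game_of_kind(rng: np.random.Generator, kind: GameKind) -> Game2x2:
    for _ in range(_KIND_SAMPLERS_CAP):
        a = rng.uniform(0.0, 5.0, size=4)
        game = Game2x2(*a)
        rep = classify_game(game)
        if rep.kind == kind:
            return game
    raise RuntimeError(f"failed to sample a game of kind {kind}")  # pragma: no cover


def generate_regime_scenarios(
    seed: int,
    alpha=(1.0, 2.0),
    beta=(0.01, 0.01),
    c=(0.5, 0.0),
) -> list[Scenario]:
    """One random scenario per generic regime (16 in total), deterministic
    under the seed. Payoff entries are drawn uniformly from [0, 5] and
    rejection-sampled until each game has the required ESS structure; the
    environment defaults to the one-way-migration setting of the built-in
    examples."""
    rng = np.random.default_rng(seed)
    out = []
    for (kindA, kindB), label in REGIME_TABLE.items():
        gameA = _sample_game_of_kind(rng, kindA)
        gameB = _sample_game_of_kind(rng, kindB)
        sys = TwoPatchSystem(
            gameA, gameB, PatchEnv(alpha[0], beta[0], c[0]), PatchEnv(alpha[1], beta[1], c[1])
        )
        assert classify_pair(sys).label == label
        out.append(Scenario(f"regime-{label}-seed{seed}", sys, "generated fixture"))
    assert {s.id.split("-")[1] for s in out} == set(ALL_REGIME_LABELS)
    return out
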