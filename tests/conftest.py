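import pytest

import patchgame as pg

# game-pair scenarios with non-degenerate classification (fig1a/b are
# constant-payoff density illustrations and excluded from regime suites)
FIG2_IDS = [f"fig2{c}" for c in "abcdefghijklmnop"]
FIG3_IDS = [f"fig3{c}" for c in "abcdefgh"]
GAME_SCENARIOS = FIG2_IDS + FIG3_IDS + ["fig4", "case1-sixeq"]
ALL_SCENARIOS = ["fig1a", "fig1b"] + GAME_SCENARIOS


@pytest.fixture(scope="session")
def scenario():
    """Accessor for built-in scenario systems (cached per session)."""
    cache = {}

    def get(sid: str) -> pg.TwoPatchSystem:
        if sid not in cache:
            cache[sid] = pg.get_scenario(sid).sys
        return cache[sid]

    return get


@pytest.fixture(scope="session")
def analyzed(scenario):
    """Accessor for classified equilibrium sets (cached per session).

    Enumeration + stability is deterministic, so sharing results across
    tests only saves time without coupling them.
    """
    cache = {}

    def get(sid: str) -> pg.EquilibriumSet:
        if sid not in cache:
            cache[sid] = pg.analyze(scenario(sid))
        return cache[sid]

    return get
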