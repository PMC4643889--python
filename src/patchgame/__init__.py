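"""patchgame: equilibria, stability and bifurcations of two-phenotype
evolutionary games on two patches coupled by phenotype-independent migration.
"""

from .bifurcation import BifurcationRow, default_c_grid, detect_thresholds, scan, with_migration
from .equilibria import (
    CurveIntersection,
    Equilibrium,
    EquilibriumSet,
    case1_equilibria,
    decoupled_equilibria,
    curve_intersections,
    enumerate_equilibria,
    general_equilibria,
    solve_density,
    symmetric_equilibria,
)
from .games import (
    DegenerateGameError,
    ESSReport,
    GameKind,
    RegimePair,
    classify_game,
    classify_pair,
)
from .io import load_config, load_scenario
from .model import (
    DomainError,
    Game2x2,
    PatchEnv,
    SystemState,
    TwoPatchSystem,
    convert_state,
    patch_payoffs,
    vector_field_abundance,
    vector_field_frequency,
)
from .scenarios import generate_regime_scenarios, get_scenario, list_scenarios
from .simulate import BasinCensus, Trajectory, basin_census, integrate
from .stability import classify_all, classify_stability

__version__ = "0.1.0"


def analyze(sys: TwoPatchSystem, grid: int = 201, case1_branches: str = "stable") -> EquilibriumSet:
    """Enumerate all positive equilibria and classify their stability."""
    return classify_all(sys, enumerate_equilibria(sys, grid=grid, case1_branches=case1_branches))


__all__ = [
    "analyze",
    "BifurcationRow", "default_c_grid", "detect_thresholds", "scan", "with_migration",
    "CurveIntersection", "curve_intersections",
    "Equilibrium", "EquilibriumSet", "case1_equilibria", "decoupled_equilibria",
    "enumerate_equilibria", "general_equilibria", "solve_density", "symmetric_equilibria",
    "DegenerateGameError", "ESSReport", "GameKind", "RegimePair", "classify_game", "classify_pair",
    "load_config", "load_scenario",
    "DomainError", "Game2x2", "PatchEnv", "SystemState", "TwoPatchSystem",
    "convert_state", "patch_payoffs", "vector_field_abundance", "vector_field_frequency",
    "generate_regime_scenarios", "get_scenario", "list_scenarios",
    "BasinCensus", "Trajectory", "basin_census", "integrate",
    "classify_all", "classify_stability",
]
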