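"""Config parsing and result writers.

Scenario configs are YAML or JSON mappings with exactly the keys ``A``,
``B`` (row-major 2x2 payoff matrices), ``alpha``, ``beta`` and ``c``
(two-element lists, patch 1 first). Results are written as RFC-4180 CSV
(UTF-8, '.' decimal separator, 12 significant digits) or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .bifurcation import BifurcationRow
from .equilibria import EquilibriumSet
from .model import TwoPatchSystem
from .scenarios import Scenario, build_system, get_scenario
from .simulate import BasinCensus

__all__ = [
    "load_config",
    "load_scenario",
    "equilibria_frame",
    "write_equilibria",
    "scan_frame",
    "write_scan",
    "write_census",
]

_CONFIG_KEYS = {"A", "B", "alpha", "beta", "c"}
_FLOAT_FMT = "%.12g"


def load_config(path: str | Path) -> TwoPatchSystem:
    """Parse and validate a scenario config file (YAML or JSON)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = _CONFIG_KEYS - set(data)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    return build_system(data["A"], data["B"], data["alpha"], data["beta"], data["c"])


def load_scenario(id_or_path: str) -> tuple[str, TwoPatchSystem]:
    """Resolve a built-in scenario id or a config file path."""
    try:
        sc: Scenario = get_scenario(id_or_path)
        return sc.id, sc.sys
    except KeyError:
        if Path(id_or_path).exists():
            return Path(id_or_path).stem, load_config(id_or_path)
        raise


def equilibria_frame(
    eqset: EquilibriumSet, scenario: str, sys: TwoPatchSystem
) -> pd.DataFrame:
    rows = [
        {"scenario": scenario, "c1": sys.c1, "c2": sys.c2, **eq.to_dict()}
        for eq in eqset
    ]
    cols = ["scenario", "c1", "c2", "p", "q", "n1", "n2",
            "kind", "residual", "max_re_eig", "stability"]
    return pd.DataFrame(rows, columns=cols)


def write_equilibria(
    eqset: EquilibriumSet, scenario: str, sys: TwoPatchSystem,
    path: str | Path, fmt: str = "csv",
) -> None:
    frame = equilibria_frame(eqset, scenario, sys)
    _write_frame(frame, path, fmt)


def scan_frame(rows: list[BifurcationRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def write_scan(rows: list[BifurcationRow], path: str | Path, fmt: str = "csv") -> None:
    _write_frame(scan_frame(rows), path, fmt)


def write_census(census: BasinCensus, path: str | Path) -> None:
    Path(path).write_text(json.dumps(census.to_dict(), indent=2) + "\n")


def _write_frame(frame: pd.DataFrame, path: str | Path, fmt: str) -> None:
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif fmt == "json":
        frame.to_json(path, orient="records", indent=2, double_precision=15)
    else:
        raise ValueError(f"unknown output format {fmt!r}")
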