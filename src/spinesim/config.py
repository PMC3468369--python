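"""Experiment configuration files (YAML or JSON).

A configuration describes one simulated experiment::

    population: synthetic-default   # or a morphometry CSV path
    n: 8
    m: 60
    variable: head_width
    change: {kind: linear_growth, variable: head_width, factor: 1.2}
    test: {name: t_test, alpha: 0.01}
    runs: 2000
    seed: 1

or, with a ``grid`` section, a whole sweep; grid lists are expanded into one
config per cell (cartesian product).  Validation errors name the offending
key path (e.g. ``test.alpha``).
"""
from __future__ import annotations

import json
from pathlib import Path

import yaml

from .change_models import ChangeModel
from .errors import ConfigurationError, SchemaError
from .population import VARIABLES
from .simulator import ExperimentConfig
from .stats_engines import ClassificationThresholds, TESTS, TestSpec

__all__ = ["parse_config", "config_to_dict"]

_TOP_KEYS = {
    "population", "population_size", "n_cells", "n", "m", "variable",
    "change", "test", "runs", "seed", "grid",
}
_GRID_KEYS = {"magnitudes", "alphas", "variables", "m_values"}
_TEST_KEYS = {"name", "alpha", "subclass", "thresholds"}


def _fail(path: str, msg: str):
    raise ConfigurationError(f"config key {path!r}: {msg}")


def _build_test(d: dict) -> TestSpec:
    if not isinstance(d, dict):
        _fail("test", f"expected a mapping, got {type(d).__name__}")
    unknown = set(d) - _TEST_KEYS
    if unknown:
        _fail("test", f"unknown key(s) {sorted(unknown)}")
    name = d.get("name", "t_test")
    if name not in TESTS:
        _fail("test.name", f"expected one of {TESTS}, got {name!r}")
    alpha = d.get("alpha", 0.01)
    if not isinstance(alpha, (int, float)) or not (0 < alpha < 1):
        _fail("test.alpha", f"must be a number in (0, 1), got {alpha!r}")
    kw = {"test": name, "alpha": float(alpha)}
    if "subclass" in d:
        kw["subclass"] = d["subclass"]
    if "thresholds" in d:
        try:
            kw["thresholds"] = ClassificationThresholds(**d["thresholds"])
        except (TypeError, ConfigurationError) as exc:
            _fail("test.thresholds", str(exc))
    try:
        return TestSpec(**kw)
    except ConfigurationError as exc:
        _fail("test", str(exc))


def _build_change(d: dict) -> ChangeModel:
    if not isinstance(d, dict):
        _fail("change", f"expected a mapping, got {type(d).__name__}")
    try:
        return ChangeModel.from_dict(d)
    except (TypeError, ConfigurationError) as exc:
        _fail("change", str(exc))


def _build_experiment(doc: dict) -> ExperimentConfig:
    kw = {}
    for key in ("population", "population_size", "n_cells", "n", "m", "seed", "runs"):
        if key in doc:
            kw[key] = doc[key]
    if "variable" in doc:
        if doc["variable"] not in VARIABLES:
            _fail("variable", f"expected one of {VARIABLES}, got {doc['variable']!r}")
        kw["variable"] = doc["variable"]
    if "change" in doc:
        kw["change"] = _build_change(doc["change"])
    if "test" in doc:
        kw["test"] = _build_test(doc["test"])
    try:
        return ExperimentConfig(**kw)
    except (TypeError, ConfigurationError) as exc:
        raise ConfigurationError(f"config: {exc}") from exc


def parse_config(path):
    """Parse a config file into an :class:`ExperimentConfig` (or list of them).

    Without a ``grid`` section the result is a single validated config with
    defaults filled in (runs default to 2000 for false-negative and 10000 for
    false-positive estimation, chosen by the consumer).  With a ``grid``
    section the cartesian product of the grid lists is expanded into one
    config per cell, each inheriting the non-grid keys.
    """
    path = Path(path)
    text = path.read_text()
    try:
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise SchemaError(f"{path}: not parseable as {'JSON' if path.suffix == '.json' else 'YAML'}: {exc}")
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        _fail(sorted(unknown)[0], "unknown top-level key")

    if "grid" not in doc:
        return _build_experiment(doc)

    grid = doc["grid"]
    if not isinstance(grid, dict):
        _fail("grid", f"expected a mapping, got {type(grid).__name__}")
    unknown = set(grid) - _GRID_KEYS
    if unknown:
        _fail(f"grid.{sorted(unknown)[0]}", "unknown grid key")
    magnitudes = grid.get("magnitudes", [None])
    alphas = grid.get("alphas", [None])
    variables = grid.get("variables", [doc.get("variable", "head_width")])
    m_values = grid.get("m_values", [doc.get("m", 60)])

    base = dict(doc)
    base.pop("grid")
    cells = []
    for mag in magnitudes:
        for alpha in alphas:
            for variable in variables:
                for m in m_values:
                    cell = dict(base)
                    cell["variable"] = variable
                    cell["m"] = m
                    if mag is not None:
                        cell["change"] = {
                            "kind": "linear_growth",
                            "variable": variable,
                            "factor": 1.0 + float(mag),
                        }
                    if alpha is not None:
                        test = dict(cell.get("test", {}))
                        test["alpha"] = alpha
                        cell["test"] = test
                    cells.append(_build_experiment(cell))
    return cells


def config_to_dict(config: ExperimentConfig) -> dict:
    """Serialisable echo of a config (population objects become a tag)."""
    pop = config.population
    return {
        "population": pop if isinstance(pop, str) else "<in-memory source>",
        "population_size": config.population_size,
        "n_cells": config.n_cells,
        "n": config.n,
        "m": config.m,
        "variable": config.variable,
        "change": config.change.to_dict(),
        "test": config.test.to_dict(),
        "runs": config.runs,
        "seed": config.seed,
    }
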