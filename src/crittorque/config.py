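"""Configuration and result I/O: YAML scheme/parameter files, CSV/JSON
results, with schema validation that names the offending key."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import SCENARIO_NAMES, LoadingScheme, ModelParameters, MuscleState, Stage

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_scheme",
    "write_scheme",
    "load_params",
    "write_params",
    "external_params_loader",
    "load_config",
    "write_config",
    "write_results",
]


class ConfigError(ValueError):
    """A configuration file violated the expected schema."""


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return mapping[key]


# ---------------------------------------------------------------------------
# loading schemes


def scheme_to_dict(scheme: LoadingScheme) -> dict:
    return {
        "name": scheme.name,
        "x0": [scheme.x0.x_slow, scheme.x0.x_fast],
        "stages": [
            {"duration_s": s.duration, "mode": s.mode, "level": s.level}
            for s in scheme.stages
        ],
    }


def scheme_from_dict(data: dict, context: str = "scheme") -> LoadingScheme:
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    stages_raw = _require(data, "stages", context)
    if not isinstance(stages_raw, list) or not stages_raw:
        raise ConfigError(f"{context}: 'stages' must be a nonempty list")
    stages = []
    for i, raw in enumerate(stages_raw):
        ctx = f"{context}.stages[{i}]"
        try:
            stages.append(
                Stage(
                    duration=float(_require(raw, "duration_s", ctx)),
                    mode=str(raw.get("mode", "relative")),
                    level=float(_require(raw, "level", ctx)),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc
    x0_raw = data.get("x0", [1.0, 1.0])
    if len(x0_raw) != 2:
        raise ConfigError(f"{context}: 'x0' must have two components")
    try:
        x0 = MuscleState(float(x0_raw[0]), float(x0_raw[1]))
    except ValueError as exc:
        raise ConfigError(f"{context}.x0: {exc}") from exc
    return LoadingScheme(stages=tuple(stages), x0=x0, name=data.get("name"))


def load_scheme(path) -> LoadingScheme:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return scheme_from_dict(data, context=str(path))


def write_scheme(scheme: LoadingScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme_to_dict(scheme), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# parameters


def load_params(path) -> ModelParameters:
    """Read a parameter file: either a plain 5-list or a mapping with key
    ``p`` (and optional ``name``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = _require(data, "p", str(path))
    values = np.asarray(data, dtype=float).ravel()
    if values.size != 5:
        raise ConfigError(
            f"{path}: expected 5 parameter values, got {values.size}"
        )
    if np.any(values < 0):
        bad = int(np.flatnonzero(values < 0)[0])
        raise ConfigError(
            f"{path}: parameter p{bad + 1} is negative ({values[bad]})"
        )
    return ModelParameters.from_array(values)


#: alias emphasising the intended use: ingesting an externally supplied
#: (e.g. subject-specific published) parameter vector
external_params_loader = load_params


def write_params(params: ModelParameters, path, name: str | None = None) -> None:
    data: dict = {"p": [float(v) for v in params.as_array()]}
    if name:
        data["name"] = name
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """A reproducible run: scenario + parameter source + numerics."""

    scenario: str | None = None
    scheme_file: str | None = None
    params_file: str | None = None
    fixture: str | None = None
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10
    horizon_s: float = 3600.0
    out: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "scenario": self.scenario,
            "scheme_file": self.scheme_file,
            "params_file": self.params_file,
            "fixture": self.fixture,
            "seed": self.seed,
            "rtol": self.rtol,
            "atol": self.atol,
            "horizon_s": self.horizon_s,
            "out": self.out,
        }
        out.update(self.extra)
        return out


_RUN_KEYS = {"scenario", "scheme_file", "params_file", "fixture", "seed",
             "rtol", "atol", "horizon_s", "out"}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    scenario = data.get("scenario")
    if scenario is not None and scenario.upper() not in SCENARIO_NAMES:
        raise ConfigError(
            f"{path}: unknown scenario {scenario!r}; known scenarios: "
            f"{', '.join(SCENARIO_NAMES)}"
        )
    known = {k: v for k, v in data.items() if k in _RUN_KEYS}
    extra = {k: v for k, v in data.items() if k not in _RUN_KEYS}
    cfg = RunConfig(**known, extra=extra)
    for key in ("scheme_file", "params_file"):
        value = getattr(cfg, key)
        if value is not None and not Path(value).exists():
            raise ConfigError(f"{path}: {key} points to a missing file: {value}")
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def write_results(result, path) -> None:
    """Serialize a result object to JSON (dataclasses expose ``to_dict``)."""
    if hasattr(result, "to_dict"):
        payload = result.to_dict()
    elif isinstance(result, dict):
        payload = result
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj).__name__}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
        fh.write("\n")
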