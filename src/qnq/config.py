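"""Configuration loading and validation.

Model parameters, scenario sets and noise models are plain flat YAML
mappings; packaged defaults under ``qnq/data/`` reproduce the study
conditions.  :func:`validate_config` performs a dry check of a run
configuration and returns a list of issues instead of raising, so a CLI
can report all problems at once.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .model import ModelParams
from .scenarios import Scenario
from .synthetic import NoiseModel

__all__ = [
    "RunConfig",
    "Issue",
    "load_params",
    "load_scenarios",
    "load_noise",
    "load_run_config",
    "validate_config",
]

_DATA = resources.files("qnq") / "data"


def _load_yaml(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return loaded


def _from_mapping(cls, mapping: dict, where: str):
    types = {f.name: f.type for f in fields(cls)}
    unknown = sorted(set(mapping) - set(types))
    if unknown:
        raise ValueError(f"{where}: unknown key(s) {unknown}")
    coerced = {}
    for key, value in mapping.items():
        # YAML 1.1 floats like "3.2e6" (no sign after "e") load as strings;
        # coerce scalars to the dataclass field's declared numeric type
        declared = str(types[key])
        try:
            if "float" in declared and value is not None:
                value = float(value)
            elif "int" in declared and "str" not in declared and value is not None:
                value = int(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{where}: bad value for {key!r}: {exc}") from exc
        coerced[key] = value
    return cls(**coerced)


def load_params(path=None) -> ModelParams:
    """Load model parameters from YAML (packaged defaults when ``path`` is None)."""
    source = path if path is not None else _DATA / "default_params.yaml"
    params = _from_mapping(ModelParams, _load_yaml(source), str(source))
    params.validate()
    return params


def load_scenarios(path=None) -> list[Scenario]:
    """Load a scenario list from YAML (packaged plate layout by default)."""
    source = path if path is not None else _DATA / "default_scenarios.yaml"
    raw = _load_yaml(source)
    entries = raw.get("scenarios")
    if not entries:
        raise ValueError(f"{source}: expected a non-empty 'scenarios' list")
    return [_from_mapping(Scenario, e, f"{source} scenario #{i}")
            for i, e in enumerate(entries)]


def load_noise(path=None, seed: Optional[int] = None) -> NoiseModel:
    """Load a noise model from YAML; ``seed`` overrides the file's seed."""
    source = path if path is not None else _DATA / "default_noise.yaml"
    mapping = _load_yaml(source)
    if seed is not None:
        mapping["seed"] = int(seed)
    return _from_mapping(NoiseModel, mapping, str(source))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str = "qnq_out"
    seed: int = 0
    params_path: Optional[str] = None
    scenarios_path: Optional[str] = None
    noise_path: Optional[str] = None
    data_path: Optional[str] = None       # read this CSV instead of generating
    time_points: list = field(default_factory=lambda: [2.0, 10.0, 24.0])
    lag_method: str = "threshold"         # or "max_growth"
    fit_free: dict = field(default_factory=dict)  # name -> [low, high]
    fit_generations: int = 60

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    field: str
    message: str


def validate_config(config: RunConfig) -> list[Issue]:
    """Check a run configuration without executing it.

    The configuration is executable iff no error-severity issue is
    returned.  Warnings flag legal-but-notable settings (for example a
    negative lag slope, which is allowed but clamped so lags never drop
    below zero).
    """
    issues: list[Issue] = []

    def error(field_name, message):
        issues.append(Issue("error", field_name, message))

    def warning(field_name, message):
        issues.append(Issue("warning", field_name, message))

    try:
        params = load_params(config.params_path)
        if params.lag_q_slope < 0 or params.lag_nq_slope < 0:
            warning("lag_slope", "negative lag slope: lags are clamped at 0 h")
    except (OSError, ValueError, TypeError) as exc:
        error("params_path", str(exc))
        params = None
    if config.data_path is None:
        try:
            load_scenarios(config.scenarios_path)
        except (OSError, ValueError, TypeError) as exc:
            error("scenarios_path", str(exc))
        try:
            load_noise(config.noise_path, seed=config.seed)
        except (OSError, ValueError, TypeError) as exc:
            error("noise_path", str(exc))
    elif not Path(config.data_path).exists():
        error("data_path", f"data file not found: {config.data_path}")
    if config.lag_method not in ("threshold", "max_growth"):
        error("lag_method", f"unknown lag method {config.lag_method!r}")
    if not config.time_points:
        error("time_points", "at least one analysis time point is required")
    if params is not None and config.fit_free:
        for name, bound in config.fit_free.items():
            if not hasattr(params, name):
                error("fit_free", f"unknown model parameter {name!r}")
            elif len(bound) != 2 or not bound[0] < bound[1]:
                error("fit_free", f"bounds for {name!r} must be [low, high]")
    out_parent = Path(config.out_dir).resolve().parent
    if not out_parent.exists():
        error("out_dir", f"parent directory does not exist: {out_parent}")
    return issues


def load_run_config(path) -> RunConfig:
    return _from_mapping(RunConfig, _load_yaml(path), str(path))
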