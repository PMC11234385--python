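"""Run configuration, CSV/JSON readers and writers, and metadata sidecars.

CSV is the interchange format for trajectories and orbits (columns: time or
arclength, then species); parameters and configuration are JSON/YAML;
every records file gets a JSON sidecar carrying the schema version,
parameter hash, seed and solver settings so a run can be reconstructed
from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .dynamics import Orbit, Trajectory, orbit_from_points
from .errors import ConfigError
from .models import MODEL_BUILDERS
from .parameters import ParameterSet

RECORDS_SCHEMA = "orbitempo/records/v1"
CONFIG_SCHEMA = "orbitempo/config/v1"


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"


@dataclass(frozen=True)
class MetricSettings:
    normalize: str = "own"        # own | reference | none
    closed: bool = False
    n_points: int = 500


@dataclass(frozen=True)
class ExperimentSettings:
    n_systems: int = 200
    seed: int = 0
    fold_min: float = 0.2
    fold_max: float = 5.0
    distribution: str = "log-uniform"
    orbit_preservation_threshold: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a CLI run."""

    model: str = "repressilator_reduced"
    params_path: Optional[str] = None
    solver: SolverSettings = field(default_factory=SolverSettings)
    metric: MetricSettings = field(default_factory=MetricSettings)
    experiment: ExperimentSettings = field(default_factory=ExperimentSettings)
    out_dir: str = "."

    def load_params(self) -> Optional[ParameterSet]:
        if self.params_path is None:
            return None
        return ParameterSet.load(self.params_path)


def _build_section(cls, payload, name):
    if not isinstance(payload, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    fields = cls.__dataclass_fields__
    unknown = set(payload) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in config section {name!r}: {sorted(unknown)}"
        )
    coerced = {}
    for key, value in payload.items():
        target = fields[key].type
        # YAML parses "1e-8" (no decimal point) as a string; coerce floats,
        # but never silently round a float into an int field
        if target == "float":
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ConfigError(f"config key {name}.{key} must be a number")
        elif target == "int" and isinstance(value, str):
            try:
                value = int(value)
            except ValueError:
                raise ConfigError(f"config key {name}.{key} must be an integer")
        coerced[key] = value
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected (naming the offending key); missing keys take
    documented defaults; numeric sanity (positive tolerances, integer seed)
    is enforced.
    """
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigError("config file must contain a mapping")
    payload = dict(payload)
    schema = payload.pop("schema", CONFIG_SCHEMA)
    if schema != CONFIG_SCHEMA:
        raise ConfigError(f"unsupported config schema {schema!r}")
    sections = {"solver": SolverSettings, "metric": MetricSettings,
                "experiment": ExperimentSettings}
    kwargs = {}
    for key, value in payload.items():
        if key in sections:
            kwargs[key] = _build_section(sections[key], value, key)
        elif key in ("model", "params_path", "out_dir"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")
    config = RunConfig(**kwargs)
    _validate_config(config)
    return config


def _validate_config(config: RunConfig) -> None:
    if config.model not in MODEL_BUILDERS:
        raise ConfigError(f"unknown model {config.model!r}")
    if config.solver.rtol <= 0 or config.solver.atol <= 0:
        raise ConfigError("solver tolerances must be positive")
    if not isinstance(config.experiment.seed, int):
        raise ConfigError("experiment.seed must be an integer")
    if config.experiment.fold_min <= 0 or config.experiment.fold_max < config.experiment.fold_min:
        raise ConfigError("experiment fold range must be positive and ordered")
    if config.experiment.orbit_preservation_threshold <= 0:
        raise ConfigError("orbit preservation threshold must be positive")
    if config.metric.n_points < 8:
        raise ConfigError("metric.n_points must be >= 8")
    if config.metric.normalize not in ("own", "reference", "none"):
        raise ConfigError(f"unknown normalization {config.metric.normalize!r}")
    if config.params_path is not None and not Path(config.params_path).exists():
        raise ConfigError(f"params file not found: {config.params_path}")


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    payload = {"schema": CONFIG_SCHEMA, **asdict(config)}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# records and sidecars
# ---------------------------------------------------------------------------

def params_hash(params: Optional[ParameterSet]) -> str:
    payload = params.to_dict() if params is not None else None
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_records(table: pd.DataFrame, path, params: Optional[ParameterSet] = None,
                  seed: Optional[int] = None, extra_metadata: Optional[dict] = None) -> Path:
    """Write a records table as CSV plus a JSON metadata sidecar.

    Columns keep their declared order; floats are written at full
    round-trip precision.  The sidecar (``<name>.meta.json``) carries the
    schema version, parameter hash, seed and tool version.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    meta = {
        "schema": RECORDS_SCHEMA,
        "tool_version": __version__,
        "columns": list(table.columns),
        "n_records": int(len(table)),
        "params_hash": params_hash(params),
        "seed": seed,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def _write_sidecar(path: Path, kind: str, metadata: Optional[dict]) -> None:
    if metadata is None:
        return
    payload = {"schema": RECORDS_SCHEMA, "kind": kind,
               "tool_version": __version__, **metadata}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def write_trajectory_csv(traj: Trajectory, path, species=None,
                         metadata: Optional[dict] = None) -> Path:
    path = Path(path)
    species = list(species) if species is not None else [
        f"x{j}" for j in range(traj.n_species)]
    df = pd.DataFrame(traj.states, columns=species)
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)
    _write_sidecar(path, "trajectory", metadata)
    return path


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise ConfigError(f"{path}: trajectory CSV needs a 'time' column")
    return Trajectory(df["time"].to_numpy(),
                      df.drop(columns="time").to_numpy(dtype=float))


def write_orbit_csv(orbit: Orbit, path, species=None,
                    metadata: Optional[dict] = None) -> Path:
    path = Path(path)
    species = list(species) if species is not None else [
        f"x{j}" for j in range(orbit.dimension)]
    df = pd.DataFrame(orbit.points, columns=species)
    df.insert(0, "arclength", orbit.cumulative_arclength)
    df.to_csv(path, index=False)
    _write_sidecar(path, "orbit", metadata)
    return path


def read_orbit_csv(path, closed: bool = False) -> Orbit:
    df = pd.read_csv(path, float_precision="round_trip")
    if "arclength" in df.columns:
        df = df.drop(columns="arclength")
    if "time" in df.columns:  # tolerate trajectory files as raw curves
        df = df.drop(columns="time")
    return orbit_from_points(df.to_numpy(dtype=float), closed=closed)
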