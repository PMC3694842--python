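"""Run configuration: validated, serializable, reproducible.

A run is fully determined by its configuration plus seeds. The schema has
one section per concern (model parameters, input signal, integrator,
scan grids, ensemble sizes, seeds); unknown keys are rejected so typos
fail loudly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .dde import IntegratorConfig, Trajectory
from .params import InputSignal, ModelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "write_results"]

_FLOAT_FMT = "%.12g"  # 12 significant digits for bit-stable text output


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


@dataclass
class RunConfig:
    params: ModelParams
    signal: InputSignal
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    t_end: float = 600.0
    tau2_grid: list[float] = field(default_factory=lambda: [7.5 * i for i in range(13)])
    eps_grid: list[float] = field(default_factory=lambda: [0.1 * i for i in range(11)])
    k_grid: list[float] = field(default_factory=lambda: [0.25, 0.5, 1.0, 2.0, 4.0])
    pulse_durations: list[float] = field(default_factory=lambda: [15.0, 30.0, 45.0, 60.0, 90.0, 120.0])
    threshold: float = 50.0
    n_nfkb_total: int = 1000
    n_runs: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "params": asdict(self.params),
            "signal": {
                "amplitude": self.signal.amplitude,
                "t_on": self.signal.t_on,
                "duration": self.signal.duration if math.isfinite(self.signal.duration) else "inf",
                "baseline": self.signal.baseline,
            },
            "integrator": asdict(self.integrator),
        }
        for f in fields(self):
            if f.name not in ("params", "signal", "integrator"):
                d[f.name] = getattr(self, f.name)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration (for run logging)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(section: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in section {section!r}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid section {section!r}: {e}") from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key {sorted(unknown)[0]!r}")
    if "params" not in data:
        raise ConfigError("missing required section 'params'")
    params = _build("params", ModelParams, data["params"])
    sig = dict(data.get("signal", {"amplitude": 1.0}))
    if sig.get("duration") in ("inf", ".inf", None):
        sig.pop("duration", None)
    signal = _build("signal", InputSignal, sig)
    integrator = _build("integrator", IntegratorConfig, data.get("integrator", {}))
    rest = {k: v for k, v in data.items() if k not in ("params", "signal", "integrator")}
    try:
        return RunConfig(params=params, signal=signal, integrator=integrator, **rest)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def _format_float(x) -> str:
    return _FLOAT_FMT % float(x)


def write_results(obj, path, fmt: str | None = None) -> None:
    """Serialize a result object with fixed float formatting.

    Trajectories and DataFrames go to CSV (columns
    ``time_min,y_alpha_nM,y_eps_nM,x_nM`` for trajectories); mappings,
    scan results and duration curves go to JSON. The output is bit-stable
    for identical inputs.
    """
    import pandas as pd

    from .pipelines import DurationCurve, ScanResult

    path = Path(path)
    fmt = fmt or ("csv" if path.suffix == ".csv" else "json")
    try:
        if isinstance(obj, Trajectory):
            obj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False, float_format=_FLOAT_FMT)
        elif isinstance(obj, ScanResult):
            payload = {
                "tau2_grid": [float(t) for t in obj.tau2_grid],
                "eps_grid": [float(e) for e in obj.eps_grid],
                "metric": [[None if np.isnan(v) else float(_format_float(v)) for v in row]
                           for row in obj.metric],
                "argmin": {"tau2": obj.argmin[0], "eps": obj.argmin[1]},
            }
            path.write_text(json.dumps(payload, indent=1) + "\n")
        elif isinstance(obj, DurationCurve):
            payload = {
                "input_durations_min": [float(v) for v in obj.input_durations],
                "response_durations_min": [float(_format_float(v)) for v in obj.response_durations],
                "threshold_nM": obj.threshold,
            }
            path.write_text(json.dumps(payload, indent=1) + "\n")
        elif isinstance(obj, dict):
            path.write_text(json.dumps(obj, indent=1, default=_format_float) + "\n")
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__}")
    except OSError as e:
        raise OSError(f"failed writing results to {path}: {e}") from e
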