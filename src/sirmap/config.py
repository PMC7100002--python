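"""Run configuration (YAML/JSON), validation and serialization helpers.

Configs are schema-validated before any computation runs; unknown keys are
rejected with a message naming the key.  Numeric output uses 17
significant digits so that deterministic runs replay bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .model import EpidemicState, ModelParameters, Trajectory

logger = logging.getLogger("sirmap")

#: float format giving an exact round-trip through text
FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class ParameterBlock(_Block):
    """The five per-step rates; ``lambda`` is accepted as the YAML key."""

    Lambda: float = Field(alias="lambda", ge=0)
    beta: float = Field(ge=0)
    mu: float = Field(ge=0)
    delta: float = Field(default=0.0, ge=0)
    gamma: float = Field(ge=0)

    def to_params(self) -> ModelParameters:
        return ModelParameters(self.Lambda, self.beta, self.mu, self.delta,
                               self.gamma)


class InitialBlock(_Block):
    S: float = Field(ge=0)
    I: float = Field(ge=0)
    R: float = Field(default=0.0, ge=0)

    def to_state(self) -> EpidemicState:
        return EpidemicState(self.S, self.I, self.R)


class RunBlock(_Block):
    horizon: int = Field(default=1000, ge=1)
    t0: int = 0
    clip: bool = True
    out: Optional[str] = None


class ScanBlock(_Block):
    r0_min: float = Field(gt=0)
    r0_max: float = Field(gt=0)
    points: int = Field(default=101, ge=1)
    transient: int = Field(default=50_000, ge=1)
    window: int = Field(default=512, ge=2)
    tol: float = Field(default=1e-6, gt=0)
    max_period: int = Field(default=64, ge=1)


class RunConfig(_Block):
    parameters: ParameterBlock
    initial: Optional[InitialBlock] = None
    run: RunBlock = Field(default_factory=RunBlock)
    scan: Optional[ScanBlock] = None
    scenario: Optional[Literal["mumps"]] = None


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("invalid config: " + "; ".join(lines)) from exc
    logger.info("loaded config %s: %s", path, dump_config(cfg))
    return cfg


def dump_config(cfg: RunConfig) -> dict:
    """Normalized plain-dict form (aliased keys, defaults filled)."""
    return cfg.model_dump(by_alias=True)


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def run_metadata(trajectory: Trajectory) -> dict:
    p = trajectory.params
    return {
        "parameters": {
            "lambda": p.Lambda, "beta": p.beta, "mu": p.mu,
            "delta": p.delta, "gamma": p.gamma,
        },
        "feasible": trajectory.feasible,
        "clip_events": trajectory.clip_events,
        "warnings": list(trajectory.warnings),
    }


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """CSV with header t,S,I,R,N,incidence (incidence empty on the last
    row: it is a per-step transfer, not a state)."""
    path = Path(path)
    N = trajectory.N
    with path.open("w") as fh:
        fh.write("t,S,I,R,N,incidence\n")
        for i, t in enumerate(trajectory.times):
            inc = (
                _fmt(trajectory.incidence[i])
                if i < len(trajectory.incidence)
                else ""
            )
            s, iv, r = trajectory.states[i]
            fh.write(
                f"{t},{_fmt(s)},{_fmt(iv)},{_fmt(r)},{_fmt(N[i])},{inc}\n"
            )


def write_trajectory_json(trajectory: Trajectory, path) -> None:
    payload = {
        "metadata": run_metadata(trajectory),
        "t": trajectory.times.tolist(),
        "S": trajectory.S.tolist(),
        "I": trajectory.I.tolist(),
        "R": trajectory.R.tolist(),
        "incidence": trajectory.incidence.tolist(),
    }
    write_json(payload, path)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, complex):
            return {"re": o.real, "im": o.imag}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.complexfloating):
            return {"re": float(o.real), "im": float(o.imag)}
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            d = {
                f.name: getattr(o, f.name)
                for f in dataclasses.fields(o)
            }
            d["_type"] = type(o).__name__
            return d
        return super().default(o)


def report_to_json_str(obj) -> str:
    """Serialize dataclass reports (stability, theorem, fit …) to JSON."""
    return json.dumps(obj, cls=_ReportEncoder, indent=2, sort_keys=True)


def write_json(obj, path) -> None:
    Path(path).write_text(report_to_json_str(obj) + "\n")


def write_scan_csv(scan, path) -> None:
    """Plot-ready bifurcation-diagram data: one row per (R0, I sample)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("beta,R0,period,transitional,I\n")
        for b, r0, s in zip(scan.beta_grid, scan.r0_grid, scan.summaries):
            if s is None:
                continue
            per = "" if s.period is None else s.period
            # distinct attractor values are enough for the diagram
            vals = s.samples[-min(len(s.samples), 128):]
            for v in np.unique(np.round(vals, 9)):
                fh.write(f"{_fmt(b)},{_fmt(r0)},{per},{int(s.transitional)},{_fmt(v)}\n")


def write_annual_csv(annual, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("year,cases\n")
        for y, c in zip(annual.years, annual.cases):
            fh.write(f"{y},{_fmt(c)}\n")
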