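"""Run configuration: a single human-readable key = value file with
nested sections, lossless round-trip, and validation against the model
invariants.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import configparser
import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

from .network import ModelParams
from .scenarios import Scenario, free, gradient, isometric, uniaxial

__all__ = ["RunConfig", "parse_config", "write_config"]

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(ModelParams)}
_SCENARIO_KEYS = {"kind", "stress", "phi_hi", "ramp_frac"}
_RUN_KEYS = {"t_end", "frame_dt", "outdir"}


@dataclass
class RunConfig:
    """Everything needed to reproduce one run: model parameters, scenario
    and schedule.  An empty config file yields the reference parameter set
    with a stress-free uniaxial scenario."""

    params: ModelParams = dataclasses.field(default_factory=ModelParams)
    kind: str = "uniaxial"
    stress: float = 0.0
    phi_hi: Optional[float] = None
    ramp_frac: float = 0.05
    t_end: float = 10.0
    frame_dt: Optional[float] = None
    outdir: str = "runs"

    def scenario(self) -> Scenario:
        if self.kind == "uniaxial":
            return uniaxial(self.stress)
        if self.kind == "free":
            return free()
        if self.kind == "isometric":
            return isometric(self.phi_hi)
        if self.kind == "gradient":
            return gradient(self.phi_hi if self.phi_hi is not None else 0.5,
                            self.ramp_frac)
        raise ValueError(f"unknown scenario kind: {self.kind!r}")


def _parse_value(raw: str, typ):
    raw = raw.strip()
    if raw.lower() in {"none", ""}:
        return None
    if raw.lower() in {"inf", "infinity"}:
        return math.inf
    if typ is int or typ == "int":
        return int(raw)
    if typ is bool:
        return raw.lower() in {"1", "true", "yes"}
    return float(raw)


def parse_config(path) -> RunConfig:
    """Read and validate a config file.

    Sections: ``[params]`` (any ModelParams field), ``[scenario]``
    (kind, stress, phi_hi, ramp_frac), ``[run]`` (t_end, frame_dt,
    outdir).  Missing entries fall back to the reference defaults;
    unknown sections or keys raise ValueError naming the offender.
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys are case-sensitive (L vs l_c, D_x ...)
    with open(path) as fh:
        cp.read_string("[__root__]\n" + fh.read())
    cfg = RunConfig()
    pkw = {}
    for section in cp.sections():
        if section == "__root__":
            if cp.items(section):
                raise ValueError("top-level keys not allowed; use sections "
                                 "[params], [scenario], [run]")
            continue
        if section == "params":
            for key, raw in cp.items(section):
                if key not in _PARAM_FIELDS:
                    raise ValueError(f"unknown parameter: {key}")
                typ = int if key == "seed" else float
                pkw[key] = _parse_value(raw, typ)
        elif section == "scenario":
            for key, raw in cp.items(section):
                if key not in _SCENARIO_KEYS:
                    raise ValueError(f"unknown scenario key: {key}")
                if key == "kind":
                    cfg.kind = raw.strip()
                else:
                    setattr(cfg, key, _parse_value(raw, float))
        elif section == "run":
            for key, raw in cp.items(section):
                if key not in _RUN_KEYS:
                    raise ValueError(f"unknown run key: {key}")
                if key == "outdir":
                    cfg.outdir = raw.strip()
                else:
                    setattr(cfg, key, _parse_value(raw, float))
        else:
            raise ValueError(f"unknown section: [{section}]")
    try:
        cfg.params = ModelParams(**pkw)
    except TypeError as exc:
        raise ValueError(str(exc)) from exc
    cfg.scenario()  # validates the kind
    return cfg


def _fmt(v) -> str:
    if v is None:
        return "none"
    if isinstance(v, float) and math.isinf(v):
        return "inf"
    return repr(v)


def write_config(cfg: RunConfig, path) -> None:
    """Serialize so that parse_config(write_config(c)) == c."""
    lines = ["[params]"]
    defaults = ModelParams()
    for name in _PARAM_FIELDS:
        lines.append(f"{name} = {_fmt(getattr(cfg.params, name))}")
    lines += ["", "[scenario]", f"kind = {cfg.kind}",
              f"stress = {_fmt(cfg.stress)}",
              f"phi_hi = {_fmt(cfg.phi_hi)}",
              f"ramp_frac = {_fmt(cfg.ramp_frac)}",
              "", "[run]", f"t_end = {_fmt(cfg.t_end)}",
              f"frame_dt = {_fmt(cfg.frame_dt)}",
              f"outdir = {cfg.outdir}", ""]
    del defaults
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
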