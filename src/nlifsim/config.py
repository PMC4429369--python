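"""Experiment configuration: schema, defaults and unit handling.

Configuration files are YAML (JSON is a subset) with four sections —
``circuit``, ``noise``, ``stimulus`` and ``run`` — all optional; an empty
file yields the reference parameter set used throughout (R2 = 100 kΩ,
R_L = 1 GΩ, C1 = 3 nF, C2 = 2 nF, V_d = 0.9 V, switch 50 kΩ / 1 MΩ /
1.0 V / 0.5 V, stimulus map 1 µA / 30°).

Values are SI internally.  Any numeric field may instead be given with an
explicit unit suffix on the key, e.g. ``dt_us: 0.5``, ``c1_nf: 3``,
``i_max_ua: 1`` — the loader converts and rejects unknown keys.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .coding import StimulusMap
from .noise import NoiseSpec
from .params import NeuronCircuitParams, ThresholdSwitchSpec

__all__ = ["ConfigError", "ExperimentConfig", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


# unit suffix -> (kind, factor to SI)
_SUFFIXES = {
    "s": ("time", 1.0), "ms": ("time", 1e-3), "us": ("time", 1e-6),
    "a": ("current", 1.0), "ma": ("current", 1e-3),
    "ua": ("current", 1e-6), "na": ("current", 1e-9),
    "f": ("capacitance", 1.0), "uf": ("capacitance", 1e-6),
    "nf": ("capacitance", 1e-9), "pf": ("capacitance", 1e-12),
    "ohm": ("resistance", 1.0), "kohm": ("resistance", 1e3),
    "mohm": ("resistance", 1e6), "gohm": ("resistance", 1e9),
    "v": ("voltage", 1.0), "mv": ("voltage", 1e-3),
}

# field name -> physical kind, per section
_FIELD_KINDS = {
    "circuit": {
        "r1": "resistance", "r2": "resistance", "r_load": "resistance",
        "c1": "capacitance", "c2": "capacitance",
        "v_d": "voltage", "r_on": "resistance", "r_off": "resistance",
        "v_on": "voltage", "v_off": "voltage",
    },
    "noise": {
        "r_on": "resistance", "r_off": "resistance",
        "v_on": "voltage", "v_off": "voltage",
    },
    "stimulus": {"i_max": "current"},
    "run": {"dt": "time", "duration": "time", "window": "time"},
}


def _normalize_units(section: str, data: dict) -> dict:
    kinds = _FIELD_KINDS.get(section, {})
    out = {}
    for key, value in data.items():
        if key in kinds or "_" not in key:
            out[key] = value
            continue
        base, _, suffix = key.rpartition("_")
        entry = _SUFFIXES.get(suffix)
        if base in kinds and entry is not None and entry[0] == kinds[base]:
            if base in out or key in out:
                raise ConfigError(f"{section}.{base} specified more than once")
            out[base] = float(value) * entry[1]
        else:
            out[key] = value  # let the schema report it
    return out


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CircuitConfig(_Section):
    r1: float = Field(100e3, gt=0)
    r2: float = Field(100e3, gt=0)
    r_load: float = Field(1e9, gt=0)
    c1: float = Field(3e-9, gt=0)
    c2: float = Field(2e-9, gt=0)
    v_d: float = Field(0.9, gt=0)
    r_on: float = Field(50e3, gt=0)
    r_off: float = Field(1e6, gt=0)
    v_on: float = Field(1.0, gt=0)
    v_off: float = Field(0.5, gt=0)


class NoiseConfig(_Section):
    r_on: float = Field(50e3, gt=0)
    r_off: float = Field(1e6, gt=0)
    v_on: float = Field(1.0, gt=0)
    v_off: float = Field(0.5, gt=0)
    dev_r_on: float = Field(0.0, ge=0)
    dev_r_off: float = Field(0.0, ge=0)
    dev_v_on: float = Field(0.0, ge=0)
    dev_v_off: float = Field(0.0, ge=0)
    seed: int = 0


class StimulusConfig(_Section):
    i_max: float = Field(1e-6, gt=0)
    s_pref: float = 0.0
    sigma_s: float = Field(30.0, gt=0)


class RunConfig(_Section):
    dt: float = Field(0.5e-6, gt=0)
    duration: float = Field(30e-3, gt=0)
    window: float = Field(30e-3, gt=0)
    trials: int = Field(100, ge=1)
    seed: int = 0
    stuck_isi_multiplier: float = Field(10.0, gt=0)
    stuck_width_multiplier: float = Field(10.0, gt=0)


class ExperimentConfig(_Section):
    circuit: CircuitConfig = Field(default_factory=CircuitConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    run: RunConfig = Field(default_factory=RunConfig)

    # ---- builders -------------------------------------------------------
    def switch_spec(self) -> ThresholdSwitchSpec:
        c = self.circuit
        return ThresholdSwitchSpec(r_on=c.r_on, r_off=c.r_off,
                                   v_on=c.v_on, v_off=c.v_off)

    def circuit_params(self) -> NeuronCircuitParams:
        c = self.circuit
        spec = self.switch_spec()
        return NeuronCircuitParams(
            r1=c.r1, r2=c.r2, r_load=c.r_load, c1=c.c1, c2=c.c2,
            v_dc1=-c.v_d, v_dc2=c.v_d, s1=spec, s2=spec,
        )

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(**self.noise.model_dump())

    def stimulus_map(self) -> StimulusMap:
        return StimulusMap(**self.stimulus.model_dump())

    def to_dict(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path | None) -> ExperimentConfig:
    """Load and validate a YAML/JSON config; None or empty file -> defaults."""
    if path is None:
        raw = {}
    else:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    unknown = set(raw) - {"circuit", "noise", "stimulus", "run"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    normalized = {
        section: _normalize_units(section, data)
        for section, data in raw.items()
        if isinstance(data, dict)
    }
    for section, data in raw.items():
        if not isinstance(data, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
    try:
        return ExperimentConfig(**normalized)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        )
        raise ConfigError(msgs) from exc


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of a fully-resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
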