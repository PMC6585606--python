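"""Run configuration: validated settings for simulations, from file or code."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import AGE_PRESETS, get_preset
from .dynamics import NOISE_DIALECTS, ModelParameters

__all__ = ["ConfigurationError", "RunConfig", "load_config"]


class ConfigurationError(ValueError):
    """Invalid, unknown, or contradictory configuration values."""


_EXPLICIT_KEYS = ("c_p", "c_np", "noise_strength")


@dataclass
class RunConfig:
    """Settings for a cohort run.

    Either a ``preset`` name (14mo / 24mo / 36mo) or the three explicit
    dynamical parameters (c_p, c_np, noise_strength) select the model;
    giving both is an error.  The shared constants default to the standard
    values (tau = 3, h = -2, beta = 2, 400 steps of dt = 0.05).
    """

    preset: str | None = None
    c_p: float | None = None
    c_np: float | None = None
    noise_strength: float | None = None
    tau: float = 3.0
    h: float = -2.0
    beta: float = 2.0
    dt: float = 0.05
    n_steps: int = 400
    noise_dialect: str = "sqrt-dt"
    n_participants: int = 500
    seed: int = 0
    memory_increment: float = 1.2
    sensory_strong: float = 6.0
    sensory_weak: float = 1.0
    filter_perfect_training: bool = False
    out: str | None = None

    def __post_init__(self) -> None:
        if self.preset is not None:
            if self.preset not in AGE_PRESETS:
                raise ConfigurationError(
                    f"unknown preset {self.preset!r}; expected one of {sorted(AGE_PRESETS)}"
                )
            clash = [k for k in _EXPLICIT_KEYS if getattr(self, k) is not None]
            if clash:
                raise ConfigurationError(
                    f"preset {self.preset!r} contradicts explicit keys {clash}; "
                    "give one or the other"
                )
        if self.noise_dialect not in NOISE_DIALECTS:
            raise ConfigurationError(
                f"unknown noise_dialect {self.noise_dialect!r}; "
                f"expected one of {NOISE_DIALECTS}"
            )
        if not isinstance(self.seed, int):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")

    def model_parameters(self) -> ModelParameters:
        """Resolve the configured model, raising if underspecified."""
        shared = dict(tau=self.tau, h=self.h, beta=self.beta, dt=self.dt,
                      n_steps=self.n_steps, noise_dialect=self.noise_dialect)
        if self.preset is not None:
            return get_preset(self.preset, **shared).params
        missing = [k for k in _EXPLICIT_KEYS if getattr(self, k) is None]
        if missing:
            raise ConfigurationError(
                f"no preset given and explicit parameters incomplete: missing {missing}"
            )
        try:
            return ModelParameters(c_p=self.c_p, c_np=self.c_np,
                                   noise_strength=self.noise_strength, **shared)
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file into a validated :class:`RunConfig`.

    Omitted keys take the standard defaults; unknown keys are rejected with
    a descriptive error.
    """
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} must contain a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys in {path}: {unknown}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
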