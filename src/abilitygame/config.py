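"""TOML configuration loading for evolutionary runs.

A run is described by one flat TOML document mixing game and simulation
keys, e.g.::

    p = 1.5
    mode = "sexual"
    n_individuals = 1000
    n_generations = 10001
    initial_ability = 1.0
    segregation_sd = 0.05
    seed = 42

Unknown keys and badly typed values raise :class:`ConfigError` naming the
offending key.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .exceptions import ConfigError, DomainError
from .evolution import SimConfig
from .model import ModelParams

__all__ = ["load_sim_config", "sim_config_from_dict"]

_SIM_KEYS = {
    "mode": str,
    "n_individuals": int,
    "n_generations": int,
    "initial_ability": float,
    "segregation_sd": float,
    "mutation_prob": float,
    "mutation_sd": float,
    "record_every": int,
    "seed": int,
}


def sim_config_from_dict(data: dict) -> tuple[SimConfig, ModelParams]:
    """Validate a flat key-value mapping into (SimConfig, ModelParams)."""
    data = dict(data)
    if "p" not in data:
        raise ConfigError("missing required key 'p' (cost exponent)")
    if "mode" not in data:
        raise ConfigError("missing required key 'mode' ('sexual' or 'asexual')")
    try:
        params = ModelParams(p=float(data.pop("p")))
    except (TypeError, ValueError) as exc:
        if isinstance(exc, DomainError):
            raise ConfigError(f"key 'p': {exc}") from exc
        raise ConfigError(f"key 'p' must be a number, got {data.get('p')!r}") from exc

    kwargs = {}
    for key, value in data.items():
        if key not in _SIM_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
        want = _SIM_KEYS[key]
        if want is str:
            if not isinstance(value, str):
                raise ConfigError(f"key {key!r} must be a string, got {value!r}")
        elif want is int:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"key {key!r} must be an integer, got {value!r}")
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"key {key!r} must be a number, got {value!r}")
            value = float(value)
        kwargs[key] = value
    try:
        config = SimConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return config, params


def load_sim_config(path) -> tuple[SimConfig, ModelParams]:
    """Read a flat TOML run configuration from ``path``."""
    path = Path(path)
    try:
        with path.open("rb") as fh:
            data = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: invalid TOML: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return sim_config_from_dict(data)
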