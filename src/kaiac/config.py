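"""Run configuration: profiles, validation, manifests.

The `paper` profile carries the full-scale sampling constants (224
walkers, 8 x 20,000 annealing steps, 50,000-step sampling runs, the
0.01-step evidence ladder); the `test` profile scales every chain length
down by at least two orders of magnitude for desk-scale runs.  Configs
load from YAML (or JSON, a YAML subset); unknown keys are rejected so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field

import yaml

from .evidence import LadderConfig
from .sampler import AnnealSchedule, FitConfig


@dataclass
class RunConfig:
    profile: str = "paper"
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    ladder: LadderConfig = field(default_factory=LadderConfig)
    phong_pctATP_grid: tuple = (20.0, 40.0, 60.0, 80.0, 100.0)
    phong_KD_grid: tuple = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    noise_sd: float = 1.0

    @classmethod
    def test_profile(cls, seed: int = 0) -> "RunConfig":
        return cls(
            profile="test",
            seed=seed,
            fit=FitConfig.test_scale(),
            ladder=LadderConfig.test_scale(),
        )


_NESTED = {"fit": FitConfig, "ladder": LadderConfig, "anneal": AnnealSchedule}


def _build(cls, data: dict, path: str = ""):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{path}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a RunConfig; an empty file yields full defaults
    (the paper profile).  Walker-count sanity (n_walkers > n_dims) is
    enforced where the fit is launched, when the dimension is known."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    if data.get("profile") == "test":
        base = dataclasses.asdict(RunConfig.test_profile())
        _merge(base, data)
        data = base
    return _build(RunConfig, data)


def _merge(base: dict, override: dict) -> None:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def check_walker_count(n_walkers: int, n_dims: int) -> None:
    """Ensemble MCMC needs more walkers than free parameters."""
    if n_walkers <= n_dims:
        raise ValueError(
            f"n_walkers={n_walkers} must exceed the number of free parameters ({n_dims})"
        )


def write_manifest(path, *, seed: int, config: RunConfig | None = None, **extra) -> None:
    """Record what produced an artifact: seed, config hash, versions."""
    payload = {
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "python": platform.python_version(),
        **extra,
    }
    if config is not None:
        blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
        payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
        payload["profile"] = config.profile
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
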