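"""Simulation configuration: typed sub-configs, YAML I/O, and shipped profiles.

Two profiles ship with the package:

* ``full`` — a 5000 x 1000 um strip of flattened gut surface, the calibration
  on which the baseline produces the murine 8-12 patches per run.
* ``test`` — a 2000 x 500 um strip with proportionally scaled stromal-cell
  count, used for fast perturbation experiments and in the test suite.

All lengths are micrometres, times are hours since E14.5 unless a key name
says otherwise (``dt_minutes``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for malformed configuration (unknown keys, invalid values)."""


@dataclass
class EnvironmentConfig:
    width_um: float = 5000.0
    height_um: float = 1000.0
    lto_count: int = 10
    lto_radius_um: float = 14.0


@dataclass
class CellConfig:
    motile_radius_um: float = 5.0
    speed_um_per_min: float = 5.0


@dataclass
class AdhesionConfig:
    r_adh_um: float = 25.0
    l0: float = 0.05
    dl: float = 0.09


@dataclass
class ChemokineConfig:
    r_chem_um: float = 80.0
    threshold: float = 0.3
    fd_step_um: float = 1.0


@dataclass
class InputConfig:
    """Cell-entry schedule parameters.

    ``fraction_pct`` is the percentage of the gut surface area occupied by
    LTin cells at E15.5 (t = 24 h); the flow-cytometry anchor is 0.45 %.
    ``fold`` multiplies the resulting E15.5 count (the fold-increase
    perturbations).  LTi entry is configured independently so that LTin
    perturbations leave the inducer population untouched.
    """

    form: str = "linear"  # linear | exponential | sqrt
    fraction_pct: float = 0.45
    fold: float = 1.0
    k_per_hour: float = 0.028881132523331052  # ln(2)/24: doubling per day
    t_end_hours: float = 72.0
    lti_form: str = "linear"
    lti_fraction_pct: float = 0.9


@dataclass
class PatchConfig:
    linking_distance_um: float = 20.0
    min_size: int = 15
    basis: str = "cells"  # cells | lto (what the cluster is detected from)


@dataclass
class SimConfig:
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    adhesion: AdhesionConfig = field(default_factory=AdhesionConfig)
    chemokine: ChemokineConfig = field(default_factory=ChemokineConfig)
    input: InputConfig = field(default_factory=InputConfig)
    patches: PatchConfig = field(default_factory=PatchConfig)
    dt_minutes: float = 1.0
    profile: str = "full"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        env = self.environment
        if env.width_um <= 0 or env.height_um <= 0:
            raise ConfigError("environment dimensions must be positive")
        if env.lto_count < 0:
            raise ConfigError("environment.lto_count must be >= 0")
        if self.dt_minutes <= 0:
            raise ConfigError("dt_minutes must be positive")
        total_min = self.input.t_end_hours * 60.0
        n_steps = total_min / self.dt_minutes
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigError(
                f"simulated window ({self.input.t_end_hours} h) is not divisible "
                f"into whole steps of {self.dt_minutes} min"
            )
        if self.input.form not in _FORMS:
            raise ConfigError(f"unknown input.form {self.input.form!r}")
        if self.input.lti_form not in _FORMS:
            raise ConfigError(f"unknown input.lti_form {self.input.lti_form!r}")
        if not 0.0 <= self.input.fraction_pct <= 100.0:
            raise ConfigError("input.fraction_pct must be in [0, 100]")
        if self.patches.min_size < 1:
            raise ConfigError("patches.min_size must be >= 1")
        if self.patches.basis not in ("cells", "lto"):
            raise ConfigError(f"unknown patches.basis {self.patches.basis!r}")

    @property
    def n_steps(self) -> int:
        return round(self.input.t_end_hours * 60.0 / self.dt_minutes)

    @property
    def gut_area_um2(self) -> float:
        return self.environment.width_um * self.environment.height_um

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **subtree_updates: dict[str, Any]) -> "SimConfig":
        """Return a copy with values inside named sub-configs replaced.

        ``cfg.replace(input={"fraction_pct": 0.35})`` touches only that key.
        """
        d = self.to_dict()
        for subtree, updates in subtree_updates.items():
            if subtree not in d:
                raise ConfigError(f"unknown configuration subtree {subtree!r}")
            if isinstance(updates, dict):
                unknown = set(updates) - set(d[subtree])
                if unknown:
                    raise ConfigError(
                        f"unknown keys in {subtree!r}: {sorted(unknown)}"
                    )
                d[subtree].update(updates)
            else:
                d[subtree] = updates
        return config_from_dict(d)


_FORMS = ("linear", "exponential", "sqrt")

_SUBCONFIGS = {
    "environment": EnvironmentConfig,
    "cells": CellConfig,
    "adhesion": AdhesionConfig,
    "chemokine": ChemokineConfig,
    "input": InputConfig,
    "patches": PatchConfig,
}


def config_from_dict(d: dict[str, Any]) -> SimConfig:
    """Build a :class:`SimConfig` from a (possibly partial) plain dict.

    Unknown keys at any level raise :class:`ConfigError` naming the offenders,
    so a typo in a YAML file fails loudly instead of silently using a default.
    """
    d = dict(d)
    kwargs: dict[str, Any] = {}
    for name, cls in _SUBCONFIGS.items():
        sub = d.pop(name, None)
        if sub is None:
            kwargs[name] = cls()
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"configuration section {name!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - valid
        if unknown:
            raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
        kwargs[name] = cls(**sub)
    for scalar in ("dt_minutes", "profile"):
        if scalar in d:
            kwargs[scalar] = d.pop(scalar)
    if d:
        raise ConfigError(f"unknown top-level configuration keys: {sorted(d)}")
    return SimConfig(**kwargs)


def default_config(profile: str = "full") -> SimConfig:
    """The shipped calibrations.

    The ``test`` profile keeps the full profile's densities (stromal cells per
    unit area; the 0.45 % motile-cell anchor is itself a density) on a domain
    a fifth the area, so per-run patch counts scale down accordingly.
    """
    if profile == "full":
        return SimConfig(profile="full")
    if profile == "test":
        return SimConfig(
            environment=EnvironmentConfig(
                width_um=2000.0, height_um=500.0, lto_count=3
            ),
            profile="test",
        )
    raise ConfigError(f"unknown profile {profile!r} (expected 'full' or 'test')")


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML configuration file.

    The file may set ``profile`` to start from a shipped profile and override
    individual keys on top of it.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    profile = raw.get("profile", "full")
    base = default_config(profile).to_dict()
    for key, value in raw.items():
        if key in _SUBCONFIGS:
            if not isinstance(value, dict):
                raise ConfigError(f"configuration section {key!r} must be a mapping")
            valid = set(base[key])
            unknown = set(value) - valid
            if unknown:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            base[key].update(value)
        elif key in ("dt_minutes", "profile"):
            base[key] = value
        else:
            raise ConfigError(f"unknown top-level configuration key: {key!r}")
    return config_from_dict(base)


def save_config(config: SimConfig, path: str | Path) -> None:
    """Write a configuration as YAML (round-trips losslessly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
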