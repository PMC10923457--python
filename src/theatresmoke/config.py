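"""Run configuration: one YAML document binding the whole pipeline.

Every physical constant the simulated theatre uses appears here with the
study's value as the default, so a bare ``RunConfig()`` reproduces the
published setup; anything may be overridden from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .empirical import CalibrationSet, DEFAULT_COMPOSITION
from .scene import TheatreScene
from .solver import (BoundaryConditionSet, GasProperties, SolverSettings,
                     TurbulenceConstants)

__all__ = ["RunConfig", "ConfigError"]

CONFIG_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated, YAML-round-trippable configuration of one simulation."""

    seed: int = 0
    resolution: tuple[int, int, int] = (40, 30, 15)
    #: stretch the mesh toward the incision (the physical smoke source is
    #: centimetres across, far below the mean cell size); disable for a
    #: uniform grid
    graded_mesh: bool = True
    tip_temps: tuple[float, ...] = (200.0, 300.0, 400.0, 500.0)
    composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    tar_density: float = 1000.0        # kg/m^3 (assumed; measured table unavailable)
    particle_density: float = 1200.0
    scene: TheatreScene = field(default_factory=TheatreScene)
    boundary: BoundaryConditionSet = field(default_factory=BoundaryConditionSet)
    settings: SolverSettings = field(default_factory=lambda: SolverSettings(
        tolerance=1e-3, max_iterations=3000))
    constants: TurbulenceConstants = field(default_factory=TurbulenceConstants)
    gas: GasProperties = field(default_factory=GasProperties)
    calibration: CalibrationSet = field(default_factory=CalibrationSet)
    thresholds: dict = field(default_factory=lambda: {
        "co_ppm": (9.0, 50.0, 200.0), "tar_g_m3": 20.0, "particle_g_m3": 12.0})

    def build_mesh(self):
        from .scene import GradingSpec, build_mesh

        grading = GradingSpec() if self.graded_mesh else None
        return build_mesh(self.scene, self.resolution, grading=grading)

    def __post_init__(self):
        self.resolution = tuple(int(v) for v in self.resolution)
        if len(self.resolution) != 3 or min(self.resolution) < 1:
            raise ConfigError("resolution must be three positive integers")
        self.tip_temps = tuple(float(t) for t in self.tip_temps)
        if self.tar_density <= 0 or self.particle_density <= 0:
            raise ConfigError("dispersed-phase densities must be positive")
        s = sum(self.composition.values())
        if s > 1 + 1e-12 or any(v < 0 for v in self.composition.values()):
            raise ConfigError("composition mole fractions must be in [0,1], sum <= 1")

    # -- YAML ---------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "version": CONFIG_VERSION,
            "seed": self.seed,
            "resolution": list(self.resolution),
            "graded_mesh": self.graded_mesh,
            "tip_temps": list(self.tip_temps),
            "composition": dict(self.composition),
            "tar_density": self.tar_density,
            "particle_density": self.particle_density,
            "scene": asdict(self.scene),
            "boundary": asdict(self.boundary),
            "settings": asdict(self.settings),
            "constants": asdict(self.constants),
            "gas": asdict(self.gas),
            "calibration": self.calibration.to_dict(),
            "thresholds": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                           for k, v in self.thresholds.items()},
        }
        return d

    def to_yaml(self, path=None) -> str:
        def _clean(o):
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            return o

        text = yaml.safe_dump(_clean(self.to_dict()), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {version}")
        kwargs = {}
        plain = ("seed", "resolution", "graded_mesh", "tip_temps",
                 "composition", "tar_density", "particle_density", "thresholds")
        for key in plain:
            if key in d:
                kwargs[key] = d.pop(key)
        builders = {
            "scene": (TheatreScene, "scene"),
            "boundary": (BoundaryConditionSet, "boundary"),
            "settings": (SolverSettings, "settings"),
            "constants": (TurbulenceConstants, "constants"),
            "gas": (GasProperties, "gas"),
        }
        for key, (klass, attr) in builders.items():
            if key in d:
                sub = d.pop(key)
                try:
                    sub = {k: (tuple(v) if isinstance(v, list) else v)
                           for k, v in sub.items()}
                    kwargs[attr] = klass(**sub)
                except TypeError as exc:
                    raise ConfigError(f"bad '{key}' block: {exc}") from None
        if "calibration" in d:
            kwargs["calibration"] = CalibrationSet.from_dict(d.pop("calibration"))
        if d:
            raise ConfigError(f"unknown config keys: {sorted(d)}")
        try:
            return cls(**kwargs)
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        import os

        if isinstance(path_or_text, str) and os.path.exists(path_or_text):
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        elif hasattr(path_or_text, "read"):
            data = yaml.safe_load(path_or_text)
        else:
            data = yaml.safe_load(path_or_text)
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(data)
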