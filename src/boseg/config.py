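"""Run configuration: one YAML document holding every model constant.

The package ships a single frozen ``defaults.yaml``; every experiment and
test uses it unchanged, so all reported numbers refer to one parameter
set.  ``RunConfig`` round-trips losslessly through YAML and records a
short hash of the resolved values next to run outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .contour import ContourParams
from .cost import ModelParams, ScaleMultipliers
from .interpreter import RepulsionSettings
from .optimizer import DescentSettings, RelaxationSchedule

__all__ = ["RunConfig", "load_config", "default_config"]

CONFIG_VERSION = "1.0"


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    multipliers: ScaleMultipliers = field(default_factory=ScaleMultipliers)
    schedule: RelaxationSchedule = field(default_factory=RelaxationSchedule)
    descent: DescentSettings = field(default_factory=DescentSettings)
    final_descent: DescentSettings = field(default_factory=DescentSettings)
    repulsion: RepulsionSettings = field(default_factory=RepulsionSettings)
    contour: ContourParams = field(default_factory=ContourParams)
    seed: int = 17
    illusory_fraction_threshold: float = 0.02
    version: str = CONFIG_VERSION

    _SECTIONS = {
        "model": ModelParams,
        "multipliers": ScaleMultipliers,
        "schedule": RelaxationSchedule,
        "descent": DescentSettings,
        "final_descent": DescentSettings,
        "repulsion": RepulsionSettings,
        "contour": ContourParams,
    }

    def to_dict(self) -> dict:
        out = {}
        for name, cls in self._SECTIONS.items():
            out[name] = dataclasses.asdict(getattr(self, name))
        out["seed"] = self.seed
        out["illusory_fraction_threshold"] = self.illusory_fraction_threshold
        out["version"] = self.version
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                section = data[name]
                valid = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(section) - valid
                if unknown:
                    raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")
                kwargs[name] = section_cls(**section)
        for name in ("seed", "illusory_fraction_threshold", "version"):
            if name in data:
                kwargs[name] = data[name]
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Short stable hash of the resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return RunConfig.from_dict(data)


def default_config() -> RunConfig:
    """The frozen parameter set shipped with the package."""
    text = resources.files("boseg").joinpath("defaults.yaml").read_text()
    return RunConfig.from_dict(yaml.safe_load(text))
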