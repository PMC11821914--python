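"""Analysis configuration: every module's tunables, YAML round-trippable.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError
from .frc import FRCParams
from .membrane import GapParams
from .sacd import SACDParams

__all__ = ["RegistrationParams", "RMSParams", "OpticsParams", "AnalysisConfig"]


@dataclass
class RegistrationParams:
    angle_range_deg: float = 10.0
    angle_step_deg: float = 0.25
    grid_spacing_px: int = 16


@dataclass
class RMSParams:
    n_pairs_per_bin: int = 1000
    n_bins: int = 10


@dataclass
class OpticsParams:
    na: float = 1.27
    wavelength_nm: float = 580.0


@dataclass
class AnalysisConfig:
    seed: int = 0
    frc: FRCParams = field(default_factory=FRCParams)
    gaps: GapParams = field(default_factory=GapParams)
    sacd: SACDParams = field(default_factory=SACDParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    rms: RMSParams = field(default_factory=RMSParams)
    optics: OpticsParams = field(default_factory=OpticsParams)

    # -- round-trip -------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    _SECTIONS = {"frc": FRCParams, "gaps": GapParams, "sacd": SACDParams,
                 "registration": RegistrationParams, "rms": RMSParams,
                 "optics": OpticsParams}

    @classmethod
    def from_dict(cls, doc: dict) -> "AnalysisConfig":
        def build(klass, sub):
            if not isinstance(sub, dict):
                raise SchemaError(f"expected a mapping for {klass.__name__}, got {sub!r}")
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - names
            if unknown:
                raise SchemaError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**sub)

        doc = dict(doc or {})
        kwargs = {}
        if "seed" in doc:
            kwargs["seed"] = doc.pop("seed")
        for name, klass in cls._SECTIONS.items():
            if name in doc:
                kwargs[name] = build(klass, doc.pop(name))
        if doc:
            raise SchemaError(f"unknown config keys: {sorted(doc)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
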