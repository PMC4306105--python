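"""Run configuration: YAML serialization and validation.

A :class:`RunConfig` aggregates every physical and numerical parameter of a
simulation campaign.  The defaults reproduce the reference stented-artery
setup: 3 mm lumen, 10 mm bend radius, 90-degree arc, six 0.1 mm struts,
blood with rho = 1055 kg/m^3 and mu = 3.5e-3 kg/(m s), drug diffusivities
1e-7 / 1e-12 m^2/s, Reynolds sweep {200, 400, 600, 800}.

All quantities are SI.  Validation happens eagerly: constructing the nested
dataclasses enforces every type invariant before any solve starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .flow_solver import FluidProperties, SolverSettings
from .drug_transport import TransportProperties
from .geometry import StentGeometry

__all__ = ["RunConfig"]

DEFAULT_REYNOLDS = (200.0, 400.0, 600.0, 800.0)


@dataclass(frozen=True)
class RunConfig:
    geometry: StentGeometry = field(default_factory=StentGeometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    transport: TransportProperties = field(default_factory=TransportProperties)
    solver: SolverSettings = field(default_factory=SolverSettings)
    reynolds_numbers: tuple[float, ...] = DEFAULT_REYNOLDS
    resolution: float = 20.0            # cells per mm
    wss_threshold: float = 0.5          # Pa, low-WSS definition
    line_offset: float = 0.25e-3        # m, reference-line offset from interface
    restrict_low_wss_to_stent: bool = True
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if any(re <= 0 for re in self.reynolds_numbers):
            raise ValueError("Reynolds numbers must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.wss_threshold <= 0:
            raise ValueError("wss_threshold must be positive")
        if self.line_offset <= 0:
            raise ValueError("line_offset must be positive")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["reynolds_numbers"] = list(self.reynolds_numbers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("geometry", StentGeometry), ("fluid", FluidProperties),
                         ("transport", TransportProperties),
                         ("solver", SolverSettings)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "reynolds_numbers" in d:
            d["reynolds_numbers"] = tuple(float(x) for x in d["reynolds_numbers"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
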