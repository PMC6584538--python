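"""Pipeline configuration with lossless YAML round trips."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .forward import IlluminationPlan
from .morphometry3d import RIBandSet
from .presets import MEDIUM_RI, RI_INCREMENT_ML_PER_G
from .reconstruction import ReconstructionSettings

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of an end-to-end run, serializable to/from YAML."""

    optics: IlluminationPlan = field(default_factory=IlluminationPlan)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    pad_um: float = 1.0
    bands: RIBandSet = field(default_factory=RIBandSet)
    medium_ri: float = MEDIUM_RI
    ri_increment: float = RI_INCREMENT_ML_PER_G
    reconstruction: ReconstructionSettings = field(default_factory=ReconstructionSettings)
    seed: int = 0
    n_per_group: int = 30
    simulate_optics: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"]["bands"] = [list(b) for b in self.bands.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "optics" in d:
            optics = dict(d["optics"])
            if optics.get("carrier_frequency") is not None:
                optics["carrier_frequency"] = tuple(optics["carrier_frequency"])
            d["optics"] = IlluminationPlan(**optics)
        if "bands" in d:
            b = dict(d["bands"])
            b["bands"] = tuple(tuple(x) for x in b["bands"])
            b["whole_cell"] = tuple(b["whole_cell"])
            d["bands"] = RIBandSet(**b)
        if "reconstruction" in d:
            d["reconstruction"] = ReconstructionSettings(**d["reconstruction"])
        if "voxel_size" in d:
            d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
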