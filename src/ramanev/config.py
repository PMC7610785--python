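"""Pipeline configuration: validated on load, written beside every run's
outputs so results are reproducible from (inputs, resolved config, seed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .bands import BandDefinition, DEFAULT_BANDS
from .preprocess import PreprocessConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    detection_k: float = 3.0
    # EV signal is cluster-sized (adjacent pixels); isolated single-pixel
    # positives are treated as noise flecks in the full pipeline
    prune_isolated: bool = True
    closing_radius: int = 1
    min_area: int = 25
    exterior_margin: int = 3
    pca_components: int = 2

    def __post_init__(self) -> None:
        if self.detection_k <= 0:
            raise ValueError("detection_k must be positive")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")
        if self.closing_radius < 0 or self.min_area < 0 or self.exterior_margin < 0:
            raise ValueError("morphology parameters must be non-negative")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocess"]["crop_range"] = list(self.preprocess.crop_range)
        d["bands"] = [
            {"name": b.name, "lo": b.lo, "hi": b.hi, "mode": b.mode} for b in self.bands
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pre = d.pop("preprocess", {})
        if isinstance(pre, dict):
            if "crop_range" in pre:
                pre["crop_range"] = tuple(pre["crop_range"])
            pre = PreprocessConfig(**pre)
        bands = d.pop("bands", None)
        if bands is None:
            bands = DEFAULT_BANDS
        else:
            bands = tuple(
                b if isinstance(b, BandDefinition) else BandDefinition(**b) for b in bands
            )
        return cls(preprocess=pre, bands=bands, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(loaded)
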