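"""Pipeline configuration: one document driving every processing stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .segmentation import DetectionConfig
from .windows import WindowSpec
from .stats import EquivalenceBounds, DEFAULT_BOUNDS
from .demodulation import DEFAULT_WAVELENGTH_MM

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved configuration for process/analyze runs.

    Every run logs ``config_hash`` so each reported number is traceable to
    the exact settings that produced it.
    """

    band_low_hz: float = 0.07
    band_high_hz: float = 0.4
    filter_order: int = 4
    zero_phase: bool = True
    wavelength_mm: float = DEFAULT_WAVELENGTH_MM
    displacement_sign: float = 1.0
    min_arc_deg: float = 90.0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    bounds: dict = field(
        default_factory=lambda: {
            m: (b.lower, b.upper) for m, b in DEFAULT_BOUNDS.items()
        }
    )
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("band edges must satisfy 0 < low < high")
        if isinstance(self.detection, dict):
            self.detection = DetectionConfig(**self.detection)
        if isinstance(self.window, dict):
            self.window = WindowSpec(**self.window)
        for m, b in self.bounds.items():
            lo, hi = (b.lower, b.upper) if isinstance(b, EquivalenceBounds) else tuple(b)
            EquivalenceBounds(lo, hi)  # validate
            self.bounds[m] = (lo, hi)

    def equivalence_bounds(self) -> dict[str, EquivalenceBounds]:
        return {m: EquivalenceBounds(*b) for m, b in self.bounds.items()}

    @property
    def transient_margin_s(self) -> float:
        return 1.0 / self.band_low_hz

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
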