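"""Pipeline configuration: every tunable of the end-to-end workflow in one
serialisable object, so any output is reproducible from config + seed."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import BinningConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of the transform/feature/ranking pipeline.

    ``voi_mode`` is ``"auto"`` (threshold + connected component around the
    SUV argmax) or ``"manual"`` (boxes read from ``voi_table``, a CSV with
    0-based inclusive voxel bounds per nodule).
    """

    suv_threshold: float = 2.5
    voi_mode: str = "auto"
    voi_table: str | None = None
    voi_margin_mm: float = 5.0
    contour_levels: int = 8
    binning: BinningConfig = field(default_factory=BinningConfig)
    pattern_neutral_reference: int = 2
    pattern_in_context: bool = True
    classification_threshold: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.suv_threshold <= 0:
            raise ValueError("suv_threshold must be positive")
        if self.voi_mode not in ("auto", "manual"):
            raise ValueError("voi_mode must be 'auto' or 'manual'")
        if self.voi_mode == "manual" and not self.voi_table:
            raise ValueError("voi_mode='manual' requires voi_table")
        if self.contour_levels < 2:
            raise ValueError("contour_levels must be >= 2")
        if not 0.0 <= self.classification_threshold <= 1.0:
            raise ValueError("classification_threshold must lie in [0, 1]")
        if self.voi_margin_mm < 0:
            raise ValueError("voi_margin_mm must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        binning = data.pop("binning", None)
        if isinstance(binning, dict):
            for key in ("v2_thresholds", "v3_thresholds", "v4_thresholds_mm2"):
                if key in binning and binning[key] is not None:
                    binning[key] = tuple(binning[key])
            data["binning"] = BinningConfig(**binning)
        elif binning is not None:
            data["binning"] = binning
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
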