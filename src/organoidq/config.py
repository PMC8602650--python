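"""Pipeline parameters and YAML round-trip.

Every numeric threshold used by segmentation, classification and
quantification lives here, so a single :class:`PipelineParams` fully
determines a run.  The CLI serialises the active parameter set next to every
output table (``runconfig.yaml``); re-running from that stamp reproduces all
deterministic outputs byte-for-byte.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class SegmentationParams:
    """Thresholds for the edge-projection / watershed segmentation.

    Lengths are in pixels of the input image.  ``canny_low``/``canny_high``
    default to ``None``, meaning the high threshold is set per plane by Otsu's
    method on the gradient magnitude and the low threshold to half of it.
    """

    autoscale_p_low: float = 1.0
    autoscale_p_high: float = 99.0
    canny_sigma: float = 2.0
    canny_low: Optional[float] = None
    canny_high: Optional[float] = None
    canny_floor_mult: float = 3.0
    min_edge_component_px: int = 10
    close_radius: int = 3
    boundary_erosion_px: int = 2
    min_object_area: int = 200
    min_peak_separation: int = 15
    min_peak_height: float = 5.0


@dataclass
class ClassificationParams:
    """Thresholds for crop extraction and the shape-feature classifier."""

    crop_size: int = 120
    crop_object_side: int = 116
    junk_area_px: float = 700.0
    junk_solidity: float = 0.5
    spheroid_circularity: float = 0.86
    spheroid_max_lobes: int = 1
    defect_depth_frac: float = 0.1


@dataclass
class QuantificationParams:
    exclude_junk: bool = True
    exclude_border: bool = False


@dataclass
class PipelineParams:
    """Complete parameter set for one pipeline run."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    quantification: QuantificationParams = field(default_factory=QuantificationParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        return cls(
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            classification=ClassificationParams(**d.get("classification", {})),
            quantification=QuantificationParams(**d.get("quantification", {})),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
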