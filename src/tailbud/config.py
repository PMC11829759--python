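"""Flat per-run pipeline configuration.

One text (YAML) config per run, no hidden state: every stage parameter
that matters lives here with its standard default — 10 µm equalisation
kernel, difference-of-Gaussians sigmas 1 and 3 (voxel units), 0.6 IoU
stitching threshold, two rounds of 0.8 µm median filtering for HCR
channels, 11 µm neighbourhood-averaging radius, MSD-exponent threshold
1.1, 60 µm track distance cutoff, and the usual significance tiers.
Configs round-trip losslessly through their file form and hash stably
for run manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # segmentation
    equalize_kernel_um: float = 10.0
    dog_low_sigma: float = 1.0
    dog_high_sigma: float = 3.0
    dog_sigma_units: str = "voxel"
    iou_threshold: float = 0.6
    nucleus_diameter_um: float = 10.0
    # expression quantification
    hcr_median_kernel_um: float = 0.8
    hcr_median_rounds: int = 2
    # registration / mapping
    neighborhood_radius_um: float = 11.0
    # track metrics
    msd_alpha_threshold: float = 1.1
    distance_cutoff_um: float = 60.0
    max_frame_gap: int = 2
    track_start_window_s: tuple[float, float] = (0.0, 600.0)
    min_track_length: int = 10
    # axis conventions (zyx unit vectors; ventral-positive DV)
    dv_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    ap_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    # statistics
    tier_thresholds: tuple[float, float, float, float] = (0.05, 0.01, 0.001, 0.0001)
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.iou_threshold <= 1:
            raise ValueError(f"iou_threshold must be in (0, 1], got {self.iou_threshold}")
        if not 0 < self.dog_low_sigma < self.dog_high_sigma:
            raise ValueError("need 0 < dog_low_sigma < dog_high_sigma")
        if self.dog_sigma_units not in ("voxel", "um"):
            raise ValueError(f"dog_sigma_units must be 'voxel' or 'um', got {self.dog_sigma_units!r}")
        if self.equalize_kernel_um <= 0 or self.hcr_median_kernel_um <= 0:
            raise ValueError("kernel sizes must be positive")
        if self.hcr_median_rounds < 1:
            raise ValueError("hcr_median_rounds must be >= 1")
        if self.neighborhood_radius_um <= 0 or self.distance_cutoff_um <= 0:
            raise ValueError("radii/cutoffs must be positive")
        if self.max_frame_gap < 0:
            raise ValueError("max_frame_gap must be >= 0")
        if list(self.tier_thresholds) != sorted(self.tier_thresholds, reverse=True):
            raise ValueError("tier_thresholds must be strictly decreasing")

    # -- round-trip --------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("track_start_window_s", "dv_axis", "ap_axis", "tier_thresholds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("track_start_window_s", "dv_axis", "ap_axis", "tier_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable content hash for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
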