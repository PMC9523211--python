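"""Analysis parameter set with the method's reference defaults.

Grid spacing (15 px), curvature-variation lag (5 frames) and the salience
threshold α = 0.6 follow the reference values of the method; the remaining
knobs (smoothing windows, flow window, event segmentation, intensity
scales) are implementation defaults documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    #: feature-point grid interval in pixels
    grid_spacing: int = 15
    #: curvature-variation lag in frames
    lag: int = 5
    #: salience threshold on normalised |Δτ|, in [0, 1]
    alpha: float = 0.6
    #: logistic slope of the rendering weight
    beta: float = 10.0
    #: absolute |Δτ| noise floor (1/px); clips never exceeding it carry no
    #: peristalsis and get zero salience
    min_magnitude: float = 2e-4
    #: temporal moving-average window (frames, odd)
    temporal_window: int = 5
    #: spatial moving-average window (grid cells, odd)
    spatial_window: int = 3
    #: optical-flow least-squares window (px)
    flow_window: int = 21
    #: warping iterations of the flow solver
    num_warp: int = 3
    #: minimum simultaneously salient rows for a frame to be wave-active
    min_count: int = 3
    #: discard events shorter than this (seconds)
    min_duration_s: float = 2.0
    #: merge active runs separated by gaps shorter than this (seconds)
    merge_gap_s: float = 3.0
    #: scale mapping fractional spatial extent to the intensity range axis
    range_scale: float = 2.0
    #: scale mapping fractional point participation to the amplitude axis
    amp_scale: float = 2.0
    #: random seed recorded in reports (the analysis itself is deterministic)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        for name in ("temporal_window", "spatial_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1")
        if self.min_count < 1 or self.min_duration_s <= 0 or self.merge_gap_s < 0:
            raise ValueError("event segmentation parameters must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
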