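"""Flat pipeline configuration with validated keys and documented defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .breathing import BreathingConfig
from .motion_tracking import TrackingConfig
from .movement import MovementConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable parameter of the pipeline, in one flat namespace.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    # tracking
    fps: float = 5.0
    probe_interval_s: float = 5.0
    rebase_px: float = 15.0
    reestimate_frac: float = 0.20
    reestimate_interval_s: float = 30.0
    gauss_delta_frac: float = 0.10
    gauss_support_sigmas: float = 3.0
    # breathing
    lowcut_hz: float = 0.05
    highcut_hz: float = 2.0
    lowpass_order: int = 5
    highpass_order: int = 2
    min_prominence_frac: float = 1.0
    min_distance_s: float = 60.0 / 180.0
    window_s: float = 60.0
    stride_s: float = 1.0
    thresh1: float | None = None
    thresh1_frac: float = 0.5
    thresh2: float | None = None
    thresh2_frac: float = 0.5
    breathing_axis: str = "y"
    # movement
    window_frames: int = 6
    stride_frames: int = 5
    min_mm: float = 9.0
    shoulder_m: float = 0.40
    # scoring
    intro_end_s: float = 120.0
    conclusive_s: float = 120.0
    baseline: float = 50.0
    score_min: float = 0.0
    score_max: float = 100.0
    low_rr: float = 10.0
    sustain_s: float = 60.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def tracking(self) -> TrackingConfig:
        return TrackingConfig(
            fps=self.fps,
            probe_interval_s=self.probe_interval_s,
            rebase_px=self.rebase_px,
            reestimate_frac=self.reestimate_frac,
            reestimate_interval_s=self.reestimate_interval_s,
            gauss_delta_frac=self.gauss_delta_frac,
            gauss_support_sigmas=self.gauss_support_sigmas,
        )

    def breathing(self) -> BreathingConfig:
        return BreathingConfig(
            lowcut_hz=self.lowcut_hz,
            highcut_hz=self.highcut_hz,
            lowpass_order=self.lowpass_order,
            highpass_order=self.highpass_order,
            min_prominence_frac=self.min_prominence_frac,
            min_distance_s=self.min_distance_s,
            window_s=self.window_s,
            stride_s=self.stride_s,
            thresh1=self.thresh1,
            thresh1_frac=self.thresh1_frac,
            thresh2=self.thresh2,
            thresh2_frac=self.thresh2_frac,
            axis=self.breathing_axis,
        )

    def movement(self) -> MovementConfig:
        return MovementConfig(
            window_frames=self.window_frames,
            stride_frames=self.stride_frames,
            min_mm=self.min_mm,
            shoulder_m=self.shoulder_m,
            fs=self.fps,
        )
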