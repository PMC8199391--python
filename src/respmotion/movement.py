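"""Windowed movement-direction classification for each body part.

Every keypoint's horizontal and vertical displacement series is scanned with
a 6-frame (1.2 s) window slid 5 frames (1 s) at a time.  Per window the
series is decomposed and the slope of a least-squares line fitted to the
trend component gives the movement direction: negative slope means left
(horizontal) or up (vertical, since image y grows downward and the exposed
semantics are physical), positive means right or down.  Windows whose net
displacement — last sample minus first, converted to millimetres through the
subject's physical shoulder width — is below the 9 mm micro-movement gate
emit nothing, so breathing-scale motion never registers as a movement event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .keypoints import AXES, KEYPOINT_NAMES, TrackSet

__all__ = [
    "MovementEvent",
    "MovementConfig",
    "decompose_trend",
    "window_direction",
    "analyze_movement",
]

#: default physical shoulder width in metres; 1 SWU = 400 mm under it
DEFAULT_SHOULDER_M = 0.40


@dataclass(frozen=True)
class MovementEvent:
    """One classified movement: a body part moving in one direction in one window."""

    part: str
    t_start: float
    t_end: float
    axis: str  # "horizontal" | "vertical"
    direction: str  # left | right | up | down
    net_mm: float
    slope: float  # SWU per second, image-coordinate sign


@dataclass
class MovementConfig:
    window_frames: int = 6  # 1.2 s at 5 fps
    stride_frames: int = 5  # 1 s
    min_mm: float = 9.0  # micro-movement gate
    shoulder_m: float = DEFAULT_SHOULDER_M
    fs: float = 5.0

    @property
    def mm_per_swu(self) -> float:
        return self.shoulder_m * 1000.0


def decompose_trend(window: np.ndarray, period: int | None = None) -> np.ndarray:
    """Extract the trend component of a short displacement window.

    For windows long enough to resolve seasonality (length >= 3 x period) a
    classical decomposition is used: the trend is the centred moving average
    of length ``period`` with shrinking averages at the edges.  The default
    6-sample window is too short for any seasonal structure, so its trend is
    the window smoothed with a 3-point moving average.  Deterministic.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    if period is not None and len(x) >= 3 * period:
        k = period if period % 2 == 1 else period + 1
    else:
        k = 3
    half = k // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def window_direction(
    window: np.ndarray,
    axis: str,
    mm_per_swu: float = DEFAULT_SHOULDER_M * 1000.0,
    min_mm: float = 9.0,
    fs: float = 5.0,
) -> tuple[str | None, float, float]:
    """Classify one window's movement direction, or None below the 9 mm gate.

    The gate compares ``|last - first|`` of the *raw* window, in millimetres;
    the direction comes from the sign of the least-squares slope of the
    window's trend component.  ``axis`` is ``"horizontal"`` (image x) or
    ``"vertical"`` (image y); vertical directions are physical, so a
    positive image-y slope (downward in the image) maps to ``"down"``.

    Returns ``(direction_or_None, net_mm, slope_swu_per_s)``.
    """
    x = np.asarray(window, dtype=float)
    if len(x) == 0:
        raise ValueError("empty window")
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"unknown axis {axis!r}")
    net_mm = float((x[-1] - x[0]) * mm_per_swu)
    trend = decompose_trend(x) if len(x) >= 2 else x
    t = np.arange(len(x)) / fs
    slope = float(np.polyfit(t, trend, 1)[0]) if len(x) >= 2 else 0.0
    if abs(net_mm) < min_mm or slope == 0.0:
        return None, net_mm, slope
    if axis == "horizontal":
        direction = "left" if slope < 0 else "right"
    else:
        direction = "down" if slope > 0 else "up"
    return direction, net_mm, slope


def analyze_movement(tracks: TrackSet, config: MovementConfig | None = None) -> list[MovementEvent]:
    """Emit movement events for every keypoint, axis and qualifying window.

    Windows are ``window_frames`` long with ``stride_frames`` stride over the
    valid samples; any window touching an invalid (person-absent) sample is
    skipped.
    """
    cfg = config or MovementConfig(fs=tracks.fs)
    events: list[MovementEvent] = []
    n = len(tracks)
    w, s = cfg.window_frames, cfg.stride_frames
    axis_names = {"x": "horizontal", "y": "vertical"}
    for start in range(0, n - w + 1, s):
        sl = slice(start, start + w)
        if not tracks.valid[sl].all():
            continue
        for part in KEYPOINT_NAMES:
            for ax in AXES:
                window = tracks.data[sl, KEYPOINT_NAMES.index(part), AXES.index(ax)]
                direction, net_mm, slope = window_direction(
                    window, axis_names[ax], cfg.mm_per_swu, cfg.min_mm, cfg.fs
                )
                if direction is not None:
                    events.append(
                        MovementEvent(
                            part=part,
                            t_start=tracks.time_s[start],
                            t_end=tracks.time_s[start + w - 1],
                            axis=axis_names[ax],
                            direction=direction,
                            net_mm=net_mm,
                            slope=slope,
                        )
                    )
    return events
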