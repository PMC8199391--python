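"""Named body keypoints and the pixel-space containers shared by all stages.

Eleven upper/lower-body landmarks are tracked: head, thorax, stomach and the
left/right shoulders, elbows, wrists and knees.  All pixel coordinates use the
image convention (x = column rightward, y = row downward, 0-based).  The
distance between the two shoulder keypoints -- the *shoulder width* -- is the
length unit everything downstream is normalised by (1 SWU = one shoulder
width), which makes displacement tracks comparable across camera resolutions
and subject sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KEYPOINT_NAMES: tuple[str, ...] = (
    "head",
    "thorax",
    "stomach",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_knee",
    "right_knee",
)

AXES: tuple[str, str] = ("x", "y")

#: body-part groups used by the scoring rules
PART_GROUPS: dict[str, str] = {
    "head": "head",
    "left_knee": "lower_body",
    "right_knee": "lower_body",
    "left_wrist": "hands",
    "right_wrist": "hands",
    "left_elbow": "hands",
    "right_elbow": "hands",
    "thorax": "body",
    "stomach": "body",
    "left_shoulder": "body",
    "right_shoulder": "body",
}


@dataclass
class KeypointSet:
    """Pixel coordinates of the 11 named keypoints in one frame.

    Parameters
    ----------
    coords
        Mapping from keypoint name to ``(x, y)`` pixel coordinates.
    timestamp
        Seconds from the start of the video.
    """

    coords: dict[str, tuple[float, float]]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        missing = set(KEYPOINT_NAMES) - set(self.coords)
        if missing:
            raise ValueError(f"missing keypoints: {sorted(missing)}")

    def as_array(self) -> np.ndarray:
        """Coordinates as a ``(11, 2)`` float array in ``KEYPOINT_NAMES`` order."""
        return np.array([self.coords[name] for name in KEYPOINT_NAMES], dtype=float)

    @property
    def shoulder_width(self) -> float:
        """Euclidean pixel distance between the shoulder keypoints."""
        ls = np.asarray(self.coords["left_shoulder"], dtype=float)
        rs = np.asarray(self.coords["right_shoulder"], dtype=float)
        return float(np.linalg.norm(ls - rs))

    def validate(self, shape: tuple[int, int]) -> None:
        """Check all coordinates lie inside an image of ``(rows, cols)``."""
        rows, cols = shape
        for name, (x, y) in self.coords.items():
            if not (0 <= x < cols and 0 <= y < rows):
                raise ValueError(f"keypoint {name!r} at ({x}, {y}) outside {cols}x{rows} image")
        if self.shoulder_width <= 0:
            raise ValueError("shoulder width must be positive")


@dataclass
class TrackSet:
    """Per-keypoint absolute-displacement time series in shoulder-width units.

    ``data`` holds one sample per processed frame for each keypoint and axis
    (shape ``(n_frames, 11, 2)``); samples taken while no person was in frame
    are NaN and flagged invalid.  Displacement is measured from the first
    frame in which the person was found, so the first valid sample is zero.
    """

    fs: float
    time_s: np.ndarray
    data: np.ndarray  # (n, 11, 2) SWU, NaN where invalid
    valid: np.ndarray  # (n,) bool
    correction_px: np.ndarray = field(default_factory=lambda: np.zeros((len(KEYPOINT_NAMES), 2)))
    base_frame_history: list[int] = field(default_factory=list)
    shoulder_width_px: float = float("nan")
    status: str = "ok"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.time_s) != len(self.data) or len(self.time_s) != len(self.valid):
            raise ValueError("time, data and validity mask lengths differ")

    def __len__(self) -> int:
        return len(self.time_s)

    def series(self, part: str, axis: str) -> np.ndarray:
        """Displacement series (SWU) for one keypoint and axis; NaN where invalid."""
        return self.data[:, KEYPOINT_NAMES.index(part), AXES.index(axis)]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs if len(self) else 0.0
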