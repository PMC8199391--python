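"""Pluggable person / keypoint / flow backends for the tracking loop.

The tracking algorithm only needs three capabilities and is agnostic to how
they are produced, so each is an injectable callable:

* **person backend** -- ``(frame, frame_idx) -> bool``: is a person in frame?
* **keypoint backend** -- ``(frame, frame_idx) -> KeypointSet | None``:
  estimate the 11 body keypoints (None when estimation fails / no person).
* **flow backend** -- ``(base_frame, frame) -> FlowField``: dense optical
  flow between the base frame and the current frame, returned as an
  ``(rows, cols, 2)`` array of per-pixel ``(dx, dy)`` displacements in
  pixels, positive when scene content moved right/down.

The default flow backend is a classical dense estimator (iterative
Lucas-Kanade); a learned estimator can be dropped in without touching the
tracking loop.  The fixture backends replay scripted ground truth and keep
the whole pipeline testable without any model download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.registration import optical_flow_ilk

from .keypoints import KeypointSet

FlowField = np.ndarray  # (rows, cols, 2) of (dx, dy) in pixels


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3].mean(axis=-1)
    return frame.astype(np.float32)


@dataclass
class ILKFlow:
    """Dense optical flow via iterative Lucas-Kanade with image warping.

    A classical coarse-to-fine estimator: each pixel's displacement is solved
    from local image gradients in a ``radius``-pixel neighbourhood, iterated
    ``num_warp`` times with the moving image warped back between iterations.
    Accurate to a few hundredths of a pixel on textured scenes, which is what
    the sub-pixel breathing motion requires.
    """

    radius: int = 7
    num_warp: int = 3

    def __call__(self, base_frame: np.ndarray, frame: np.ndarray) -> FlowField:
        base = _to_gray(base_frame)
        cur = _to_gray(frame)
        if base.shape != cur.shape:
            raise ValueError("base frame and current frame shapes differ")
        # returns (2, r, c) in (row, col) order; positive = content moved down/right
        flow_rc = optical_flow_ilk(base, cur, radius=self.radius, num_warp=self.num_warp)
        return np.stack([flow_rc[1], flow_rc[0]], axis=-1)


@dataclass
class ConstantFlow:
    """Test double: per-frame-index constant flow fields.

    ``vectors[i]`` is the uniform ``(dx, dy)`` displacement of frame ``i``
    relative to frame ``base_idx``; the backend is told the current base via
    ``set_base`` by the tracking loop when used directly in tests.
    """

    vectors: Sequence[tuple[float, float]]
    shape: tuple[int, int]

    def field_for(self, vec: tuple[float, float]) -> FlowField:
        out = np.empty(self.shape + (2,), dtype=float)
        out[..., 0], out[..., 1] = vec
        return out


class AlwaysPresent:
    """Person backend that reports a person in every frame."""

    def __call__(self, frame: np.ndarray, frame_idx: int) -> bool:
        return True


@dataclass
class ScriptedPresence:
    """Person backend replaying a scripted presence schedule.

    ``present(t)`` is evaluated at the frame timestamp ``frame_idx / fs``.
    """

    present: Callable[[float], bool]
    fs: float = 5.0

    def __call__(self, frame: np.ndarray, frame_idx: int) -> bool:
        return bool(self.present(frame_idx / self.fs))


@dataclass
class ScriptedKeypoints:
    """Fixture keypoint backend replaying ground-truth keypoints per frame.

    ``sets[i]`` is the true :class:`KeypointSet` for frame ``i`` (or None
    while the person is absent).  Stands in for a learned pose estimator.
    """

    sets: Sequence[Optional[KeypointSet]]

    def __call__(self, frame: np.ndarray, frame_idx: int) -> Optional[KeypointSet]:
        if frame_idx >= len(self.sets):
            return None
        return self.sets[frame_idx]

    def presence(self) -> "ScriptedPresence":
        """Matching person backend: present wherever a keypoint set exists."""
        sets = self.sets

        def present(t: float) -> bool:
            i = int(round(t * 5.0))
            return i < len(sets) and sets[i] is not None

        return ScriptedPresence(present, fs=5.0)
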