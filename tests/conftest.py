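"""Shared fixtures: small rendered sessions and scripted tracking backends."""

from __future__ import annotations

import numpy as np
import pytest

import respmotion as rm
from respmotion.backends import ILKFlow, ScriptedKeypoints


@pytest.fixture(scope="session")
def breathing_render():
    """A 12 s toy video (320x240, shoulder width 50 px) with 12 mm thorax
    breathing at 12 BPM, tracked end to end with the default dense-flow
    backend.  Session-scoped: the flow computation is the expensive part."""
    script = rm.MotionScript(
        duration_s=12.0,
        image_size=(240, 320),
        shoulder_width_px=50.0,
        breathing_amplitude_mm=12.0,
        breathing_rr_bpm=12.0,
        seed=7,
    )
    frames, kp_sets = rm.render_video(script)
    backend = ScriptedKeypoints(kp_sets)
    tracks = rm.track_session(frames, backend.presence(), backend, ILKFlow(), rm.TrackingConfig())
    return script, frames, kp_sets, tracks


class IndexedUniformFlow:
    """Flow backend for scripted rigid translation: frames are constant
    images whose value encodes the frame index, and the flow between two
    frames is the uniform difference of the scripted positions."""

    def __init__(self, positions: np.ndarray, shape: tuple[int, int] = (120, 160)):
        self.positions = np.asarray(positions, dtype=float)  # (n, 2) px
        self.shape = shape

    def frames(self) -> list[np.ndarray]:
        return [np.full(self.shape, i, dtype=np.int32) for i in range(len(self.positions))]

    def __call__(self, base: np.ndarray, frame: np.ndarray) -> np.ndarray:
        i0, i1 = int(base.flat[0]), int(frame.flat[0])
        vec = self.positions[i1] - self.positions[i0]
        out = np.empty(self.shape + (2,), dtype=float)
        out[..., 0], out[..., 1] = vec
        return out


def rigid_keypoints(positions: np.ndarray, shape=(120, 160), fs=5.0) -> ScriptedKeypoints:
    """Keypoint sets for a rigidly translating person inside ``shape``."""
    rows, cols = shape
    base = {
        "head": (80, 20), "thorax": (80, 50), "stomach": (80, 70),
        "left_shoulder": (65, 40), "right_shoulder": (95, 40),
        "left_elbow": (55, 60), "right_elbow": (105, 60),
        "left_wrist": (50, 80), "right_wrist": (110, 80),
        "left_knee": (65, 100), "right_knee": (95, 100),
    }
    sets = []
    for i, (dx, dy) in enumerate(np.asarray(positions, dtype=float)):
        coords = {k: (x + dx, y + dy) for k, (x, y) in base.items()}
        sets.append(rm.KeypointSet(coords=coords, timestamp=i / fs))
    return ScriptedKeypoints(sets)
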