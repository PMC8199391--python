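"""Per-keypoint displacement tracking from dense optical flow.

Stage one of the pipeline: a frame sequence (already resampled to the 5 fps
working rate) is turned into 22 absolute-displacement series -- 11 keypoints
x 2 axes -- expressed in shoulder-width units (SWU).

A keypoint's displacement between the *base frame* and the current frame is
the Gaussian-weighted mean of the dense flow field around the keypoint: the
weights fall off with distance from the keypoint with a standard deviation
delta equal to 10% of the shoulder width, which averages out both flow noise
and keypoint-estimation error.  The base frame is replaced (*rebased*)
whenever any keypoint has moved more than ``rebase_px`` pixels from it,
accumulating the displacement into per-keypoint correction vectors so that
absolute displacement from the session start is ``correction + current``.
Keypoints are re-estimated when any absolute displacement since the last
estimation exceeds 20% of the shoulder width, and periodically every 30 s,
to reset accumulated drift.  Frames before the person first appears, and
gaps where the person leaves, are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .backends import FlowField
from .keypoints import KEYPOINT_NAMES, KeypointSet, TrackSet

__all__ = [
    "TrackingConfig",
    "gaussian_weight_field",
    "keypoint_displacement",
    "normalize_displacement",
    "track_session",
    "flow_heatmap",
]


@dataclass
class TrackingConfig:
    """Parameters of the tracking loop (all lengths in pixels or seconds)."""

    fps: float = 5.0
    probe_interval_s: float = 5.0  # person-probing cadence while nobody is in frame
    rebase_px: float = 15.0  # base-frame replacement threshold
    reestimate_frac: float = 0.20  # of shoulder width, since last estimation
    reestimate_interval_s: float = 30.0
    gauss_delta_frac: float = 0.10  # delta as a fraction of shoulder width
    gauss_support_sigmas: float = 3.0  # weight support truncation radius


def gaussian_weight_field(
    keypoint: tuple[float, float],
    shoulder_width_px: float,
    shape: tuple[int, int],
    delta_frac: float = 0.10,
    support_sigmas: float = 3.0,
) -> np.ndarray:
    """Normalised isotropic Gaussian weights centred on a keypoint.

    ``delta = delta_frac * shoulder_width_px`` is the Gaussian standard
    deviation; weights are truncated to zero beyond ``support_sigmas * delta``
    (>99% of the mass for the default 3 sigma) and renormalised to sum to 1.

    Parameters
    ----------
    keypoint
        ``(x, y)`` pixel coordinates of the keypoint.
    shoulder_width_px
        Shoulder width in pixels; must be positive.
    shape
        ``(rows, cols)`` of the image.

    Returns
    -------
    ndarray of shape ``shape`` summing to 1.
    """
    if shoulder_width_px <= 0:
        raise ValueError("shoulder width must be positive")
    rows, cols = shape
    x0, y0 = float(keypoint[0]), float(keypoint[1])
    if not (0 <= x0 < cols and 0 <= y0 < rows):
        raise ValueError(f"keypoint ({x0}, {y0}) outside {cols}x{rows} image")
    delta = delta_frac * shoulder_width_px
    yy, xx = np.mgrid[0:rows, 0:cols]
    r2 = (xx - x0) ** 2 + (yy - y0) ** 2
    w = np.exp(-r2 / (2.0 * delta**2))
    w[r2 > (support_sigmas * delta) ** 2] = 0.0
    total = w.sum()
    if total <= 0:  # pragma: no cover - support always contains >= 1 pixel
        raise ValueError("empty weight support")
    return w / total


def keypoint_displacement(flow: FlowField, weights: np.ndarray) -> np.ndarray:
    """Weighted mean of the flow field: the keypoint's ``(dx, dy)`` in pixels.

    Because the weights sum to 1 this is a weighted average, so a uniform
    flow maps to itself and adding a constant to the flow adds the same
    constant to the result.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.shape[:2] != weights.shape:
        raise ValueError(f"flow shape {flow.shape[:2]} != weights shape {weights.shape}")
    return np.array(
        [float((flow[..., 0] * weights).sum()), float((flow[..., 1] * weights).sum())]
    )


def normalize_displacement(vec_px: np.ndarray, shoulder_width_px: float) -> np.ndarray:
    """Convert a pixel displacement vector to shoulder-width units."""
    if shoulder_width_px <= 0:
        raise ValueError("shoulder width must be positive")
    return np.asarray(vec_px, dtype=float) / shoulder_width_px


class BackendError(RuntimeError):
    """A backend raised while processing a frame; carries the frame index."""

    def __init__(self, stage: str, frame_idx: int, original: Exception):
        super().__init__(f"{stage} backend failed at frame {frame_idx}: {original}")
        self.stage = stage
        self.frame_idx = frame_idx
        self.original = original


@dataclass
class _TrackerState:
    init_pos: np.ndarray  # (11, 2) px at first estimation
    cur_pos: np.ndarray  # (11, 2) px in the current base frame
    correction: np.ndarray  # (11, 2) px accumulated at rebases / re-estimations
    disp_at_est: np.ndarray  # (11, 2) absolute px displacement at last estimation
    shoulder_width: float
    weights: list[np.ndarray] = field(default_factory=list)


def track_session(
    frames: Iterable[np.ndarray],
    person_backend: Callable[[np.ndarray, int], bool],
    keypoint_backend: Callable[[np.ndarray, int], Optional[KeypointSet]],
    flow_backend: Callable[[np.ndarray, np.ndarray], FlowField],
    config: TrackingConfig | None = None,
) -> TrackSet:
    """Run the full tracking loop over a 5 fps frame sequence.

    The loop: (a) probe for a person every ``probe_interval_s`` until one is
    found; (b) estimate keypoints and set the base frame; (c) for every
    subsequent frame compute dense flow against the base frame and each
    keypoint's weighted displacement; (d) rebase when any keypoint moved more
    than ``rebase_px`` from the base frame, folding the displacement into the
    correction vectors; (e) re-estimate keypoints when any absolute
    displacement since the last estimation exceeds ``reestimate_frac`` of the
    shoulder width or every ``reestimate_interval_s`` (re-estimation wins if
    both trigger); (f) if re-estimation finds nobody, fall back to probing
    and mark the gap invalid.

    Returns a :class:`TrackSet` in SWU; ``status`` is ``"no_person"`` when
    nobody was ever found.
    """
    cfg = config or TrackingConfig()
    probe_every = max(1, int(round(cfg.probe_interval_s * cfg.fps)))
    reest_every = max(1, int(round(cfg.reestimate_interval_s * cfg.fps)))

    times: list[float] = []
    samples: list[np.ndarray] = []  # (11, 2) SWU or NaN
    valid: list[bool] = []
    base_history: list[int] = []

    nan_sample = np.full((len(KEYPOINT_NAMES), 2), np.nan)
    state: Optional[_TrackerState] = None
    base_frame: Optional[np.ndarray] = None
    last_est_idx = -1
    searching = True

    def make_weights(st: _TrackerState, shape: tuple[int, int]) -> None:
        rows, cols = shape
        st.weights = []
        for pos in st.cur_pos:
            x = float(np.clip(pos[0], 0, cols - 1))
            y = float(np.clip(pos[1], 0, rows - 1))
            st.weights.append(
                gaussian_weight_field(
                    (x, y), st.shoulder_width, shape, cfg.gauss_delta_frac, cfg.gauss_support_sigmas
                )
            )

    def estimate(frame: np.ndarray, idx: int) -> Optional[KeypointSet]:
        try:
            return keypoint_backend(frame, idx)
        except Exception as exc:  # noqa: BLE001 - annotated and re-raised
            raise BackendError("keypoint", idx, exc) from exc

    for idx, frame in enumerate(frames):
        frame = np.asarray(frame)
        shape = frame.shape[:2]
        t = idx / cfg.fps
        times.append(t)

        if searching:
            found = False
            if idx % probe_every == 0:
                try:
                    found = bool(person_backend(frame, idx))
                except Exception as exc:  # noqa: BLE001
                    raise BackendError("person", idx, exc) from exc
            if found:
                kps = estimate(frame, idx)
                found = kps is not None
            if not found:
                samples.append(nan_sample.copy())
                valid.append(False)
                continue
            pos = kps.as_array()
            if state is None:
                state = _TrackerState(
                    init_pos=pos.copy(),
                    cur_pos=pos.copy(),
                    correction=np.zeros_like(pos),
                    disp_at_est=np.zeros_like(pos),
                    shoulder_width=kps.shoulder_width,
                )
            else:
                # re-anchor after an absence gap: absolute displacement is the
                # keypoint position change since the very first estimation
                state.cur_pos = pos.copy()
                state.correction = pos - state.init_pos
                state.disp_at_est = state.correction.copy()
                state.shoulder_width = kps.shoulder_width
            make_weights(state, shape)
            base_frame = frame
            base_history.append(idx)
            last_est_idx = idx
            searching = False
            samples.append(state.correction / state.shoulder_width)
            valid.append(True)
            continue

        # tracking mode
        assert state is not None and base_frame is not None
        try:
            flow = flow_backend(base_frame, frame)
        except Exception as exc:  # noqa: BLE001
            raise BackendError("flow", idx, exc) from exc
        disp_px = np.array([keypoint_displacement(flow, w) for w in state.weights])
        abs_px = state.correction + disp_px

        since_est = np.linalg.norm(abs_px - state.disp_at_est, axis=1)
        need_reest = (idx - last_est_idx) >= reest_every or bool(
            (since_est > cfg.reestimate_frac * state.shoulder_width).any()
        )
        if need_reest:
            kps = estimate(frame, idx)
            if kps is None:
                searching = True
                samples.append(nan_sample.copy())
                valid.append(False)
                continue
            pos = kps.as_array()
            state.cur_pos = pos.copy()
            state.correction = pos - state.init_pos
            state.disp_at_est = state.correction.copy()
            state.shoulder_width = kps.shoulder_width
            make_weights(state, shape)
            base_frame = frame
            base_history.append(idx)
            last_est_idx = idx
            samples.append(state.correction / state.shoulder_width)
            valid.append(True)
            continue

        if bool((np.linalg.norm(disp_px, axis=1) > cfg.rebase_px).any()):
            state.correction = state.correction + disp_px
            state.cur_pos = state.cur_pos + disp_px
            make_weights(state, shape)
            base_frame = frame
            base_history.append(idx)
            abs_px = state.correction.copy()

        samples.append(abs_px / state.shoulder_width)
        valid.append(True)

    status = "ok" if state is not None else "no_person"
    return TrackSet(
        fs=cfg.fps,
        time_s=np.array(times),
        data=np.array(samples) if samples else np.zeros((0, len(KEYPOINT_NAMES), 2)),
        valid=np.array(valid, dtype=bool),
        correction_px=state.correction if state is not None else np.zeros((len(KEYPOINT_NAMES), 2)),
        base_frame_history=base_history,
        shoulder_width_px=state.shoulder_width if state is not None else float("nan"),
        status=status,
    )


def flow_heatmap(flow: FlowField, saturation_magnitude: float = 5.0) -> np.ndarray:
    """Render a flow field as an RGBA image (direction -> hue, magnitude -> alpha).

    The hue follows the standard optical-flow colour wheel (angle of the
    vector on the HSV wheel); the alpha channel is the vector magnitude
    scaled by ``saturation_magnitude`` (pixels at which the overlay becomes
    fully opaque) and clipped to [0, 1].  Zero flow is fully transparent.

    Returns a float RGBA array of shape ``(rows, cols, 4)`` in [0, 1].
    """
    from matplotlib.colors import hsv_to_rgb

    flow = np.asarray(flow, dtype=float)
    if not np.isfinite(flow).all():
        raise ValueError("flow field contains non-finite values")
    dx, dy = flow[..., 0], flow[..., 1]
    mag = np.hypot(dx, dy)
    # screen y grows downward; negate so "up" lands where the wheel expects it
    hue = (np.arctan2(-dy, dx) / (2 * np.pi)) % 1.0
    hsv = np.stack([hue, np.ones_like(hue), np.ones_like(hue)], axis=-1)
    rgb = hsv_to_rgb(hsv)
    alpha = np.clip(mag / saturation_magnitude, 0.0, 1.0)
    return np.concatenate([rgb, alpha[..., None]], axis=-1)
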