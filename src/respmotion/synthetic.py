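"""Ground-truthed synthetic inputs: breath signals, track sets, toy videos.

Everything the pipeline consumes can be generated here with known truth, so
every stage is testable offline:

* :func:`synth_breath_signal` -- a 1-D thorax-motion signal with a known
  (possibly time-varying) respiratory rate, amplitude modulation, linear
  drift and additive Gaussian noise, plus analytically derived true peak
  times and per-window true RR.
* :func:`synth_track_set` -- a noiseless :class:`TrackSet` following scripted
  per-keypoint trajectories (timed shifts in millimetres plus a breathing
  oscillation on the thorax and stomach), with the list of movement windows
  whose scripted net motion reaches the 9 mm gate.
* :func:`render_video` -- the same script rendered as textured patches over a
  textured background, with sub-pixel motion, so a dense optical-flow
  backend can recover the scripted trajectories end to end; returns the true
  per-frame keypoints for use as a fixture keypoint backend.

All generators are exactly reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter, map_coordinates

from .breathing import BreathSignal
from .keypoints import AXES, KEYPOINT_NAMES, KeypointSet, TrackSet

__all__ = [
    "BreathScript",
    "Shift",
    "MotionScript",
    "TruthLabel",
    "synth_breath_signal",
    "synth_track_set",
    "render_video",
]

#: default keypoint layout: offsets from the image centre in shoulder widths
_LAYOUT: dict[str, tuple[float, float]] = {
    "head": (0.0, -1.6),
    "left_shoulder": (-0.5, -0.7),
    "right_shoulder": (0.5, -0.7),
    "thorax": (0.0, 0.0),
    "stomach": (0.0, 0.8),
    "left_elbow": (-0.9, 0.1),
    "right_elbow": (0.9, 0.1),
    "left_wrist": (-1.1, 1.0),
    "right_wrist": (1.1, 1.0),
    "left_knee": (-0.6, 1.8),
    "right_knee": (0.6, 1.8),
}


@dataclass
class BreathScript:
    """Recipe for a synthetic thorax-motion signal.

    ``rr_bpm`` may be a constant, a ``(start, end)`` linear sweep over the
    whole duration, or a list of ``(time_s, rr)`` breakpoints interpolated
    piecewise-linearly.  ``drift_slope`` is in SWU per minute; noise is white
    Gaussian.  ``modulation`` optionally scales the amplitude over time as
    ``(times, factors)`` breakpoints.
    """

    rr_bpm: float | tuple[float, float] | Sequence[tuple[float, float]] = 12.0
    amplitude: float = 1.0
    duration_s: float = 120.0
    fs: float = 5.0
    drift_slope: float = 0.0  # SWU / min
    noise_sd: float = 0.0  # SWU
    modulation: Optional[tuple[Sequence[float], Sequence[float]]] = None
    seed: int = 0

    def rr_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.isscalar(self.rr_bpm) or isinstance(self.rr_bpm, (int, float)):
            return np.full_like(t, float(self.rr_bpm))
        arr = np.asarray(self.rr_bpm, dtype=float)
        if arr.ndim == 1 and len(arr) == 2:  # (start, end) sweep
            return np.interp(t, [0.0, self.duration_s], arr)
        return np.interp(t, arr[:, 0], arr[:, 1])

    def validate(self) -> None:
        rr = self.rr_at(np.linspace(0, self.duration_s, 101))
        if rr.min() < 3 or rr.max() > 180:
            raise ValueError("respiratory rate must stay within [3, 180] BPM")
        if self.fs <= 2 * rr.max() / 60.0:
            raise ValueError("sampling rate must exceed twice the breathing frequency")
        if self.duration_s <= 0 or self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("invalid script parameters")


def synth_breath_signal(script: BreathScript) -> tuple[BreathSignal, dict]:
    """Generate the scripted signal plus analytic ground-truth annotations.

    The signal is ``amplitude * mod(t) * sin(phase(t)) + drift + noise`` with
    ``phase(t) = 2*pi * integral of rr(t)/60``.  Annotations: ``peak_times``
    and ``trough_times`` solved from the phase function, and ``rr_window``
    mapping each 60 s window start (1 s stride) to the true breath count
    ``(phase(t+60) - phase(t)) / 2*pi``.
    """
    script.validate()
    rng = np.random.default_rng(script.seed)
    n = int(round(script.duration_s * script.fs))
    t = np.arange(n) / script.fs

    fine = np.linspace(0.0, script.duration_s, max(2, int(script.duration_s * 1000) + 1))
    phase_fine = 2 * np.pi * cumulative_trapezoid(script.rr_at(fine) / 60.0, fine, initial=0.0)
    phase = np.interp(t, fine, phase_fine)

    mod = np.ones_like(t)
    if script.modulation is not None:
        mt, mv = script.modulation
        mod = np.interp(t, np.asarray(mt, float), np.asarray(mv, float))

    x = script.amplitude * mod * np.sin(phase)
    x = x + script.drift_slope * t / 60.0
    if script.noise_sd > 0:
        x = x + rng.normal(0.0, script.noise_sd, size=n)

    total = phase_fine[-1]
    peak_targets = np.arange(np.pi / 2, total, 2 * np.pi)
    trough_targets = np.arange(3 * np.pi / 2, total, 2 * np.pi)
    peak_times = np.interp(peak_targets, phase_fine, fine)
    trough_times = np.interp(trough_targets, phase_fine, fine)

    rr_window = {}
    if script.duration_s >= 60.0:
        for t0 in np.arange(0.0, script.duration_s - 60.0 + 1e-9, 1.0):
            p0 = np.interp(t0, fine, phase_fine)
            p1 = np.interp(t0 + 60.0, fine, phase_fine)
            rr_window[float(t0)] = (p1 - p0) / (2 * np.pi)

    annotations = {
        "peak_times": peak_times,
        "trough_times": trough_times,
        "rr_window": rr_window,
        "mean_rr": total / (2 * np.pi) * 60.0 / script.duration_s,
    }
    return BreathSignal(samples=x, fs=script.fs), annotations


@dataclass(frozen=True)
class Shift:
    """A timed smooth shift of one keypoint along one image axis.

    ``magnitude_mm`` is signed in image coordinates: positive x moves right,
    positive y moves down.  The shift ramps from 0 to its full magnitude
    over ``duration_s`` with a smoothstep profile.
    """

    part: str
    axis: str  # "x" | "y"
    t_start: float
    duration_s: float
    magnitude_mm: float


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth movement label for one window of a scripted session."""

    part: str
    t_start: float
    t_end: float
    axis: str  # horizontal | vertical
    direction: str
    net_mm: float


@dataclass
class MotionScript:
    """Recipe for a scripted multi-keypoint session (and its toy video)."""

    duration_s: float = 20.0
    fs: float = 5.0
    image_size: tuple[int, int] = (480, 640)  # rows, cols
    shoulder_width_px: float = 100.0
    shoulder_m: float = 0.40
    shifts: list[Shift] = field(default_factory=list)
    breathing_amplitude_mm: float = 2.0
    breathing_rr_bpm: float = 12.0
    absence: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0
    rest: Optional[dict[str, tuple[float, float]]] = None

    @property
    def px_per_mm(self) -> float:
        return self.shoulder_width_px / (self.shoulder_m * 1000.0)

    @property
    def mm_per_swu(self) -> float:
        return self.shoulder_m * 1000.0

    def rest_positions(self) -> dict[str, tuple[float, float]]:
        if self.rest is not None:
            return self.rest
        rows, cols = self.image_size
        cx, cy = cols / 2.0, rows / 2.0
        return {
            name: (cx + ox * self.shoulder_width_px, cy + oy * self.shoulder_width_px)
            for name, (ox, oy) in _LAYOUT.items()
        }

    def scaled(self, factor: float) -> "MotionScript":
        """The same physical scene rendered at ``factor`` x resolution."""
        rows, cols = self.image_size
        rest = None
        if self.rest is not None:
            rest = {k: (x * factor, y * factor) for k, (x, y) in self.rest.items()}
        return replace(
            self,
            image_size=(int(round(rows * factor)), int(round(cols * factor))),
            shoulder_width_px=self.shoulder_width_px * factor,
            rest=rest,
        )

    def absent_at(self, t: float) -> bool:
        return any(t0 <= t < t1 for t0, t1 in self.absence)

    def trajectory(self, part: str, t: np.ndarray) -> np.ndarray:
        """True pixel position of ``part`` at times ``t``; shape ``(len(t), 2)``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x0, y0 = self.rest_positions()[part]
        pos = np.stack([np.full_like(t, x0), np.full_like(t, y0)], axis=-1)
        if part in ("thorax", "stomach") and self.breathing_amplitude_mm > 0:
            amp_px = self.breathing_amplitude_mm * self.px_per_mm
            pos[:, 1] += amp_px * np.sin(2 * np.pi * self.breathing_rr_bpm / 60.0 * t)
        for sh in self.shifts:
            if sh.part != part:
                continue
            u = np.clip((t - sh.t_start) / max(sh.duration_s, 1e-9), 0.0, 1.0)
            ramp = u * u * (3.0 - 2.0 * u)  # smoothstep
            pos[:, AXES.index(sh.axis)] += sh.magnitude_mm * self.px_per_mm * ramp
        return pos

    def validate(self) -> None:
        rows, cols = self.image_size
        t = np.linspace(0, self.duration_s, max(2, int(self.duration_s * 10)))
        for part in KEYPOINT_NAMES:
            pos = self.trajectory(part, t)
            if pos[:, 0].min() < 0 or pos[:, 0].max() >= cols or pos[:, 1].min() < 0 or pos[:, 1].max() >= rows:
                raise ValueError(f"trajectory of {part!r} leaves the {cols}x{rows} image")
        if self.shoulder_width_px <= 0:
            raise ValueError("shoulder width must be positive")


def synth_track_set(
    script: MotionScript, min_mm: float = 9.0, window_frames: int = 6, stride_frames: int = 5
) -> tuple[TrackSet, list[TruthLabel], BreathScript]:
    """Noiseless SWU tracks, ground-truth movement labels and breath truth.

    Labels list every sliding window (same geometry as the movement
    classifier) whose scripted net motion on one axis reaches ``min_mm``,
    with the direction implied by the sign.
    """
    script.validate()
    n = int(round(script.duration_s * script.fs))
    times = np.arange(n) / script.fs
    valid = np.array([not script.absent_at(t) for t in times])
    sw = script.shoulder_width_px

    data = np.full((n, len(KEYPOINT_NAMES), 2), np.nan)
    first_valid = int(np.argmax(valid)) if valid.any() else 0
    t0 = times[first_valid]
    for k, part in enumerate(KEYPOINT_NAMES):
        traj = script.trajectory(part, times)
        ref = script.trajectory(part, np.array([t0]))[0]
        swu = (traj - ref) / sw
        data[valid, k, :] = swu[valid]

    labels: list[TruthLabel] = []
    axis_names = {"x": "horizontal", "y": "vertical"}
    for start in range(0, n - window_frames + 1, stride_frames):
        sl = slice(start, start + window_frames)
        if not valid[sl].all():
            continue
        for k, part in enumerate(KEYPOINT_NAMES):
            for a, ax in enumerate(AXES):
                net_swu = data[sl, k, a][-1] - data[sl, k, a][0]
                net_mm = net_swu * script.mm_per_swu
                if abs(net_mm) >= min_mm:
                    if ax == "x":
                        direction = "right" if net_mm > 0 else "left"
                    else:
                        direction = "down" if net_mm > 0 else "up"
                    labels.append(
                        TruthLabel(
                            part=part,
                            t_start=times[start],
                            t_end=times[start + window_frames - 1],
                            axis=axis_names[ax],
                            direction=direction,
                            net_mm=float(net_mm),
                        )
                    )

    breath_truth = BreathScript(
        rr_bpm=script.breathing_rr_bpm,
        amplitude=script.breathing_amplitude_mm / script.mm_per_swu,
        duration_s=script.duration_s,
        fs=script.fs,
        seed=script.seed,
    )
    tracks = TrackSet(
        fs=script.fs,
        time_s=times,
        data=data,
        valid=valid,
        shoulder_width_px=sw,
        status="ok" if valid.any() else "no_person",
    )
    return tracks, labels, breath_truth


def _noise_texture(rng: np.random.Generator, shape: tuple[int, int], sigma: float, lo: float, hi: float) -> np.ndarray:
    tex = gaussian_filter(rng.random(shape), sigma)
    tex = (tex - tex.min()) / max(float(np.ptp(tex)), 1e-12)
    return lo + (hi - lo) * tex


def render_video(
    script: MotionScript,
) -> tuple[list[np.ndarray], list[Optional[KeypointSet]]]:
    """Render the script as 8-bit RGB frames with sub-pixel patch motion.

    Each keypoint is a high-contrast textured square patch whose centre
    follows the scripted trajectory (sampled with bicubic interpolation, so
    fractions of a pixel register), over a static lower-contrast textured
    background.  During absence intervals only the background is rendered.

    Returns ``(frames, keypoint_sets)`` where ``keypoint_sets[i]`` is the
    true :class:`KeypointSet` for frame ``i`` (None while absent), directly
    usable with :class:`~respmotion.backends.ScriptedKeypoints`.
    """
    script.validate()
    rng = np.random.default_rng(script.seed)
    rows, cols = script.image_size
    half = int(np.ceil(0.3 * script.shoulder_width_px)) + 5
    margin = 4

    background = _noise_texture(rng, (rows, cols), sigma=1.5, lo=0.35, hi=0.6)
    textures = {
        part: _noise_texture(rng, (2 * (half + margin) + 1,) * 2, sigma=1.0, lo=0.0, hi=1.0)
        for part in KEYPOINT_NAMES
    }

    n = int(round(script.duration_s * script.fs))
    times = np.arange(n) / script.fs
    trajectories = {part: script.trajectory(part, times) for part in KEYPOINT_NAMES}

    frames: list[np.ndarray] = []
    kp_sets: list[Optional[KeypointSet]] = []
    for i, t in enumerate(times):
        img = background.copy()
        if script.absent_at(t):
            kp_sets.append(None)
        else:
            coords = {}
            for part in KEYPOINT_NAMES:
                x, y = trajectories[part][i]
                coords[part] = (float(x), float(y))
                r0, c0 = int(round(y)) - half, int(round(x)) - half
                rr_idx = np.arange(r0, r0 + 2 * half + 1)
                cc_idx = np.arange(c0, c0 + 2 * half + 1)
                rg, cg = np.meshgrid(rr_idx, cc_idx, indexing="ij")
                # texture coordinates: centre of the texture tracks (x, y)
                tr = rg - y + half + margin
                tc = cg - x + half + margin
                patch = map_coordinates(textures[part], [tr, tc], order=3, mode="nearest")
                inside = (rg >= 0) & (rg < rows) & (cg >= 0) & (cg < cols)
                img[rg[inside], cg[inside]] = patch[inside]
            kp_sets.append(KeypointSet(coords=coords, timestamp=float(t)))
        frame8 = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        frames.append(np.stack([frame8] * 3, axis=-1))
    return frames, kp_sets
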