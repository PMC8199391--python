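"""Reading and writing the stage-boundary files.

Every stage of the pipeline reads and writes plain-text formats so each
module is independently runnable: tracks as long-format CSV with a JSON
sidecar, breathing metrics as JSON, movement events and score timelines as
CSV.  Floats are written with 12 significant digits, so write -> read is an
identity up to that precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .breathing import BreathMetrics
from .keypoints import AXES, KEYPOINT_NAMES, KeypointSet, TrackSet
from .movement import MovementEvent
from .scoring import ScoreTimeline

__all__ = [
    "write_tracks",
    "read_tracks",
    "write_metrics",
    "read_metrics",
    "write_events",
    "read_events",
    "write_score",
    "read_breath_series",
    "load_frames",
    "write_frames",
    "write_keypoint_sets",
    "read_keypoint_sets",
]

_FLOAT_FMT = "%.12g"

TRACK_COLUMNS = ["time_s", "keypoint", "axis", "displacement_swu", "valid"]


class ParseError(ValueError):
    """A stage-boundary file did not conform to its schema."""


def write_tracks(tracks: TrackSet, path: str | Path, sidecar: bool = True, params: dict | None = None) -> None:
    """Write a TrackSet as long CSV plus a JSON sidecar with tracking state."""
    path = Path(path)
    rows = []
    for i, t in enumerate(tracks.time_s):
        for k, part in enumerate(KEYPOINT_NAMES):
            for a, ax in enumerate(AXES):
                rows.append((t, part, ax, tracks.data[i, k, a], bool(tracks.valid[i])))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if sidecar:
        meta = {
            "fs": tracks.fs,
            "shoulder_width_px": None if np.isnan(tracks.shoulder_width_px) else tracks.shoulder_width_px,
            "base_frame_history": list(map(int, tracks.base_frame_history)),
            "correction_px": np.asarray(tracks.correction_px).tolist(),
            "status": tracks.status,
            "params": params or {},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_tracks(path: str | Path) -> TrackSet:
    """Read a track CSV (and its JSON sidecar if present) back to a TrackSet."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df["keypoint"].loc[~df["keypoint"].isin(KEYPOINT_NAMES)]
    if len(bad):
        line = bad.index[0] + 2  # header + 1-based
        raise ParseError(f"{path}: unknown keypoint {bad.iloc[0]!r} at line {line}")

    times = np.sort(df["time_s"].unique())
    index = {t: i for i, t in enumerate(times)}
    n = len(times)
    data = np.full((n, len(KEYPOINT_NAMES), 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    for row in df.itertuples(index=False):
        i = index[row.time_s]
        data[i, KEYPOINT_NAMES.index(row.keypoint), AXES.index(row.axis)] = row.displacement_swu
        valid[i] = bool(row.valid)

    fs = 1.0 / np.median(np.diff(times)) if n > 1 else 5.0
    meta_path = path.with_suffix(".json")
    kwargs: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fs = meta.get("fs", fs)
        kwargs = {
            "shoulder_width_px": meta.get("shoulder_width_px") or float("nan"),
            "base_frame_history": meta.get("base_frame_history", []),
            "correction_px": np.asarray(meta.get("correction_px", np.zeros((len(KEYPOINT_NAMES), 2)))),
            "status": meta.get("status", "ok"),
        }
    return TrackSet(fs=float(fs), time_s=times, data=data, valid=valid, **kwargs)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_metrics(metrics: BreathMetrics, path: str | Path, params: dict | None = None) -> None:
    """Write breathing metrics as JSON, embedding the resolved parameters."""
    payload = {
        "rr_series": [
            {"t": float(t), "rr": float(v)} for t, v in zip(metrics.rr_times, metrics.rr_values)
        ],
        "rhythmic": metrics.rhythmic,
        "stable": metrics.stable,
        "amplitudes": _jsonify(metrics.amplitudes),
        "d1": _jsonify(metrics.d1),
        "d2": _jsonify(metrics.d2),
        "thresh1": metrics.thresh1,
        "thresh2": metrics.thresh2,
        "status": metrics.status,
        "params": {**metrics.params, **(params or {})},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def read_metrics(path: str | Path) -> BreathMetrics:
    payload = json.loads(Path(path).read_text())
    series = payload.get("rr_series")
    if series is None:
        raise ParseError(f"{path}: missing 'rr_series'")
    return BreathMetrics(
        rr_times=np.array([p["t"] for p in series]),
        rr_values=np.array([p["rr"] for p in series]),
        rhythmic=payload.get("rhythmic"),
        stable=payload.get("stable"),
        amplitudes=np.asarray(payload.get("amplitudes", [])),
        d1=np.asarray(payload.get("d1", [])),
        d2=np.asarray(payload.get("d2", [])),
        thresh1=payload.get("thresh1"),
        thresh2=payload.get("thresh2"),
        status=payload.get("status", "ok"),
        params=payload.get("params", {}),
    )


EVENT_COLUMNS = ["t_start", "t_end", "part", "axis", "direction", "net_mm", "slope"]


def write_events(events: Sequence[MovementEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.t_start, e.t_end, e.part, e.axis, e.direction, e.net_mm, e.slope) for e in events],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path: str | Path) -> list[MovementEvent]:
    try:
        df = pd.read_csv(Path(path))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        MovementEvent(
            part=row.part, t_start=float(row.t_start), t_end=float(row.t_end),
            axis=row.axis, direction=row.direction, net_mm=float(row.net_mm),
            slope=float(row.slope),
        )
        for row in df.itertuples(index=False)
    ]


def write_score(timeline: ScoreTimeline, path: str | Path, summary: dict | None = None) -> None:
    """Write the score timeline CSV and a JSON summary next to it."""
    path = Path(path)
    ann = [
        ";".join(f"{rule}:{delta:+d}" for rule, delta in timeline.annotations.get(t, []))
        for t in timeline.time_s
    ]
    df = pd.DataFrame({"time_s": timeline.time_s, "score": timeline.score, "annotations": ann})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    payload = {"final_score": timeline.final_score, **(summary or {})}
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2, default=_jsonify))


def read_breath_series(path: str | Path, axis: str = "y") -> tuple[np.ndarray, float]:
    """Load a thorax displacement series from a track CSV or a 2-column CSV.

    Accepts either the long track CSV (the thorax/``axis`` series is
    extracted, NaN where invalid) or a plain ``time_s, displacement`` CSV.
    Returns ``(samples, fs)``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if set(TRACK_COLUMNS) <= set(df.columns):
        tracks = read_tracks(path)
        return tracks.series("thorax", axis), tracks.fs
    if not {"time_s", "displacement"} <= set(df.columns):
        raise ParseError(f"{path}: expected track CSV or columns ['time_s', 'displacement']")
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 5.0
    return df["displacement"].to_numpy(dtype=float), float(fs)


def write_frames(frames: Sequence[np.ndarray], out_dir: str | Path) -> list[Path]:
    """Write a frame sequence as zero-padded PNGs (frame_00000.png, ...)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:05d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def load_frames(path: str | Path, fps: float = 5.0):
    """Yield frames at the working rate from a video file or a PNG directory.

    Directories are read as sorted image sequences already at the working
    rate.  Video files are decoded with imageio and resampled to ``fps`` by
    nearest-frame selection.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        for p in sorted(path.glob("*.png")):
            yield iio.imread(p)
        return
    meta = iio.immeta(path)
    src_fps = float(meta.get("fps", fps))
    step = src_fps / fps
    want = 0.0
    for i, frame in enumerate(iio.imiter(path)):
        if i + 1e-9 >= want:
            yield frame
            want += step


def write_keypoint_sets(kp_sets: Sequence[Optional[KeypointSet]], path: str | Path) -> None:
    """Serialise per-frame keypoint sets (None = absent) as JSON."""
    payload = [
        None if k is None else {"timestamp": k.timestamp, "coords": {n: list(c) for n, c in k.coords.items()}}
        for k in kp_sets
    ]
    Path(path).write_text(json.dumps(payload))


def read_keypoint_sets(path: str | Path) -> list[Optional[KeypointSet]]:
    payload = json.loads(Path(path).read_text())
    out: list[Optional[KeypointSet]] = []
    for item in payload:
        if item is None:
            out.append(None)
        else:
            out.append(
                KeypointSet(
                    coords={n: tuple(c) for n, c in item["coords"].items()},
                    timestamp=float(item.get("timestamp", 0.0)),
                )
            )
    return out
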