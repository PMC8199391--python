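"""End-to-end orchestration: track -> breathe -> move -> score.

:func:`run_pipeline` runs the four stages in order, starting from frames
(with backends) or from an existing :class:`TrackSet`, and optionally writes
every stage-boundary file.  Outputs are deterministic for identical inputs
and configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np

from . import io as rio
from .breathing import BreathMetrics, analyze_breathing
from .config import PipelineConfig
from .keypoints import TrackSet
from .motion_tracking import track_session
from .movement import MovementEvent, analyze_movement
from .scoring import (
    PhaseSchedule,
    RuleFiring,
    RuleTable,
    ScoreTimeline,
    derive_rule_events,
    score_session,
)

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("respmotion")


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    tracks: Optional[TrackSet] = None
    metrics: Optional[BreathMetrics] = None
    events: list[MovementEvent] = field(default_factory=list)
    firings: list[RuleFiring] = field(default_factory=list)
    timeline: Optional[ScoreTimeline] = None
    timings_s: dict[str, float] = field(default_factory=dict)


def _rr_per_second(metrics: BreathMetrics, duration_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Expand the windowed RR series to one value per session second.

    Each 60 s window's RR is attributed to its start second; seconds past
    the last window start carry the final window's value, so scoring covers
    the whole session.
    """
    seconds = np.arange(int(np.floor(duration_s)) + 1, dtype=float)
    if len(metrics.rr_values) == 0:
        return seconds, np.full_like(seconds, np.nan)
    rr = np.interp(seconds, metrics.rr_times, metrics.rr_values)
    return seconds, rr


def run_pipeline(
    config: PipelineConfig | None = None,
    frames: Optional[Iterable[np.ndarray]] = None,
    person_backend: Optional[Callable] = None,
    keypoint_backend: Optional[Callable] = None,
    flow_backend: Optional[Callable] = None,
    tracks: Optional[TrackSet] = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the pipeline from frames or from an existing track set.

    Provide either ``frames`` together with the three backends, or a
    ``tracks`` object / CSV-loaded TrackSet to start from the breathing
    stage.  When ``out_dir`` is given, tracks CSV, breathing JSON, events
    CSV and score CSV (+ JSON summary) are written there.
    """
    cfg = config or PipelineConfig()
    result = PipelineResult()

    if tracks is None:
        if frames is None:
            raise ValueError("provide frames (with backends) or a TrackSet")
        if keypoint_backend is None or flow_backend is None:
            raise ValueError("frames input requires keypoint and flow backends")
        if person_backend is None:
            person_backend = lambda frame, idx: True  # noqa: E731
        t0 = time.perf_counter()
        tracks = track_session(frames, person_backend, keypoint_backend, flow_backend, cfg.tracking())
        result.timings_s["track"] = time.perf_counter() - t0
        log.info("track: %d frames, status=%s", len(tracks), tracks.status)
    result.tracks = tracks

    t0 = time.perf_counter()
    thorax = tracks.series("thorax", cfg.breathing_axis)
    metrics = analyze_breathing(thorax, cfg.breathing(), fs=tracks.fs)
    result.metrics = metrics
    result.timings_s["breathe"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    events = analyze_movement(tracks, cfg.movement())
    result.events = events
    result.timings_s["move"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    duration = tracks.duration_s
    dur = max(duration, 1.0)
    intro_end = min(cfg.intro_end_s, dur)
    schedule = PhaseSchedule(
        duration_s=dur,
        intro_end_s=intro_end,
        conclusive_start_s=max(intro_end, dur - cfg.conclusive_s),
    )
    rr_t, rr_v = _rr_per_second(metrics, duration)
    ok = np.isfinite(rr_v)
    firings = derive_rule_events(
        rr_t[ok], rr_v[ok], events, schedule, low_rr=cfg.low_rr, sustain_s=cfg.sustain_s
    )
    timeline = score_session(
        firings, RuleTable(), schedule, baseline=cfg.baseline, bounds=(cfg.score_min, cfg.score_max)
    )
    result.firings = firings
    result.timeline = timeline
    result.timings_s["score"] = time.perf_counter() - t0

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        echo = config.to_dict() if config else PipelineConfig().to_dict()
        rio.write_tracks(tracks, out_dir / "tracks.csv", params=echo)
        rio.write_metrics(metrics, out_dir / "breathing.json", params={"config": echo})
        rio.write_events(events, out_dir / "events.csv")
        per_phase: dict[str, float] = {}
        for t_ann, anns in timeline.annotations.items():
            from .scoring import phase_of

            ph = phase_of(float(t_ann), schedule)
            per_phase[ph] = per_phase.get(ph, 0.0) + sum(d for _, d in anns)
        rio.write_score(timeline, out_dir / "score.csv", summary={"per_phase_deltas": per_phase, "config": echo})
    return result
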