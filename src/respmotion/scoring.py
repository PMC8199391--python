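"""Phase-weighted session scoring from breathing and movement observations.

A session is split into an *introduction* phase (first 2 min), a *conclusive*
phase (last 2 min by default) and the *main* phase between them.  Seven
rules fire on the per-second RR series and the movement events, each
carrying a phase-dependent score delta:

====================================================  ======  =====  ==========
rule                                                  intro   main   conclusive
====================================================  ======  =====  ==========
breath: first decrease below 10 breaths/min            +20      0        0
breath: increase above 10 breaths/min                   -5     -15      -10
breath: staying lower than 10 breaths/min              +10     +10      +10
head movements                                          -3      -5        0
changing the position of the lower body                 -3     -10       -5
changing the position of the hands                      -3      -5        0
body movement                                           -3      -7       -2
====================================================  ======  =====  ==========

The score starts at a configurable baseline (default 50), accumulates the
deltas of every firing, and is clamped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .movement import MovementEvent

__all__ = [
    "PhaseSchedule",
    "RuleTable",
    "RuleFiring",
    "ScoreTimeline",
    "phase_of",
    "derive_rule_events",
    "score_session",
]

PHASES = ("introduction", "main", "conclusive")

RULES = (
    "breath_first_decrease",
    "breath_increase",
    "breath_staying_low",
    "head_movement",
    "lower_body",
    "hands",
    "body_movement",
)

#: movement-event part -> scoring rule
_PART_RULE = {
    "head": "head_movement",
    "left_knee": "lower_body",
    "right_knee": "lower_body",
    "left_wrist": "hands",
    "right_wrist": "hands",
    "left_elbow": "hands",
    "right_elbow": "hands",
    "thorax": "body_movement",
    "stomach": "body_movement",
    "left_shoulder": "body_movement",
    "right_shoulder": "body_movement",
}

_DEFAULT_DELTAS: dict[str, tuple[int, int, int]] = {
    "breath_first_decrease": (20, 0, 0),
    "breath_increase": (-5, -15, -10),
    "breath_staying_low": (10, 10, 10),
    "head_movement": (-3, -5, 0),
    "lower_body": (-3, -10, -5),
    "hands": (-3, -5, 0),
    "body_movement": (-3, -7, -2),
}


@dataclass
class PhaseSchedule:
    """Session phase boundaries in seconds.

    ``intro_end_s`` defaults to 120 s and ``conclusive_start_s`` to
    ``duration - 120``; for sessions too short to hold both they are pulled
    in so the invariant 0 < intro_end <= conclusive_start <= duration holds.
    """

    duration_s: float
    intro_end_s: float = 120.0
    conclusive_start_s: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        self.intro_end_s = min(self.intro_end_s, self.duration_s)
        if self.conclusive_start_s is None:
            self.conclusive_start_s = max(self.intro_end_s, self.duration_s - 120.0)
        if not (0 < self.intro_end_s <= self.conclusive_start_s <= self.duration_s):
            raise ValueError("phase boundaries out of order")


@dataclass
class RuleTable:
    """Score delta per rule per phase; defaults are the standard table above."""

    deltas: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_DELTAS)
    )

    def __post_init__(self) -> None:
        unknown = set(self.deltas) - set(RULES)
        if unknown:
            raise ValueError(f"unknown rules: {sorted(unknown)}")
        for rule in RULES:
            self.deltas.setdefault(rule, _DEFAULT_DELTAS[rule])

    def delta(self, rule: str, phase: str) -> int:
        return self.deltas[rule][PHASES.index(phase)]


@dataclass(frozen=True)
class RuleFiring:
    """A rule firing at a given second of the session."""

    t: float
    rule: str


@dataclass
class ScoreTimeline:
    """Per-second score with the rule annotations that changed it."""

    time_s: np.ndarray
    score: np.ndarray
    annotations: dict[float, list[tuple[str, int]]]

    @property
    def final_score(self) -> float:
        return float(self.score[-1])


def phase_of(t: float, schedule: PhaseSchedule) -> str:
    """Phase containing time ``t``: introduction, main or conclusive."""
    if not (0 <= t <= schedule.duration_s):
        raise ValueError(f"t={t} outside session [0, {schedule.duration_s}]")
    if t < schedule.intro_end_s:
        return "introduction"
    if t >= schedule.conclusive_start_s:
        return "conclusive"
    return "main"


def derive_rule_events(
    rr_times: Sequence[float],
    rr_values: Sequence[float],
    movement_events: Sequence[MovementEvent],
    schedule: PhaseSchedule,
    low_rr: float = 10.0,
    sustain_s: float = 60.0,
) -> list[RuleFiring]:
    """Turn the RR series and movement events into timestamped rule firings.

    Breath rules on the per-second RR series: the *first decrease* below
    ``low_rr`` fires once, at the first second where RR is below it (either
    from the start or on a downward crossing); an *increase* fires at every
    upward crossing back to ``low_rr`` or above; *staying low* fires once per
    completed ``sustain_s`` of uninterrupted RR below ``low_rr``.  Movement
    events map to the four part-group rules, collapsed to at most one firing
    per rule per second.
    """
    firings: list[RuleFiring] = []
    rr_t = np.asarray(rr_times, dtype=float)
    rr = np.asarray(rr_values, dtype=float)

    fired_first = False
    run_start: float | None = None
    fired_sustains = 0
    for t, v in zip(rr_t, rr):
        low = v < low_rr
        if low:
            if not fired_first:
                firings.append(RuleFiring(t, "breath_first_decrease"))
                fired_first = True
            if run_start is None:
                run_start = t
                fired_sustains = 0
            completed = int((t - run_start + 1.0) // sustain_s)
            if completed > fired_sustains:
                firings.append(RuleFiring(t, "breath_staying_low"))
                fired_sustains = completed
        else:
            if run_start is not None and v >= low_rr:
                firings.append(RuleFiring(t, "breath_increase"))
            run_start = None

    seen: set[tuple[str, int]] = set()
    for ev in movement_events:
        rule = _PART_RULE[ev.part]
        key = (rule, int(ev.t_start))
        if key in seen:
            continue
        seen.add(key)
        firings.append(RuleFiring(float(int(ev.t_start)), rule))

    firings.sort(key=lambda f: (f.t, RULES.index(f.rule)))
    return firings


def score_session(
    firings: Sequence[RuleFiring],
    rules: RuleTable | None = None,
    schedule: PhaseSchedule | None = None,
    baseline: float = 50.0,
    bounds: tuple[float, float] = (0.0, 100.0),
) -> ScoreTimeline:
    """Accumulate rule firings into the per-second score timeline.

    ``score(t)`` is the baseline plus the sum of the phase-weighted deltas of
    every firing at or before ``t``, clamped to ``bounds`` after each firing.
    """
    if schedule is None:
        duration = max((f.t for f in firings), default=0.0) + 1.0
        schedule = PhaseSchedule(duration_s=max(duration, 1.0))
    table = rules or RuleTable()
    n = int(np.floor(schedule.duration_s)) + 1
    times = np.arange(n, dtype=float)
    score = np.empty(n)
    annotations: dict[float, list[tuple[str, int]]] = {}

    by_second: dict[int, list[RuleFiring]] = {}
    for f in firings:
        if not (0 <= f.t <= schedule.duration_s):
            raise ValueError(f"firing at t={f.t} outside session")
        by_second.setdefault(int(f.t), []).append(f)

    current = baseline
    for i in range(n):
        for f in by_second.get(i, ()):  # apply this second's firings
            delta = table.delta(f.rule, phase_of(f.t, schedule))
            current = float(np.clip(current + delta, *bounds))
            annotations.setdefault(times[i], []).append((f.rule, delta))
        score[i] = current
    return ScoreTimeline(time_s=times, score=score, annotations=annotations)
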