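"""Matplotlib renderings of the stage outputs (breathing panels, score curve)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .breathing import BreathMetrics, BreathSignal
from .scoring import ScoreTimeline

__all__ = ["plot_breathing", "plot_score"]


def plot_breathing(raw: BreathSignal, clean: BreathSignal, metrics: BreathMetrics):
    """Three panels: raw thorax signal; cleaned signal with extrema; RR series."""
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=False)
    axes[0].plot(raw.times, raw.samples, lw=0.8)
    axes[0].set_ylabel("raw (SWU)")
    axes[0].set_title("thorax motion")

    axes[1].plot(clean.times, clean.samples, lw=0.8)
    ex = metrics.extrema
    if ex is not None and ex.n_peaks:
        axes[1].plot(ex.peak_times, ex.peak_values, "r.", label="peaks")
    if ex is not None and ex.n_troughs:
        axes[1].plot(ex.trough_times, ex.trough_values, "g.", label="troughs")
    axes[1].set_ylabel("cleaned (SWU)")
    axes[1].legend(loc="upper right", fontsize=8)

    axes[2].plot(metrics.rr_times, metrics.rr_values, lw=1.2)
    axes[2].set_ylabel("RR (breaths/min)")
    axes[2].set_xlabel("time (s)")
    flags = f"rhythmic={metrics.rhythmic}  stable={metrics.stable}"
    axes[2].set_title(flags, fontsize=9)
    fig.tight_layout()
    return fig


def plot_score(timeline: ScoreTimeline):
    """Score-versus-time curve with rule annotations marked."""
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(timeline.time_s, timeline.score, lw=1.5)
    for t, anns in sorted(timeline.annotations.items()):
        i = int(np.searchsorted(timeline.time_s, t))
        y = timeline.score[min(i, len(timeline.score) - 1)]
        ax.plot([t], [y], "ko", ms=3)
        ax.annotate(
            "\n".join(rule for rule, _ in anns), (t, y),
            textcoords="offset points", xytext=(0, 8), fontsize=6, rotation=45,
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("score")
    ax.set_ylim(-2, 102)
    fig.tight_layout()
    return fig
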