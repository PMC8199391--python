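"""Score a full session from its breathing and movement observations.

A 10-minute session breathing slowly at 8 breaths/min with a single head
movement at t = 200 s.  The rule table rewards the first drop below 10
breaths/min (+20 in the introduction phase) and every sustained-low minute
(+10), and penalises the head movement (-5 in the main phase); the score
starts at 50 and is clamped to [0, 100].
"""

import respmotion as rm
from respmotion.pipeline import run_pipeline

script = rm.MotionScript(
    duration_s=600.0,
    breathing_amplitude_mm=2.0,
    breathing_rr_bpm=8.0,
    shifts=[rm.Shift("head", "x", 200.0, 1.0, -30.0)],
)
tracks, _, _ = rm.synth_track_set(script)
result = run_pipeline(tracks=tracks)

print(f"{len(result.firings)} rule firings:")
for t, anns in sorted(result.timeline.annotations.items()):
    for rule, delta in anns:
        print(f"  t={t:5.0f} s  {rule:22s} {delta:+d}")
print(f"final score: {result.timeline.final_score:.0f} / 100")
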