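"""Published benchmark values for the respiratory-rate estimator.

The annotated evaluation set behind the published accuracy figures consists
of eight videos of different people with ground-truth respiratory rates; the
videos themselves are not redistributable, but the ground-truth / estimated
RR pairs are printed and reproduce the reported mean absolute error of
1.75 breaths per minute.
"""

from __future__ import annotations

#: (ground truth BPM, estimated BPM) per benchmark video, in published order
REFERENCE_RR_PAIRS: tuple[tuple[float, float], ...] = (
    (18, 16),
    (34, 31),
    (10, 9),
    (24, 22),
    (13, 12),
    (8, 7),
    (9, 8),
    (35, 32),
)
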