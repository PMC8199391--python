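# Methods

This note describes the models and procedures implemented in `respmotion`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Problem setting

A monocular camera watches a seated, mostly-still person (the motivating
application is meditation practice).  From the video alone the package
estimates (1) per-keypoint body-motion tracks, (2) respiratory rate and two
qualitative breathing descriptors — rhythmicity and stability — from the
chest motion, (3) discrete movement events with direction per body part, and
(4) a rule-based session score.  Eleven keypoints are tracked: head, thorax,
stomach, shoulders, elbows, wrists and knees.  All processing runs at a
fixed 5 fps working rate; higher-rate input is resampled by nearest-frame
selection.

## Motion tracking

**Displacement model.**  Dense optical flow between a *base frame* and the
current frame gives per-pixel displacement vectors.  A keypoint's
displacement is the Gaussian-weighted mean of the flow around the keypoint:

    w(x, y) ∝ exp(−((x−μx)² + (y−μy)²) / 2δ²),   δ = 0.10 × shoulder width

The weighted *mean* (weights normalised to 1) rather than a raw weighted
sum is used so that a uniform flow maps to itself.  Weights are truncated
at 3δ (>99% of the Gaussian mass) and renormalised, bounding the cost and
the influence of unrelated background.  Displacements are divided by the
shoulder width in pixels (shoulder-width units, SWU), making tracks
comparable across resolutions, distances and body sizes.

**Tracking loop.**  While no person is visible, frames are probed every
5 s.  Once keypoints are estimated, the current frame becomes the base
frame.  When any keypoint's displacement relative to the base frame exceeds
15 px (Euclidean norm), the current frame becomes the new base frame and
the displacement is folded into per-keypoint *correction vectors*, so
absolute displacement from session start is `correction + current`.  When
any absolute displacement since the last keypoint estimation exceeds 20% of
the shoulder width, or every 30 s regardless, keypoints are re-estimated
and the track is re-anchored to `new position − first position`, resetting
accumulated flow drift (the keypoint estimator is treated as the trusted
reference).  If both a rebase and a re-estimation trigger on the same
frame, re-estimation wins, since it subsumes the rebase.  If re-estimation
finds nobody, the tracker falls back to probing and the gap is marked
invalid (NaN samples, excluded from all downstream analysis).  The shoulder
width used for normalisation is the one measured at the most recent
keypoint estimation.

**Backends.**  Person detection, keypoint estimation and dense flow are
injectable callables.  The default flow backend is classical iterative
Lucas-Kanade (`skimage.registration.optical_flow_ilk`, radius 7, 3 warps),
which resolves the sub-pixel chest motion on textured scenes to a few
hundredths of a pixel; any learned estimator with the same
`(base, frame) → flow` contract can be substituted.  Keypoint estimation is
deliberately not bundled (no model downloads): a fixture backend replays
known keypoints, and adapters to off-the-shelf pose estimators can be
plugged in for real footage.  Thresholds (15 px, 20%) compare vector norms;
per-axis comparison is a config choice away but not the default.

## Breathing analysis

**Cleaning.**  The thorax vertical track is linearly detrended, then
band-passed with a zero-phase cascade: 2nd-order Butterworth high-pass at
0.05 Hz and 5th-order Butterworth low-pass at 2 Hz.  The stated high-cut of
3 Hz would exceed the 2.5 Hz Nyquist limit at the 5 fps working rate, so
2 Hz is the default and 3 Hz remains selectable for higher sampling rates.
Zero-phase (forward-backward) filtering keeps extrema where they are, which
matters because breath times feed the stability flag.  Two numerical
details: filtering uses reflective padding of up to 300 samples, because
the 0.05 Hz high-pass has edge-transient time scales (~20 s) far beyond the
default pad, and the residual DC left by finite-signal edges is subtracted
so the cleaned signal is exactly zero-mean.  Re-cleaning a cleaned
respiration-band signal changes it by well under 1% RMS; exact idempotence
on broadband noise is unattainable with a 2 Hz band edge at fs = 5 because
the half-power point sits inside the noise band.

**Extrema.**  Peaks and troughs come from prominence- and spacing-gated
local extremum detection, with alternation enforced by keeping the more
extreme of same-type neighbours.  The minimum spacing is 60/180 s (nothing
breathes faster than 180 breaths/min).  The prominence threshold is
1.0 × the cleaned signal's standard deviation: a genuine breath in a
near-sinusoidal signal has prominence ≈ 2√2 × std, while residual in-band
noise ripple rarely reaches 1 × std, so this separates the two cleanly (a
much smaller fraction lets noise ripple masquerade as breaths and
systematically inflates the count).

**Respiratory rate.**  RR is the larger of the peak count and the trough
count in a 60 s window (300 frames), slid 1 s (5 frames) at a time; taking
the maximum makes the estimate robust to one missing extremum at a window
edge.  Sessions shorter than 60 s yield a single count scaled by
60/duration, and the rhythmicity/stability flags are reported undefined —
too few breaths to judge.

**Rhythmicity and stability.**  Per breath, the peak-to-trough amplitude is
the peak value minus the preceding trough value.  Breathing is *rhythmic*
when every amplitude lies in [median − T₁, median + T₁], and *stable* when
every wavelength (peak-to-peak interval, and separately trough-to-trough)
deviates from its family median by less than T₂.  The tolerances default to
fractions of the medians (T₁ = 0.5 × median amplitude, T₂ = 0.5 × median
wavelength, the latter pooled across both families so one number governs
both); fractional defaults make the flags invariant to signal scale, and
absolute values can be configured instead.  Both flags are session-level,
computed over all breaths, not per window.

## Movement classification

Each of the 22 series is scanned with a 6-frame (1.2 s) window slid
5 frames (1 s) at a time — long enough to catch fast movements, short
enough to overlap.  Per window: (1) the trend component is extracted — for
the default 6-sample window, which is too short for any seasonal structure,
the trend is a 3-point moving average with shrinking edges; longer windows
with a known period use a classical centred-moving-average decomposition;
(2) a least-squares line is fitted to the trend and its slope sign gives
the direction: negative → left/up, positive → right/down on the
horizontal/vertical axis respectively (image y grows downward; the exposed
up/down semantics are physical); (3) windows whose raw net displacement
|last − first| is below 9 mm emit nothing — the micro-movement gate that
keeps breathing-scale motion out of the event stream.  Conversion from SWU
to millimetres uses a configurable physical shoulder width, default 0.40 m,
so 1 SWU = 400 mm.  Windows touching person-absent samples are skipped.

## Session scoring

A session splits into introduction (first 2 min), conclusive (last 2 min
by default; the boundary is configurable) and main phases.  Seven rules
fire on the per-second RR series and the movement events with
phase-dependent deltas (see the table in the scoring module).  Breath
rules: the *first* drop below 10 breaths/min fires once (including a
session that starts below 10); each upward crossing back to ≥10 fires a
penalty; each completed minute of uninterrupted sub-10 breathing fires a
bonus (the firing cadence is a design choice — the rule set only says
"staying lower").  Movement events map to four part groups: head → head
rule, knees → lower body, wrists/elbows → hands, thorax/stomach/shoulders →
body movement, collapsed to at most one firing per rule per second.  The
score starts at a baseline of 50 and is clamped to [0, 100] after each
delta; baseline and bounds are configurable (the published score curves
constrain neither).  Breath and movement rules may fire in the same second
independently.

## Synthetic data

The generator exists so every stage is testable offline with known truth.

* **Breath signals**: `amplitude · mod(t) · sin(2π ∫ RR(t)/60 dt) + drift·t
  + noise`, with RR constant, linearly swept or piecewise linear; true peak
  times and per-window true RR are derived from the phase function
  analytically.  Defaults: amplitude 1 SWU, fs 5 Hz, no drift or noise;
  the recovery studies use drift 0.5 SWU/min and noise sd 0.2 — a harsh
  setting relative to clean seated footage.
* **Track sets**: noiseless SWU trajectories from scripted keypoint shifts
  (smoothstep ramps specified in millimetres) plus a breathing oscillation
  (default 2 mm at 12 breaths/min) on thorax and stomach, with ground-truth
  movement labels computed with the same window geometry and 9 mm gate as
  the classifier.
* **Toy videos**: high-contrast noise-textured patches centred on each
  keypoint over a static textured background, sampled with bicubic
  interpolation so sub-pixel motion registers; defaults 640×480 with a
  100 px shoulder width and 0.40 m physical shoulder (1 px = 4 mm).  Flow
  estimators need image gradient, hence the deliberate texture.

What the toy videos do *not* emulate: photometric noise, illumination
change, occlusion, clothing deformation, limb rotation and perspective —
so passing the end-to-end tests demonstrates the correctness of the
displacement/rebasing machinery and scale handling, not robustness of any
particular flow estimator on real footage.  Real-footage robustness rests
on the choice of flow/keypoint backends, which are pluggable for exactly
that reason.

## Problem sizes used in the checks

The shipped verification suite runs entirely on synthetic data: RR recovery
uses 90 s signals at six true rates (6–30 BPM) × 50 seeds; movement
detection uses 20 random 60 s scripted sessions; the resolution-invariance
check renders one 12 s script at 320×240 (50 px shoulder) and at double
resolution and compares tracked thorax amplitudes; the scoring trace uses a
600 s session.  The benchmark MAE is computed over the eight published
ground-truth/estimated RR pairs.

## Known limitations

* Single person, roughly frontal, seated; no camera motion model.
* Keypoint estimation is not bundled; real-video use requires wiring a pose
  estimator into the backend contract.
* The 3 Hz high-cut option is only meaningful above 6 fps sampling.
* The rhythmicity/stability tolerances are heuristics around the median;
  they are reported alongside the flags so users can recalibrate.
* Score baseline, bounds and the sustained-low firing cadence are package
  conventions where the underlying rule set is silent.
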