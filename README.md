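# respmotion

Contactless respiration and body-movement analysis of seated-person video —
no wearables, just a camera.  The motivating use case is evaluating
meditation practice: how calmly and regularly someone breathes, and how
still they sit.

From a monocular video (internally resampled to 5 fps) the pipeline
computes:

1. **Keypoint displacement tracks** — dense optical flow, averaged with a
   Gaussian weight (σ = 10% of the shoulder width) around each of 11 body
   keypoints, with base-frame rebasing at 15 px and periodic keypoint
   re-estimation; output in shoulder-width units (SWU), invariant to
   resolution and camera distance.
2. **Breathing metrics** — the thorax track is detrended and band-passed
   (0.05–2 Hz zero-phase Butterworth), breaths are counted as signal peaks
   in a sliding 60 s window: respiratory rate RR = max(#peaks, #troughs)
   breaths/min, plus *rhythmicity* (all peak-to-trough amplitudes within
   ±T₁ of their median) and *stability* (all breath intervals within T₂ of
   their median) flags.
3. **Movement events** — per body part and axis, a 1.2 s window slid every
   second is trend-decomposed and the slope sign of the fitted line gives
   the direction (left/right/up/down); net motion under 9 mm is ignored.
4. **Session score** — seven phase-weighted rules (slow breathing rewarded,
   movement penalised; phases: first 2 min / main / last 2 min) accumulate
   onto a 0–100 score timeline.

Person detection, keypoint estimation and optical flow are injectable
backends; the default flow is classical dense iterative Lucas-Kanade, and a
fixture keypoint backend replays known keypoints so the whole pipeline runs
offline.  A synthetic module generates ground-truthed breath signals,
keypoint scripts and renderable toy videos for testing every stage.

## Worked example

`examples/video_tracking.py` renders a 12 s toy video whose thorax
oscillates vertically by 12 mm at 12 breaths/min, then tracks it with the
default dense-flow backend:

```
frames tracked      : 60/60 valid at 5 fps
thorax amplitude    : estimated 0.0301 SWU, scripted 0.0300 SWU (100.3% recovered)
static head x spread: 0.00000 SWU (should be ~0)
```

The recovered amplitude matches the scripted truth to 0.3% — 12 mm on a
400 mm shoulder is 0.03 SWU — and keypoints that were scripted static stay
static.  `examples/breathing_analysis.py` runs the breathing stage on a
noisy, drifting synthetic signal:

```
true RR          : 12.0 breaths/min
estimated RR     : median 12.0, range 12-13 over 61 sliding 60 s windows
breaths detected : 24 peaks / 24 troughs (true peaks: 24)
rhythmic=True  stable=True (amplitude tolerance 1.0429 SWU, interval tolerance 2.50 s)
```

and `examples/session_score.py` scores a 10-minute session breathing at 8
breaths/min with one head movement at t = 200 s: +20 for the first drop
below 10 breaths/min (introduction phase), +10 per sustained-low minute,
−5 for the head movement (main phase), final score 100/100.

## Command line

Each stage reads and writes plain-text files, so stages run independently:

```
respmotion synth    --script script.json --out-dir session/
respmotion track    --input session/frames --keypoints session/keypoints.json --out tracks.csv
respmotion breathe  --input tracks.csv --out breathing.json
respmotion move     --input tracks.csv --out events.csv
respmotion score    --metrics breathing.json --events events.csv --duration 600 --out score.csv
respmotion run      --input tracks.csv --out-dir results/
respmotion evaluate                      # MAE over the built-in benchmark pairs
```

`respmotion evaluate` prints the per-video report for the eight published
ground-truth/estimated RR pairs and their mean absolute error, `MAE = 1.75
BPM`.

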