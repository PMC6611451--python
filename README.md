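# fasctrack

Automatic tracking of muscle-fascicle architecture in B-mode ultrasound
video.

During a contraction, the fascicles of a pennate muscle such as the
medial gastrocnemius shorten and rotate between the two aponeuroses that
bound the muscle belly.  Quantifying that motion — fascicle length
`L` and pennation angle `θ` per video frame — normally requires tedious
manual digitisation of a handful of frames.  `fasctrack` automates it:
the user draws three line segments in the first frame (superficial
aponeurosis, deep aponeurosis, one candidate fascicle) and the tracker
follows each structure through the rest of the video.

**Who it is for:** biomechanics and muscle-physiology researchers who
record B-mode ultrasound of pennate muscle during dynamometer or gait
protocols and want frame-by-frame architecture measurements plus the
reliability statistics used to validate them.

## Method

Per structure and per frame:

1. an oriented rectangular ROI is built along the drawn segment (the
   fascicle ROI keeps the middle 90% to avoid touching the aponeuroses);
   the deep-aponeurosis ROI is contrast-rebalanced;
2. 100 points are seeded evenly through the ROI;
3. points are propagated by pyramidal Kanade–Lucas–Tomasi optical flow
   (3 mm block, 4 pyramid levels, ≤ 30 iterations);
4. a point is discarded if the tracker fails, if it leaves the frame, or
   if its forward–backward re-track lands more than 2 mm from its start;
   losing more than 10% of the prior frame's points triggers reseeding
   with 100 fresh points, and losing 100% aborts with an error;
5. the surviving cloud is refit with a total-least-squares line.

With the three fitted lines, per frame:

```
L  =  ‖ P_sup − P_deep ‖          P_i = fascicle ∩ aponeurosis i
θ  =  ∠(fascicle, deep aponeurosis)   (acute, degrees)
```

Intersections are taken on the infinite lines, so attachments outside
the field of view are obtained by extrapolation.

The reliability battery implements ICC(A,1) (two-way ANOVA,
single-measure absolute agreement), the waveform coefficient of multiple
correlation (CMC), RMSE, Bland–Altman bias and 95% limits of agreement
with a within-subject coefficient of variation (a-priori threshold 10%),
initial-offset correction, and the correlation-strength classes
poor / moderate / strong / very strong at 0.36 / 0.67 / 0.90.

Because no imaging data ships with the package, a synthetic speckle
phantom renders a pennate-muscle scene (two bright aponeurosis bands,
oblique fascicle streaks, multiplicative speckle and additive noise)
with prescribed `L(t)` and `θ(t)` trajectories and exact per-frame
ground truth, used throughout the test suite.

## Worked example

Render a phantom contraction, track it, and inspect the measurements:

```sh
fasctrack phantom --n-frames 120 --seed 1 --out video.tif \
    --truth truth.csv --annotation init.json
fasctrack track --video video.tif --annotation init.json \
    --out measured.csv --overlay overlay.tif
```

```
wrote 120 measurements to measured.csv
```

`measured.csv` holds one row per frame (length, pennation, extrapolation
flags, surviving point counts).  On this phantom — fascicle shortening
60 → 40 mm while pennation rises 20° → 35° — the tracked series differs
from the rendered truth by an RMSE of 2.26 mm in length and 1.27° in
pennation, with waveform CMCs of 0.95 (length) and 0.97 (pennation):
the tracker recovers the prescribed contraction closely, with a small
late-contraction orientation lag that is characteristic of cloud-fit
fascicle trackers.

The study-design bookkeeping used in reliability work is available from
the CLI:

```sh
fasctrack plan --subjects 5 --conditions 5 --trials 3 \
    --examiners 3 --days 3 --frames 6
```

```
videos: 75
tracked videos: 675
manual measurements: 4050
```

And the classic mis-track arithmetic — a poorly initialised track that
measured 57.8 mm / 32° against a well-tracked 50.6 mm / 49° — comes out
as a 12.5% length over-estimate and a 53.1% pennation under-estimate:

```python
>>> from fasctrack import percent_difference
>>> round(abs(percent_difference(50.6, 57.8)), 1)
12.5
>>> round(abs(percent_difference(49.0, 32.0)), 1)
53.1
```

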