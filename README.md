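# sociotrack

Automated scoring of the **two-chamber social preference assay** in mice.

In this assay a subject mouse explores a rectangular arena (37 × 22 cm)
with two small triangular chambers in opposite corners, each holding a
stimulus — a conspecific, an object, a familiar or a novel animal.
Because the stimulus is only reachable through the chamber's front wall,
*investigation* is well defined: contact between the subject's body (or
head) and that wall.  This makes the assay a direct-measurement
alternative to the three-chamber sociability test, which only scores
which compartment the subject stands in.

`sociotrack` takes a top-down grayscale video plus an arena-geometry
config and produces per-frame contact labels, investigation bouts,
inter-bout intervals, stimulus-to-stimulus transitions, and all the
session- and group-level statistics a social preference (SP) or social
novelty preference (SNP) experiment needs.  A synthetic-data module
renders ground-truthed videos of a moving ellipse "mouse" (with optional
tail and recording cable), so the entire pipeline is testable without
animal data.

## What it computes

**Tracking** (three algorithm variants, all dark-subject-on-light-floor
thresholding):

* `body` — largest dark connected component inside the arena; contact
  scored between the body boundary and either stimulus-zone segment
  (within `contact_distance_px`, closed inequality).
* `head` — dual-threshold head-direction estimation: a moment ellipse is
  fitted to the low-threshold mask (which excludes the brighter tail of
  C57BL/6 mice); its major-axis endpoints are the nose/rump candidates,
  and the high-threshold mask (which includes the tail) disambiguates
  them.  Contact is scored for the head point only, rejecting events
  where just the flank or rump brushes a zone.
* `wired_body` — body tracking with cable suppression (morphological
  opening removes thin tethers such as recording cables or optical
  fibers before contact is scored).

**Event extraction.**  Raw per-frame labels are gap-corrected: any
interruption of contact with a stimulus shorter than 0.5 s (strictly;
15 frames at 30 fps does *not* merge) is ignored rather than breaking
the bout, unless the subject visited the other stimulus in between.
From the corrected series come bouts, same-stimulus intervals (> 0.5 s),
and transitions (start of a bout on a different stimulus than the
previous bout).

**Metrics.**  Investigation time in 20-s bins; the preference index

```
RDI = (t_stim1 − t_stim2) / (t_stim1 + t_stim2)
```

(relative duration of investigation; signed by default so the sign
carries the direction of preference, with an unsigned `|·|` option);
an interval-based RDI over prolonged (> 20 s) intervals; bout-duration
histograms (short ≤ 6 s … long > 19 s); interval-duration histograms
(< 10 s / 10–20 s / > 20 s); per-bin transition counts; the
exploration-phase (first 2 min, many transitions, short bouts) vs
interaction-phase (rest, few transitions, long bouts) split; open-field
distance traveled and center/periphery time ratio; group pooling with
mean ± SEM and Pearson correlations across subjects.

## Worked example

Simulate one subject, render it to video, and analyze it:

```sh
sociotrack simulate --n 1 --seed 42 --out sim --render
sociotrack analyze sim/subject000.avi --config sim/arena.yaml \
    --session demo --test-type SP --out analysis
```

which prints

```
session demo: stim1 159.6 s, stim2 28.6 s, RDI 0.696, 17 transitions
```

i.e. over the 5-min session this subject spent 159.6 s investigating
stimulus 1 and 28.6 s investigating stimulus 2 — a strong preference
(RDI = +0.696 of the maximum +1) — and switched between stimuli 17
times.  `analysis/` holds the event tables; the first bouts:

```
stimulus,start_s,end_s,duration_s
stim1,0.9,12.833333333333334,11.933333333333334
stim2,16.133333333333333,18.0,1.8666666666666671
stim2,21.266666666666666,21.833333333333332,0.5666666666666664
stim1,23.2,25.566666666666666,2.366666666666667
```

Batches of real videos go through `sociotrack batch manifest.yaml`,
which analyzes every listed session and pools each group (mean ± SEM
curves, transition–RDI correlation).  Exported tables are tidy CSV,
ready for any stats package.

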