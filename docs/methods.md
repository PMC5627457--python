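# Methods

This note documents the models, conventions and numerical choices behind
`sociotrack`, and what the synthetic-data validation does and does not
demonstrate.

## Coordinate and time conventions

Pixel coordinates are 0-based, x rightward, y downward (image
convention); all geometry in the config file is in pixels.  Calibrated
outputs use cm via the scalar `px_per_cm`, origin at the arena-rectangle
corner.  All times are frame counts divided by `frame_rate` — no
sub-frame interpolation anywhere, so every reported duration is an exact
multiple of one frame.

## Arena geometry

The two stimulus zones are line segments (the chambers' front walls)
with a contact buffer, not areas: the chamber wall is a plane seen
edge-on from above, so a segment plus `contact_distance_px` captures it
without requiring the user to trace a polygon.  The contact inequality
is **closed** (`d ≤ contact_distance_px`); the default buffer is 2 px at
the 320×240 fixture scale and must be calibrated per setup — no
principled physical value exists because it folds together wall
thickness, lens distortion and segmentation bias.  If both zones qualify
on one frame the nearer wins; an exact tie scores nothing (a tie is
geometrically degenerate and scoring either side would be arbitrary).

Compartments default to the two halves of the arena split by the
perpendicular bisector of the line joining the zone centers, overridable
by explicit polygons.  Validation requires the zones disjoint by more
than twice the contact buffer (otherwise single-stimulus labeling is
ill-defined) and the compartments to partition the arena.

## Tracking

Segmentation is plain thresholding — subject pixels darker than the
threshold, restricted to the arena rectangle — followed by connected
components; the largest component of at least `min_blob_area_px` is the
subject.  Area ties break by distance to the previous centroid, then by
label index.  There is no background model: the assay floor is uniform
white Plexiglass and the subject is the only large dark object, which is
exactly the regime where thresholding is as good as anything and fully
auditable.

The head-direction variant fits the *moment* ellipse (equivalent
second-moment ellipse, semi-axes `2√λ` of the pixel covariance
eigenvalues) to the low-threshold mask.  Degenerate masks (< 3 pixels or
collinear) raise a fit error and invalidate the frame.  Head/tail
disambiguation priority: (1) tail evidence — the high-threshold mask
component containing the body, minus the low-threshold mask, marks the
tail (at least 3 px required), and the major-axis endpoint farther from
it is the head; (2) temporal continuity — the endpoint closer to the
previous head; (3) otherwise the head is undetermined for that frame and
contributes no contact.  For a circular mask the axis direction is
arbitrary; downstream logic tolerates this because both endpoints are
equivalent under (1) and (2).

Cable suppression is morphological opening with a disk of radius
`⌈cable_max_width_px / 2⌉` followed by keeping the largest component.
The default removal width (3 px) deliberately exceeds the nominal cable
width so that staircase rasterization of diagonal cables is still
erased; on cable-free masks the opening changes body area by well under
15%.  Invalid frames carry no state forward except the previous head
estimate; they contribute zero to all time totals.

## Event definitions

* **Gap correction** — a maximal run of non-`s` frames strictly shorter
  than 0.5 s, flanked on both sides by stimulus `s`, is relabeled `s`
  *unless it contains frames of the other stimulus*: a visit to the
  other stimulus always breaks the bout, because silently merging across
  it would delete transitions.  (A flag allows cross-stimulus merging
  for sensitivity analysis.)  At 30 fps the strict rule means a 14-frame
  gap merges and a 15-frame gap does not; at other frame rates the 0.5-s
  definition governs.  The operation is idempotent, and increasing the
  merge window can only increase per-stimulus time and decrease bout
  count.
* **Bouts** are maximal runs of one stimulus in the corrected series,
  half-open `[start, end)`.
* **Intervals** are gaps strictly longer than 0.5 s between consecutive
  bouts of the *same* stimulus.  They may span bouts of the other
  stimulus — the interval measures how long the animal stayed away from
  that particular stimulus, which is the quantity the interval-based
  preference index needs; a flag restricts to pure gaps.
* **Transitions** occur at the start of every bout whose stimulus
  differs from the preceding bout's; the session's first bout is not a
  transition.

## Metrics

The preference index RDI is implemented **signed**,
`(t₁ − t₂)/(t₁ + t₂)`, with an unsigned option.  Directional analyses
(difference from zero per group, correlations with transition counts or
with the interval-based RDI) are only meaningful with sign, and the
unsigned value is recoverable as the absolute value; the convention is
"first-listed stimulus minus second", declared at every interface.  RDI
is undefined (missing) when the subject investigated neither stimulus.

Bout-duration categories default to edges `[6, 12.5, 19]` s: "short" is
right-closed at 6 s and "long" is left-open at 19 s, so that the two
named categories are unambiguous and any ≤/≥ discrepancy affects only
measure-zero events; the two middle edges split the middle band
symmetrically and are configurable.  Interval categories default to
edges `[10, 20]` s.  Binned investigation time apportions each bout to
20-s half-open bins by exact overlap — binning, histograms and the phase
split are all exact partitions of total investigation time (asserted to
1e-9 s in tests).

Bouts are assigned to phase windows (exploration `[0, 120)` s,
interaction `[120, end)`) by their **start** time and are never split,
because bout duration is itself the analyzed quantity.  Within a phase,
"short" bouts are strictly `< 6` s, "long" strictly `> 19` s, and the
closed middle band completes the partition.

Open-field distance sums Euclidean steps between consecutive valid-frame
centroids (steps spanning invalid frames are skipped, slightly
under-estimating distance during dropouts rather than inventing paths).
The "center" region is the centered rectangle similar to the arena with
25% of its area (sides halved) — the standard open-field convention.
The center/periphery ratio is missing when periphery time is zero.
Group SEM uses the sample (n−1) standard deviation; missing values are
excluded pairwise from means and correlations.

## Synthetic data generator

The generator produces sessions at two levels.

**Behavior scripts.**  A session is an alternating renewal process of
roam and investigate segments with exponential durations, switching
parameter sets at the phase boundary (default 120 s of a 300-s session).
Defaults: exploration phase — mean bout 3 s, mean roam 4 s, switch
propensity 0.9; interaction phase — mean bout 12 s, mean roam 8 s,
propensity 0.8.  These were chosen once to reproduce the qualitative
two-phase structure of real sessions (an early high-transition,
short-bout period giving way to fewer, longer bouts, with total
transition counts around 10–14 per 5-min session) and are illustrative,
not fitted to any dataset.

Design choices that required care:

* **Preference lives in bout duration.**  `preference` p is the fraction
  of investigation drive toward stimulus 1; a bout's mean duration is
  scaled by 2p (stim 1) or 2(1−p) (stim 2), while the bout target
  re-draws *without* bias, so the cohort-mean signed RDI is 2p−1 and —
  crucially — statistically decoupled from the subject's transition
  count.  Expressing preference through target choice instead couples
  the two mechanically (every extra transition inserts minority-stimulus
  bouts), a coupling real SP data does not show; a `count_bias`
  parameter restores the target-choice channel for sensitivity analyses.
* **Compensated roam.**  The roam mean after a bout offsets the
  drive-scaled bout mean so the expected cycle length is
  target-independent; without this, sessions that randomly draw more
  short minority bouts pack in more cycles, again coupling transitions
  to RDI through the fixed session length.
* **Exploration trait.**  Each simulated subject carries a lognormal
  multiplier on its switch propensities (σ = 0.3 by default), modelling
  stable individual differences in switching tendency independent of
  preference.
* **Recognition difficulty** d (for SNP-style cohorts) pulls the
  effective preference toward 0.5, scales switch propensity by (1+d) and
  shrinks the whole bout/roam cycle by (1 − 0.7d): a subject that cannot
  tell the stimuli apart keeps checking both, briefly and often.  Across
  a cohort with heterogeneous d this produces the jointly-raised
  transition counts and lowered RDI that manifest as a negative
  transitions–RDI correlation; with d ≡ 0 the correlation stays near
  zero.
* **Antithetic cohorts.**  `simulate_cohort` generates subjects in
  antithetic pairs: both members share the duration/switch random stream
  while their target-draw uniforms are mirrored (u vs 1−u).  Each
  subject's marginal law is unchanged; pair-wise anti-correlation
  stabilizes small-cohort means, and at p = 0.5 the cohort-mean RDI
  cancels exactly for even n.  Independent subjects are available with
  `antithetic=False`.

**Rendering.**  A script is realized as a 320×240, 30-fps movie of a
dark ellipse (gray 40) on a light floor (gray 200), optional brighter
tail (gray 110 — between the two detection thresholds of 90 and 140, so
the dual-threshold head/tail logic is genuinely exercised) and an
optional thin dark cable from nose to a fixed anchor.  During
investigation the nose is placed on the target zone; during roaming a
smooth reflecting random walk keeps the whole body outside the contact
buffer of both zones.  Poses are quantized to half pixels and the
per-frame ground-truth log (centroid, nose, contact) is computed from
the *rendered* pixel geometry using shapely distances — an independent
code path from the tracker's own distance maps — so the oracle does not
share arithmetic with the system under test.

**What the synthetic validation does not show.**  The renderer has
uniform illumination, additive Gaussian noise (σ = 2 gray levels), a
rigid body, no shadows, fur, occlusion by chambers, or perspective
distortion.  Perfect or near-perfect label recovery on these videos
demonstrates the correctness of the segmentation/contact/event logic,
not robustness to real-world imaging nuisances; thresholds on real
recordings must be tuned per setup (`--preview`-style frame dumps and
the config fields exist for that).

## Problem sizes

The test suite and the acceptance script use 10–60-s rendered videos at
320×240/30 fps and simulated cohorts of 30–45 subjects with 5-min
sessions — sizes chosen so a full validation runs in a couple of minutes
on one CPU while every statistical check retains comfortable margins
(cohort means are stabilized by the antithetic pairing rather than by
brute-force subject counts).

## Video formats

Self-contained video I/O supports uncompressed 8-bit palettized AVI
(written and read by `sociotrack.video`, byte-reproducible and playable
by standard tools), multi-page TIFF stacks, and `.npy` frame stacks;
24-bit RGB AVI frames are converted by Rec. 601 luminance on read.
Compressed containers (MP4/H.264 etc.) are out of scope; transcode to
one of the supported forms first.

## Known limitations

Single-animal tracking only; no pose beyond the head/tail axis; the
head-direction variant needs the tail visible at the high threshold or
temporal continuity, and reports "undetermined" otherwise; statistics
beyond mean ± SEM and Pearson correlation (ANOVA families, post-hoc
tests) are deliberately out of scope — the exported tidy tables are
meant to be consumed by a dedicated stats package.
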