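# Methods

## Signal model and assumptions

The monitored quantity is motion on a mound top seen by a rigidly mounted
camera. The model behind the raw activity index assumes:

- the background (mound surface, surrounding grass) is static between
  consecutive frames 10 s apart, so after registration the inter-frame
  difference inside the mound mask is produced by moving ants plus sensor
  noise;
- ants are small (a few pixels), so an object appears in the difference
  image twice — at its vacated and its newly occupied position — and the
  classic partial-visibility problem of frame differencing does not arise;
- camera motion is a pure translation (wind sway of a rigid mount), so a
  single integer shift per frame suffices;
- the day (color) and night (near-infrared, actively illuminated) sensors
  produce systematically different images, so all statistics (noise scale,
  calibration polynomial) are kept per sensor mode and no difference is
  computed across a mode switch.

The raw index `A(t)` is the sum of absolute difference intensities
exceeding `3σ` over the mask. It is a measure of total motion, not an ant
count: one fast ant and two slow ones can produce similar sums. The
calibration stage absorbs this by regressing onto the operator scale
rather than interpreting `A(t)` physically.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| frame cadence Δt | 10 | s | analysis cadence of the difference method |
| noise threshold | 3σ | intensity | suppresses sensor noise in D; strict `>` so σ = 0 admits every nonzero difference (makes noiseless tests exact) |
| σ estimator | 1.4826 · median abs. difference, out-of-mask | intensity | robust (MAD) scale from motion-free territory; one σ per sensor mode |
| registration `max_shift` | 10 | px | half-width of the NCC search window; shrink for small frames (the interest-point margin is `patch_radius + max_shift + 1`) |
| registration `min_score` / `min_points` | 0.5 / 5 | – | below either, the frame keeps shift (0,0) and its activity sample is flagged rather than dropped, preserving the time base |
| manual cadence / windows | 10 min / 144 per day | – | the operator scoring schedule |
| consensus rounding | half-up | – | "rounded mean" of three 0–7 scores; half-up chosen as the tie rule |
| pairing window | 600 | s | each consensus category is paired with the median raw sum of its full 10-min slot (flagged samples excluded, dominant sensor mode decides day/night); median is robust to unflagged outliers |
| day / night fit degree | 1 / 2 | – | the night sensor's response is visibly non-linear; day is linear |
| index clamp | [0, 7] | categories | calibrated index left continuous, never rounded |
| median filter window | 10 (total, ±5) | min | temporal median over timestamps, inclusive at both ends, truncated at the series edges |
| event filter | radius ≤ 40 km, magnitude > 2.0 | – | strict inequality on magnitude; station coordinates are configuration, never built in |
| suppression threshold | 3 | baseline SD | nights whose mean index sits further than this from the reference-night mean are flagged |
| Hough bins | 180 angle bins, ρ bin = diagonal/50, min support 3 | – | discretization defaults, exposed as parameters |

## The synthetic scene generator

`moundwatch.synthesis` renders what the pipeline assumes: a static
textured background (dark mound by day at level ~90, bright
NIR-reflecting grass by night at ~170, texture SD 18), ants as 2×2
squares of contrast 80 — bright on the day background, dark on the night
background, deliberately exercising both contrast signs — performing a
reflected random walk (step ≤ 3 px, re-drawn if zero) inside the eroded
mound mask; i.i.d. Gaussian sensor noise (SD 2 by day, 3 by night);
optional global integer camera jitter; and the 06:00/20:00 sensor-mode
switch. Every generator is a pure function of (config, seed), and the
per-frame ant positions, applied jitter and scheduled counts are returned
as ground truth.

The daily schedule `generate_daily_profile` encodes the normal routine as
an M-shaped curve: sigmoid dawn/dusk envelope (06:00/20:00, 0.7 h scale)
times two Gaussian bumps at 12:00 and 16:30 (SD 1.5 h, second peak 0.9 of
the first), peak level 12 ants. The bump width was chosen so the
inter-peak valley is pronounced, as in a genuinely M-shaped routine —
with much wider bumps the two peaks merge into a plateau and the shape is
no longer M-like. The `suppressed_night` variant raises the nocturnal
level inside a configured window around an origin time, emulating the
pre-earthquake suppression of the nocturnal rest phase. Synthetic
operators report the true category with independent ±1 slips at a 20%
disagreement rate.

What the scenes do **not** emulate: photorealistic ants, moving grass,
illumination drift, rain, shadows, predators (beyond nothing), or the
night-time material brightness changes that cause real day/night
calibration mismatches. Passing tests therefore validate the algorithmic
chain — differencing, registration, calibration, filtering — not field
robustness.

## Numerical choices

- **Intensity** stays 8-bit through I/O and is promoted to float inside
  computations; `A(t)` is an exact integer sum of 8-bit differences, so
  oracle comparisons are bit-exact.
- **Registration** detects interest points as local maxima of the Sobel
  gradient magnitude outside the mound mask (ant motion must not bias the
  estimate), scores integer shifts by the mean normalized
  cross-correlation of 9×9 patches (via `skimage.feature.match_template`),
  and optionally refines the peak parabolically. Integer shifts keep the
  differencing tests exact. Uncovered border pixels after shifting are
  excluded from the sum.
- **Median filter** windows are defined on timestamps, not sample counts,
  so irregular sampling and edges need no special casing.
- **Peak counting** on a filtered daily curve uses topological
  persistence (union-find over samples activated from the highest down): a
  peak counts when it rises at least the prominence (default 1.0
  category) above the saddle toward a higher peak. This is insensitive to
  the plateaus and micro-dips the [0, 7] clamp produces at flattened peak
  tops, where scipy's `find_peaks` prominence assigns equal-height maxima
  the full curve range.
- **Axial statistics** (lineament modes) use the doubled-angle vector
  mean: mean = ½·arg Σ w·e^{2iθ}, SD = ½·√(−2 ln R̄), so a bump straddling
  0°/180° is a single mode. Mode boundaries are the smoothed-histogram
  minima between prominent peaks (prominence 15% of the smoothed maximum,
  evaluated on the circularly tiled histogram).
- **Geographic input** is projected with a hand-written azimuthal
  equidistant projection (exact spherical formulas); distances and
  azimuths from the projection center are preserved, which is the only
  property the orientation analysis needs.
- **Degenerate inputs**: an all-equal raw-activity design is rejected as
  rank deficient; a zero-variance suppression baseline is an error, not a
  flag; σ estimation requires ≥ 10 same-mode frame pairs and otherwise
  falls back to 0 inside the series driver (noiseless synthetic input).

## Design decisions that were genuinely open

- *Operationalizing "rest-phase suppression"*: no standard statistic
  exists; the package uses the displacement of a night's mean index from
  the mean of ≥ 5 reference nights, in units of the standard deviation
  across those nights' means. Both directions trigger, since both
  abnormally high nocturnal activity (the reported pre-earthquake
  pattern) and abnormal silence are deviations from routine.
- *Pairing manual and automatic samples*: the full 10-min slot rather
  than the 1-min scored clip; every automatic sample then informs exactly
  one pair and the window median is stable.
- *Category 7 (sunbathing)* is treated as an ordinary numeric level in
  the regression; whether it truly sits above "crowded" on an activity
  ordinal is unknown.
- *Day/night transition frames* are labeled by schedule or channel-count
  heuristic and the straddling pair simply yields no sample; no blended
  handling is attempted.
- *Calibration-recovery conditions*: the acceptance check fits against
  ground-truth polynomials whose coefficients each contribute O(1) to the
  response over the raw range (day 0.001·x + 1.5; night 2·10⁻⁷·x² +
  1.5·10⁻³·x + 1.5, x ∈ [0, 6000], noise SD 0.1), so all coefficients are
  statistically identifiable at n = 300.

## Problem sizes

The test suite and the acceptance script run full synthetic days of 8,640
frames (10-s cadence, 24 h) at 64×48 px — the native analysis cadence
with a reduced frame geometry, chosen so a single CPU completes the
five-seed end-to-end recovery in seconds while every stage still sees
realistic sample counts (8,637 activity samples, 144 manual windows, 84
day + 60 night calibration pairs per day). Registration tests run at
48×64 with shifts up to ±5 px; differencing oracles at 32×32.

## Known limitations

- The suppression flag is a screening statistic, not a detector with
  controlled error rates; no significance claim is attached.
- Registration assumes translation only; rolling-shutter effects,
  rotation or scale changes are out of scope.
- The calibration is only as good as the operator consensus it is fitted
  to; real night-time material brightness changes are known to bias the
  automatic index relative to manual scores and are not corrected.
- The Hough orientation histogram depends on its discretization (ρ bin,
  angle bins, minimum support); defaults are reasonable for tens-of-km
  mound surveys but are parameters, not claims.
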