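# moundwatch

Automated quantification of red wood ant (*Formica rufa* group) activity on
a mound top from fixed dual-sensor cameras, with calibration against manual
activity scoring, earthquake-catalog correlation, and mound-alignment
analysis.

Red wood ants build stationary mounds on tectonically active, gas-permeable
fault systems, which makes a colony a fixed biological sensor: its daily
activity routine can be monitored continuously for years from a single
camera, and deviations from the routine can be screened against local
seismicity. `moundwatch` implements the full analysis chain for such a
monitoring station and ships a ground-truthed synthetic scene generator so
every stage is testable without any field recordings.

## The method

**Raw activity index.** A camera with a color sensor (day) and a
near-infrared sensor with active illumination (night) delivers one frame
every Δt = 10 s. After compensating small camera motion — a translation
estimated by normalized cross-correlation over interest points outside the
mound region — the pixel-wise absolute difference

    D_uv(t) = |I_uv(t) − I_uv(t − Δt)|

is formed. Moving ants appear as small bright spots in D. Difference
intensities exceeding three times the sensor noise σ (estimated robustly
per sensor mode from out-of-mask pixels, σ = 1.4826 · median|D|) are summed
over the mound mask M:

    A(t) = Σ_{(u,v) ∈ M} D_uv(t) · [D_uv(t) > 3σ]

**Calibration to the manual scale.** Three operators score a short clip
every 10 minutes into eight activity categories (0 = no ants on the mound
top … 6 = crowded, 7 = sunbathing); the consensus C(t) is the rounded mean
of the three scores — 144 values per day. Over a fit window, raw sums are
paired with consensus categories and split by sensor mode into sets S_d
and S_n; a first-order polynomial p_d is least-squares fitted to S_d and a
second-order polynomial p_n to S_n, minimizing the RMS difference between
C(t) and p(A(t)). The continuous index p_mode(A(t)), clamped to [0, 7], is
finally smoothed with a 10-minute temporal median filter. The normal daily
routine is an M-shaped curve: activity rises from dawn, peaks at midday
and again in the late afternoon, and falls to a near-zero nocturnal rest
phase.

**Event correlation.** Earthquake catalogs are filtered by great-circle
distance (haversine, R = 6371 km) and magnitude (strictly > threshold)
relative to the camera location; activity segments are re-timed relative
to each origin, and a displacement score (night mean versus a baseline of
reference nights, in baseline standard deviations) flags nights whose rest
phase deviates from the routine.

**Mound lineaments.** Mound coordinates, projected to a local
azimuthal-equidistant plane, go through a point-set Hough transform; the
per-angle support histogram over the axial range [0°, 180°) is partitioned
into orientation modes (axial circular mean ± SD), the preferential
alignment directions of the mound field.

## Worked example

A full synthetic day (8,640 frames at 10-s cadence, 64×48 px) with an
M-shaped ground-truth schedule, run through the entire chain:

```python
from datetime import datetime, timezone
import numpy as np
from scipy.stats import spearmanr
from moundwatch import (
    SceneConfig, generate_daily_profile, generate_video, generate_operator_scores,
    categories_from_profile, compute_activity_series, schedule_manual_windows,
    pair_samples, fit_calibration, calibrate_series, median_filter_series,
    count_activity_peaks,
)

start = datetime(2010, 6, 1, tzinfo=timezone.utc)
times, profile = generate_daily_profile("M_shaped", cadence_s=10.0, start=start)
cfg = SceneConfig(n_ants=profile, n_frames=len(profile), start=start, seed=1)
frames, truth = generate_video(cfg)

series = compute_activity_series(frames, cfg.resolved_mask(), register=False)

windows = [w for w, _ in schedule_manual_windows(start.date())]
cats = categories_from_profile(windows, times, profile)
annotations = generate_operator_scores(windows, cats, disagreement=0.2, seed=2)
model = fit_calibration(*pair_samples(series, annotations))

index = median_filter_series(calibrate_series(model, series))
```

This prints (via the accompanying report statements):

```
8637 activity samples, day sigma = 2.97
day fit p_d:   slope=1.035e-03, intercept=-0.083, rms=0.319 (84 pairs)
night fit p_n: rms=0.179 (60 pairs)
rank correlation with injected schedule: 0.999
prominent daytime peaks: 2
```

The 8,640 frames yield 8,637 samples (two frame pairs straddle the
day/night sensor switches and are skipped). The day polynomial maps ~970
raw difference units to one activity category with a residual RMS of about
a third of a category — the scale of operator disagreement. The filtered
index ranks the day almost identically to the injected schedule, and the
two prominent daytime peaks recover the M shape.

A command-line interface mirrors the stages (`moundwatch synth / activity /
calibrate / correlate / lineament / run-all`); see `moundwatch --help`.

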