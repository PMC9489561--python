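# Methods

## Scope and model

`pwvkit` measures pulse wave velocity from one cardiac cycle of flow (ml/s)
or velocity (cm/s) sampled uniformly over the cycle at each of two aortic
planes. The cycle is treated as periodic: retrospective ECG gating
reconstructs a closed cycle, so smoothing, shifting and resampling all wrap
circularly. Everything is bookkept in mm and ms internally, so
`PWV = Δd/Δt` in mm/ms is numerically m/s with no conversion factors.

The package does not touch images: vessel segmentation, flow-curve
extraction and manual centerline delineation happen upstream; `pwvkit`
consumes the resulting sampled curves and ordered centerline points.

## Transit-time estimators

Each curve is Gaussian-smoothed and a landmark time is located; Δt is the
descending-plane landmark minus the ascending-plane landmark.

- **Time-to-peak (TTP)**: time of the global maximum (earliest frame on
  ties).
- **Maximum upslope**: time of the largest discrete derivative between cycle
  start and the global maximum. The window restriction avoids diastolic
  artifacts; ties break to the earliest frame. The derivative is a central
  difference on the smoothed curve (one-sided at the array boundary), in
  units per ms.
- **Time-to-foot (TTF)**: the tangent through the maximum-upslope point
  `(t_up, y(t_up))` with slope `s` is intersected with the zero baseline:
  `foot = t_up − y(t_up)/s`. The tangent is taken from the single-point
  central-difference derivative rather than a multi-sample line fit; this is
  the simplest defensible reading and is noted below under limitations.

Landmark times are continuous (TTF has sub-frame precision); TTP and
maximum upslope land on frame times. Δt may legitimately be negative —
curves without a definitive peak can order the landmarks either way — and is
reported signed. Δt = 0 leaves PWV undefined and flagged, never ±infinity.
An optional unwrap adds one cycle when Δt < −cycle/2 (circular ambiguity);
it is off by default.

Scale invariance holds by construction for all three methods (the TTF foot
`t_up − λy/(λs)` cancels the common factor), and whole-frame circular delays
shift Δt by exactly the delay.

### Baseline correction

Only TTF references the baseline, so correction applies to TTF alone.
Automatic correction subtracts, per curve independently, the mean over the
late-diastolic window of samples with phase `0.80 ≤ i/n < 0.95` (half-open;
at n = 40 that is frames 32–37). Late diastole sits close to the systolic
upslope in cycle order, which keeps the window away from early-diastolic
retrograde flow (e.g. valve insufficiency). Manual correction subtracts the
mean over a caller-chosen phase window; the recommended placement is the
pre-systolic segment, and the pipeline default is `[0.90, 1.0)` — late
enough that the smoothing kernel's spread from the systolic onset cannot
leak into it at clinical frame counts.

### Smoothing

Gaussian, circular, with SD given as a fraction of the cardiac cycle
(default 0.025) and converted to samples per curve. A cycle-fraction SD
makes the filter independent of temporal resolution, which matters because
the same setting is applied to 44-frame clinical curves and 10,000-frame
phantom curves. The normalized circular kernel conserves the curve mean to
machine precision.

## Temporal-resolution phantom

For a vessel length L and reference PWV v, the descending curve is the
ascending waveform circularly delayed by `L/v` ms, scaled by 0.6 to mimic
blood diversion into the aortic arch branches, and smoothed with a Gaussian
filter of width 2,000 timeframes at the 10,000-frame working resolution.
Both curves are then resampled to 20–60 timeframes per cycle by periodic
linear interpolation at the acquisition phases (point sampling, phase origin
0; a phase-offset knob exists for sensitivity probes), PWV is estimated by
TTF with automatic baseline correction, and the signed % error against v is
recorded. The required timeframes per cycle is the smallest N such that
|error| ≤ 10 % for every reference PWV at every N′ ≥ N; cells where the
analysis fails are recorded as missing and count against the criterion.

Two interpretations were fixed by design:

- **"Width 2,000 timeframes"** is read as total kernel support with
  SD = width/6 (±3 SD inside the window). Reading the width as the SD itself
  (20 % of the cycle) would obliterate the waveform. The semantics are a
  named config knob (`smooth_width_semantics`).
- **Smoothing target.** The filter is applied to *both* curves by default
  (`smooth_target="both"`). Convolution commutes with the circular shift, so
  the smoothed pair remains an exactly delayed pair and the experiment
  isolates the quantity under study — temporal discretization. Smoothing
  only the shifted descending copy is available as
  `smooth_target="descending"`; it widens one upslope relative to the other
  and adds a constant foot-detection offset (measured at ≈ 6 ms for the
  default neonatal waveform) to every Δt, i.e. a resolution-independent bias
  whose relative size grows as the true delay shrinks. With the default, TTF
  at 10,000 frames recovers the construction delay to < 0.1 frames and the
  full-resolution error stays below 0.1 %; the error at 20 frames is tens of
  percent and falls by an order of magnitude by 60 frames.

The default experiment pairs vessel lengths with profiles as in the study
populations: neonatal profile with 25 mm (aortic arch) and 60 mm (thoracic
aorta), adolescent profile with 60 mm and 150 mm. The 150 mm/neonatal cross
is unphysiological (the neonatal thoracic aorta is ≈ 68 mm) and its 75 ms
delay drags the shifted dicrotic wave toward the automatic-baseline window,
but even that combination passes the convergence checks.

## Synthetic waveform generator

The generator replaces the study's non-public patient curves. One cycle, in
phase units `u ∈ [0, 1)`:

| piece | form | default |
|---|---|---|
| systolic upstroke | raised cosine over `rise = 0.3 × systolic_fraction` | — |
| systolic decline | raised cosine over the rest of the systolic window | — |
| dicrotic wave | Gaussian bump, SD 0.02 cycles, centered 0.04 cycles after end-systole | 12 % of peak |
| retrograde lobe | negative half-sine, width 0.06 cycles, immediately post-systole | off |
| diastole | flat at `baseline_offset` | 0 |
| noise | additive white Gaussian, per sample | off |

Profiles: **neonate** 138 bpm with systole occupying 0.45 of the short
cycle, **adolescent** 75 bpm with 0.33 — median group heart rates, with the
relatively shorter neonatal diastole. Systole onsets at phase 0.05. The
rise fraction 0.3 puts time-to-peak at 0.10–0.14 of the cycle, the
physiological range for aortic flow; absolute amplitude is arbitrary
(default 100) since every estimator is scale-invariant.

Cohort subjects draw ground-truth PWV uniformly from a range (single seed;
all randomness flows from it). The descending curve is evaluated
analytically at shifted phases — not interpolated — so with zero noise it is
an *exact* circularly delayed, 0.6-scaled copy, and estimator error measures
the estimator, not the construction. A delay not shorter than the cycle
raises a construction error.

What the generator does **not** emulate: beat-to-beat variability,
heart-rate-dependent waveform morphology beyond the systolic fraction,
correlated (non-white) measurement noise, velocity-aliasing artifacts, and
flow-plane angulation errors. Passing recovery tests therefore demonstrate
correctness of the estimation chain under known ground truth, not clinical
accuracy on patient data.

## Agreement statistics

Bland–Altman with differences fixed as *first argument minus second*
(recorded in the output), sample SD with n−1 denominator, limits of
agreement bias ± 1.96 SD, plus the per-pair (mean, difference) table for
plotting. Summary tables report mean ± SD per (method, baseline, curve-kind)
cell or median (range) for descriptive characteristics; a single-member cell
reports SD 0. Paired t-tests and repeated-measures ANOVA are deliberately
not re-implemented — they are routine and available in any statistics
package.

## Geometry

Centerline length is the arc length of the ordered world-space polyline (sum
of consecutive Euclidean distances, mm). No smoothing is applied by default
— the manual delineation is used as measured; an arc-length-preserving cubic
spline resampler exists for noisy point sets.

## Numerical choices and degenerate inputs

- Curves need ≥ 8 frames; values must be finite; both curves of a pair must
  share grid, cycle duration and kind.
- Resampling (up and down) is periodic linear interpolation through the
  closed cycle; integer-multiple upsampling reproduces the source samples
  exactly, and `downsample(upsample(c, N), n)` is the identity on nodes.
- Flat curves (no positive upslope) raise an analysis error for TTF and
  maximum upslope; TTP of a constant curve is frame 0 by the earliest-tie
  rule.
- An empty baseline window (phase interval containing no sample index)
  raises rather than silently correcting by 0.
- The tangent in TTF uses the single-point derivative at the max-upslope
  frame. Under white noise this is the dominant variance contributor to the
  foot estimate; at 44 frames with noise SD 5 % of peak, per-curve foot
  jitter is ≈ 2–3 ms SD, which against neonatal transit delays of 7–34 ms
  makes single-beat TTF PWV noisy (median cohort error ≈ 30 %). A
  multi-sample tangent fit would reduce this and is a known limitation, not
  a configuration option.

## Problem sizes

Default experiment sizes were chosen so the whole analysis suite runs in
seconds: phantom grids at 10,000 working frames over 5 reference PWV × 41
resolutions × 4 panels; recovery cohorts of 50 subjects at 1,000 frames
(noise-free) and 44 frames (noisy); 100-shift oracle-equivalence sweeps at
256 frames.
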