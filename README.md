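# pwvkit

Pulse wave velocity (PWV) — the speed at which the systolic flow wavefront
travels along the aorta — is the standard surrogate for arterial stiffness.
With phase-contrast MR, PWV is measured as

```
PWV = Δd / Δt
```

where Δd is the centerline blood traveling distance between two flow planes
(ascending aorta and descending aorta at the diaphragm) and Δt is the transit
time of the flow wavefront between the corresponding flow or velocity curves.
Because Δt in children is only a few milliseconds to a few tens of
milliseconds, the result is acutely sensitive to how the curve landmark is
defined, whether the curve baseline is leveled first, and how many timeframes
per cardiac cycle the acquisition reconstructs.

`pwvkit` implements that methodology end to end for researchers working on
PWV standardization in pediatric cohorts (neonates, heart rate ≈ 138 bpm, and
adolescents, ≈ 75 bpm):

- **Transit-time estimators** — time-to-foot (TTF: intersection of the tangent
  at the maximum systolic upslope with the corrected baseline), maximum
  upslope, and time-to-peak (TTP), with sub-frame landmark times and signed Δt.
- **Baseline correction** — none, automatic (mean of the late-diastolic
  80th–95th % segment of the cycle), or manual (caller-chosen phase window,
  typically the pre-systolic segment); applies to TTF only, the single
  baseline-dependent method.
- **Curve conditioning** — circular Gaussian smoothing with SD expressed as a
  fraction of the cardiac cycle (default 0.025), resolution-independent.
- **Temporal-resolution phantom** — a 10,000-frame waveform is circularly
  delayed by Δd/PWV, scaled by 0.6 (arch-branch blood diversion), smoothed,
  and downsampled to 20–60 timeframes per cycle; the %-error grid over
  reference PWV 2–10 m/s yields the minimum timeframes per cardiac cycle for
  accurate PWV.
- **Synthetic cohorts** — parametric neonatal/adolescent flow waveforms with
  known ground-truth PWV, optional dicrotic wave, retrograde diastolic flow
  and measurement noise, for parameter-recovery experiments.
- **Geometry & statistics** — centerline arc length from ordered 3D points;
  Bland–Altman bias and 95 % limits of agreement (± 1.96 SD); tidy
  method-comparison summary tables.

## Worked example

```python
import pwvkit as pk

# a synthetic neonate: thoracic Δd = 68 mm, true PWV 4 m/s, 44-frame acquisition
subject = pk.make_subject(pk.default_params("neonate"), true_pwv_m_per_s=4.0,
                          delta_d_mm=68.0, n_frames=44)
est = pk.transit_time(subject.pair, "TTF", pk.BaselineSpec(mode="automatic"))
print(f"transit time  {est.delta_t_ms:.2f} ms")
print(f"PWV           {est.pwv_m_per_s:.2f} m/s")
print(f"resolution    {pk.temporal_resolution_ms(138, 44):.2f} ms/frame")
```

prints

```
transit time  16.91 ms
PWV           4.02 m/s
resolution    9.88 ms/frame
```

The construction delay is 68 mm / 4 m s⁻¹ = 17 ms; the TTF estimate lands
within a tenth of a frame of it (one frame is 9.88 ms here), so the recovered
PWV is 4.02 m/s against a ground truth of 4.00 m/s.

## Analysis scripts

The numbered drivers under `analysis/` rebuild the study's experiments on
synthetic cohorts and write their tables under `results/`:

1. `01_simulate_cohorts.py` — neonatal (n = 15) and adolescent (n = 71)
   cohorts analyzed with every transit method × baseline mode.
2. `02_temporal_resolution_phantom.py` — required timeframes per cardiac
   cycle for the four profile/vessel-length panels.
3. `03_transit_time_methods.py` — method comparison and Bland–Altman
   agreement against TTF with automatic baseline correction.
4. `04_baseline_correction.py` — baseline-strategy agreement, including a
   retrograde-diastolic-flow cohort.

## Command line

```sh
pwvkit simulate --profile neonate --n 15 --frames 44 --delta-d 68 --seed 1 --out cohort/
pwvkit phantom  --profile neonate --length 25 --tolerance 10 --out grid.csv
pwvkit analyze  --asc asc.csv --desc desc.csv --delta-d 68 --method ttf --baseline automatic
pwvkit length   --in centerline.csv
pwvkit agreement --a ttf.csv --b ttp.csv
```

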