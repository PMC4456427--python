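# ecistools

Analysis toolkit for ECIS (Electric Cell–substrate Impedance Sensing)
wound-healing assays on microelectrode arrays, plus a seeded synthetic
experiment simulator so every stage is testable without instrument data.

The pipeline covers:

- **Data model / I/O** (`ecistools.core`): multi-frequency complex-impedance
  time-courses indexed by (time, well, frequency); long and wide
  (instrument-export) CSV dialects; series/parallel R-C channel extraction
  (R@4 kHz, C@64 kHz).
- **Disk-cell electrode model** (`ecistools.gk`): forward impedance of
  naked (CPE + Rsol), covered, and partially covered microelectrodes;
  numerically stable complex Bessel-ratio evaluation; weighted
  least-squares inversion of a spectrum for the adhesion parameter
  `alpha = r*sqrt(rho/h)` together with the barrier resistance Rb and
  membrane capacitance Cm.
- **Healing kinetics** (`ecistools.kinetics`): wound detection from the
  drop to the cell-free level, 4-parameter logistic fit of the recovery
  (hill slope, inflection point), healing time at a fractional-recovery
  threshold, radius-based migration rate, linear attachment-slope
  adhesion assay, coverage from the high-frequency capacitance channel.
- **Micromotion** (`ecistools.micromotion`): detrend + normalise,
  moving variance (512-sample segments, 150-point window, 1-point step
  → 363 points spanning 22.75 h at the 160 s sweep interval), and a
  high→low activity transition half-time from a window-convolved
  logistic fit.
- **Group statistics** (`ecistools.stats`): one-way ANOVA and
  Tukey–Kramer pairwise comparisons (unequal-n), significance at P<0.01.
- **Simulator** (`ecistools.simulate`): seeded experiments with the full
  phenomenology — attachment rise to a 15 kΩ peak at day 2, maturation
  decline over 5.5 days to an 8.5 kΩ plateau, instantaneous electrical
  wound to the 2600 Ω cell-free baseline, radial-front recovery on a
  250 µm electrode, AR(1) micromotion with a scheduled variance
  transition, and multiplicative measurement noise.  The 4 kHz knot
  values are hit exactly by construction (Rb is numerically inverted).
- **Pipeline** (`ecistools.pipeline` / CLI `run`): config-driven
  end-to-end orchestration with a JSON report and a run manifest.

## CLI

```bash
ecistools simulate --config sim.json --out-dir out/      # synthetic data
ecistools fit-healing channel.csv --cellfree-ohm 2600 \
    --radius-um 125 --threshold 0.95                      # wound → rate
ecistools fit-alpha spectrum.csv --cellfree-ohm 2600      # alpha inversion
ecistools micromotion channel.csv --window 150 --step 1 --segment 512
ecistools compare-groups groups.csv --alpha 0.01
ecistools run --config pipeline.yaml --out-dir out/       # full pipeline
```

Channel CSVs carry `time_h,value`; spectra carry
`frequency_hz,z_real_ohm,z_imag_ohm`; time-courses use the long dialect
`time_s,well,frequency_hz,z_real_ohm,z_imag_ohm` (or the wide
`R_<freq>`/`C_<freq>` export style, Ω and nF).

A minimal pipeline config:

```yaml
simulate:
  seed: 1
  duration_h: 222.0
  wells: [[A1, control], [A2, control], [B1, case], [B2, case]]
  groups:
    control: {alpha: 6.5, front_speed_um_h: 10.69}
    case:
      alpha: 7.8
      front_speed_um_h: 8.6
      schedule: {rise_h: 48.0, peak_r4k: 15000.0, decline_h: 132.0,
                 plateau_r4k: 10000.0, cellfree_r4k: 2600.0}
  wound: {time_h: 192.0}
analysis:
  cellfree_ohm: 2600.0
  radius_um: 125.0
  threshold: 0.95
```

## Conventions worth knowing

- Resistance/capacitance reporting uses the series-RC lock-in convention;
  a parallel-RC convention is selectable where area-linearity of the
  capacitance channel matters.
- The healing fit window defaults to a data-driven rule (1.6× the time
  for the trace to reach 99 % of its post-wound range, capped at 24 h),
  which makes the 0.95-threshold healing time track the true front
  closure time; a fixed window is available everywhere.
- Migration rate is radius-based by default (front travels 125 µm);
  a diameter-based convention is selectable.
- Moving variance is the unbiased (n−1) estimator; segments are
  non-overlapping 512-sample blocks with the trailing partial dropped.
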