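# clsense

Analysis pipeline for ratiometric chloride-indicator imaging in brain-slice
neurons, plus the electrophysiology companion analyses. The package covers:

- **trace_model** — data model for two-channel ROI fluorescence recordings
  (436 nm / 500 nm excitation), experimental conditions (neuron type,
  day/night phase, buffer), drug events and effect tables; strict tidy-CSV
  I/O with a JSON manifest.
- **preprocess** — signal corrections in fixed order: per-wavelength
  background subtraction, ratio computation (R = F436/F500, a proxy for
  intracellular chloride), single-exponential photoinactivation drift
  correction with event masking, and per-condition linear exposure
  normalization to a 100 ms reference.
- **calibration** — four-parameter sigmoid between chloride concentration
  and steady-state ratio, R(C) = Rmax + (Rmin − Rmax)/(1 + (C/Kd)^p), its
  exact inverse, nonlinear least-squares fitting with multi-start, and
  ratio-step → concentration-step conversion.
- **events** — windowed quantification of persistent bath-drug ratio steps
  and peak/recovery summaries of puff-evoked transients.
- **inference** — generalized estimating equations with slices as clusters
  (Gaussian family, exchangeable working correlation, bias-reduced sandwich
  standard errors), cross-model z-comparisons with Bonferroni adjustment,
  and paired t-tests.
- **egaba** — GABA reversal potential as the x-intercept of subtracted
  voltage-ramp I–V relations, plus Nernst / passive-distribution utilities.
- **synthetic_data** — deterministic generators for every input class with
  ground-truth sidecars: clustered fluorescence recordings with sensor
  photophysics, drift and shot-like noise; calibration point sets; ramp
  current pairs.
- **cli** — `clsense` command with `simulate`, `calibrate`, `analyze`,
  `egaba` and `stats` subcommands.

## CLI quick start

```bash
# generate a synthetic dataset (traces.csv + manifest.json + truth.json)
clsense simulate --seed 7 --out-dir data/sim

# fit the calibration sigmoid to a points CSV (cl_mM, steady_r[, slice_id])
clsense calibrate points.csv --out fit.json

# full analysis: corrections -> drug effects -> clustered statistics
clsense analyze --traces data/sim/traces.csv \
    --manifest data/sim/manifest.json --out-dir results/analysis

# reversal potentials from a ramp CSV
# (sweep_id, command_mV, i_gaba_pA, i_control_pA[, cell_id, phase])
clsense egaba ramps.csv --out egaba.json

# clustered GEE on an existing effects CSV
clsense stats effects.csv --out stats.json --formula "delta_r ~ neuron_type * phase"
```

Every command writes a `run_log.json` (resolved config, config hash, version)
next to its outputs; identical run-logs imply identical outputs. Exit codes:
0 success, 2 schema/validation error, 3 numerical failure.

## Data formats

- Traces CSV: one row per ROI per time point with columns `slice_id, roi_id,
  time_s, f436, f500, exposure500_ms, is_background`; exactly one background
  ROI per slice. Floats round-trip losslessly (written at 17 significant
  digits, read with exact parsing).
- Manifest JSON: maps `slice_id` to its condition
  (`neuron_type`/`phase`/`buffer`) and event list (kind, onset, optional
  offset).
- Effects CSV: one row per (ROI, intervention) with baseline/post/delta
  ratio summaries and condition labels for clustered inference.
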