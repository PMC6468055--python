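# polarfmr

Field metabolic rates (FMR) of free-ranging polar bears (*Ursus maritimus*)
from collar biologging, two independent ways:

1. **Accelerometry.** Raw tri-axial acceleration (16 Hz, ±20 m/s²) is
   decomposed into static (gravitational) and dynamic components with a 2-s
   running mean per axis; overall dynamic body acceleration (ODBA) is the
   sum of absolute dynamic accelerations over the three axes. ODBA converts
   to mass-specific oxygen consumption through the captive-bear calibration

   V̇O₂ = 0.07 + 1.90 × ODBA   (ml O₂ g⁻¹ hr⁻¹, ODBA in *g*),

   with a constant swim cost of 2.75 ml O₂ g⁻¹ hr⁻¹ substituted for seconds
   the bear is in the water (detected from the 1 Hz wet/dry conductivity
   channel or from external behavior labels), 20.083 J per ml O₂, and
   division by deployment days to give FMR_ACC in kJ kg⁻¹ day⁻¹.

2. **Doubly labeled water (DLW).** Isotope dilution spaces by the plateau
   method, exponential turnover rates of ¹⁸O and ²H, CO₂ production by the
   Speakman (1997) two-pool equation

   rCO₂ (mol/day) = (N_o / 2.078) (k_o − DSR·k_d) − 0.0062·DSR·k_d·N_o,

   using the cohort-mean dilution-space ratio DSR = mean(N_d/N_o), and
   energy at 26.32 kJ per liter CO₂ (respiratory quotient 0.76).

The package also regularizes GPS fixes onto a 30-min grid along great-circle
paths and computes movement rates, provides the validation statistics
(paired t, DLW:ACC ratio summary, least-squares regressions of FMR_DLW on
FMR_ACC, mean ODBA, body mass, movement rate and activity rate), ships the
published six-bear summary table, and includes a synthetic collar-deployment
generator with closed-form ground truth so that every stage is testable
without any field data.

Intended users: movement ecologists and physiologists working with
animal-borne accelerometers who want a tested, scriptable reference
implementation of the ODBA → energy-expenditure chain and of the DLW
calculation it is validated against.

## Worked example

Simulate a 6-hour deployment, run the pipeline, and compare with the
generator's closed-form expectation:

```python
from polarfmr import (SimConfig, simulate_behavior, simulate_accel,
                      simulate_dlw, ground_truth, process_cohort)
from polarfmr.pipeline import process_deployment

cfg = SimConfig(seed=7, duration_days=6 / 24)
labels = simulate_behavior(cfg)
trace, cond = simulate_accel(labels, cfg)
res, behavior, clip = process_deployment(trace, cond=cond, labels=labels,
                                         duration_days=cfg.duration_days)
gt = ground_truth(cfg, labels)
print(f"FMR_ACC  pipeline: {res.daily_ee:.1f} kJ kg-1 day-1")
print(f"FMR_ACC  expected: {gt.expected_fmr_acc:.1f} kJ kg-1 day-1")

samples, doses = simulate_dlw(cfg)
out = process_cohort(samples, doses)
print(f"DLW rCO2: {out.rco2_l_day[0]:.0f} L/day "
      f"-> FMR_DLW {out.fmr_kj_kg_day[0]:.1f} kJ kg-1 day-1")
```

prints

```
FMR_ACC  pipeline: 126.6 kJ kg-1 day-1
FMR_ACC  expected: 127.2 kJ kg-1 day-1
DLW rCO2: 2302 L/day -> FMR_DLW 318.8 kJ kg-1 day-1
```

The pipeline recovers the generator's expected accelerometer FMR within
0.5% here (the residual is running-mean edge effects plus sampling noise);
the DLW estimate differs from the configured true CO₂ production
(2200 L/day) by the 1% multiplicative enrichment noise the generator adds
by default.

Validation statistics on the published six-bear table:

```python
from polarfmr.validation import table1, table1_analysis
rep = table1_analysis(table1())
p, acc = rep["paired"], rep["regressions"]["fmr_acc"]
print(f"t({p['df']}) = {p['t']:.2f}, p = {p['p']:.4f}; "
      f"DLW:ACC ratio {p['mean_ratio']:.2f} ± {p['se_ratio']:.2f} SE")
print(f"FMR_DLW = {acc['intercept']:.1f} + {acc['slope']:.2f} x FMR_ACC, "
      f"r2 = {acc['r2']:.2f}")
```

```
t(5) = 5.99, p = 0.0019; DLW:ACC ratio 1.42 ± 0.07 SE
FMR_DLW = 66.4 + 1.11 x FMR_ACC, r2 = 0.70
```

i.e. the DLW estimates average ~1.4× the accelerometer estimates (movement
accounts for only part of total expenditure) yet the two are strongly
correlated — accelerometry tracks 70% of the between-bear variation.

A command-line interface mirrors the stages:

```sh
polarfmr simulate --seed 42 --outdir demo/        # or --config sim.yaml
polarfmr odba --in demo/accel.csv --out demo/odba.csv
polarfmr behave --cond demo/wetdry.csv --labels demo/labels.csv --out demo/behavior.csv
polarfmr energize --odba demo/odba.csv --behavior demo/behavior.csv --out demo/summary.csv
polarfmr dlw --samples demo/dlw_samples.csv --doses demo/dlw_doses.csv --out demo/dlw.csv
polarfmr moverate --gps demo/gps.csv --out demo/rates.csv
polarfmr validate --summaries table1.csv --report report.json
polarfmr run-all --config run.yaml --outdir out/
polarfmr --version   # prints the pinned physiological constants
```

## Layout

- `polarfmr.accel` — ODBA chain (unit conversion, running-mean static
  estimate, dynamic acceleration, epoch means, clipping QC)
- `polarfmr.behavior` — wet/dry swim detection, label merging, activity rate
- `polarfmr.energetics` — calibration model, behavior-specific energy totals
- `polarfmr.dlw` — plateau dilution spaces, turnover, two-pool CO₂, energy
- `polarfmr.movement` — haversine distances, great-circle track
  regularization, movement rates
- `polarfmr.validation` — paired t, ratio summary, regressions, the six-bear
  table
- `polarfmr.simulate` — seeded synthetic deployments with ground truth
- `polarfmr.pipeline` / `polarfmr.cli` — orchestration and the `polarfmr`
  command

See `docs/methods.md` for the model details, defaults, and limitations.
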