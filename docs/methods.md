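# Methods

This note records the models, defaults, and numerical choices behind
`polarfmr`, and what the synthetic generator does and does not emulate.

## Accelerometry → FMR

**Static/dynamic decomposition.** Raw acceleration (m/s², validated against
the ±20 m/s² sensor range) is converted to *g* (÷9.81) and smoothed per axis
with a 2-s centered running mean. At 16 Hz the window is 32 samples — 16
before, the current sample, and 15 after — truncated where it overruns the
start or end of a segment (the truncated mean uses only available samples;
no padding). Sampling gaps longer than 1.5 sample intervals split the record
into segments that are smoothed independently, so a mean never bridges a
dropout. The running mean is computed with a cumulative-sum formulation
(O(n), exact to the accumulation order); the test suite checks it against a
literal per-sample loop to 1e-12.

**ODBA.** Dynamic acceleration is raw minus static per axis; ODBA is the sum
of the three absolute dynamic components (VeDBA, the Euclidean alternative,
is provided but not used downstream). ODBA is averaged into 1-s epochs.
Epoch means are weighted by sample count, so a partial final epoch is
handled and the weighted recombination reproduces the global mean exactly;
1-s epochs also make the energy total invariant to how the record is
partitioned (tested to 1e-9).

**Energy model.** Per epoch,

    VO2 (ml O2 g^-1 hr^-1) = 0.07 + 1.90 × mean ODBA (g)

for non-swimming epochs, and a constant 2.75 for swimming epochs. Energy
per epoch is VO2 × 20.083 J/ml O2 × (epoch length / 3600 s); the sum over
epochs divided by (mass-normalized) deployment days gives FMR_ACC in
kJ kg⁻¹ day⁻¹ (kJ/kg ≡ J/g, so no mass term appears when the calibration is
already mass-specific). Closed-form anchors: an all-rest record gives
0.07 × 20.083 × 24 = 33.74 kJ kg⁻¹ day⁻¹; an all-swim record gives
2.75 × 20.083 × 24 = 1325.5.

**Swimming detection.** The 1 Hz conductivity channel yields wet runs;
interior dry gaps ≤ 2 s are bridged, then wet runs shorter than 5 s are
dropped (splash rejection). The operation is idempotent. External behavior
labels, when supplied, take precedence for rest/active; swim flags always
override. Without labels, epochs with mean ODBA below 0.05 g are classed as
resting for the activity-rate summary (this threshold does not affect
energy, which depends on ODBA continuously).

## Doubly labeled water

Dilution spaces use the plateau method: N (mol) = dose (mol) / enrichment
excess at equilibration, with dose water molar masses 20.015 g/mol (H₂¹⁸O)
and 20.028 g/mol (D₂O). Turnover rates are k = ln(excess_eq / excess_final)
/ interval days. CO₂ production uses the Speakman (1997) two-pool equation
(eq. 7.17 form), pinned as `TWO_POOL_NAME = "speakman-1997-eq7.17"`:

    rCO2 (mol/day) = (N_o / 2.078) (k_o − DSR·k_d) − 0.0062 · DSR · k_d · N_o

with the dilution-space ratio DSR taken as the cohort mean of N_d/N_o
(per-animal DSR is available via `use_group_dsr=False`). A warning is
emitted when DSR falls outside 0.9–1.15, the physiologically plausible
band. Moles convert to liters at 22.414 L/mol and to energy at 26.32 kJ/L
CO₂, corresponding to a respiratory quotient of 0.76. The null turnover
k_o = DSR·k_d·(1 + 2.078 × 0.0062) (zero CO₂ production) is exposed for QC.

## Movement

Distances are haversine on a sphere of radius 6371.0088 km (the IUGG mean
radius); at these latitudes and step lengths the ellipsoidal correction is
well under the GPS fix error, so no geodesic library is pulled in. Tracks
are regularized to a 30-min grid by spherical linear interpolation (slerp)
between bracketing fixes — a great-circle substitute for state-space track
models, adequate here because movement rate is the only quantity consumed
downstream. Movement rate is step distance / step duration on the grid.

## Validation statistics

The six-bear summary table (IDs, age, deployment duration, mass, FMR_DLW,
FMR_ACC, mean ODBA) ships as an in-package constant. On it the package
computes: a paired t-test between FMR_DLW and FMR_ACC (scipy closed form,
df = 5), the DLW:ACC ratio mean ± SE (ddof = 1) with min/max, and ordinary
least-squares regressions (scipy `linregress`) of FMR_DLW on FMR_ACC, mean
ODBA, and body mass. The regression slope p-value is cross-checked against
a permutation oracle in the tests. Recomputed values are reported alongside
the published rounded values; the acceptance policy is agreement after
rounding to the printed precision or within 3% relative (the source table
prints one decimal of values that were regressed unrounded).

## Synthetic generator

The generator exists to make every stage testable end to end with known
ground truth; it emulates the *statistical structure* the pipeline relies
on, not bear biomechanics.

- **Behavior** is a semi-Markov renewal process over rest/active/swim with
  a time budget (default 0.70 / 0.297 / 0.003) and mean dwell times
  (300 / 120 / 60 s); state entry probabilities are proportional to
  budget/dwell so the long-run occupancy matches the budget.
- **Acceleration** is a gravity vector that wanders slowly in orientation
  (0.5°/min) plus a per-state sinusoidal gait on the surge axis plus white
  noise (σ = 0.02 g). Gait frequencies are 0.5 Hz (rest), 1.5 Hz (active),
  1.0 Hz (swim): each completes an integer number of cycles per 2-s window,
  so the running mean removes none of the gait signal, and at 16 Hz the
  non-phase-locked sampling covers enough distinct phases that the sampled
  mean |sin| matches the continuous value 2a/π (0.5 and 1.5 Hz give 32
  phase points, bias < 0.3%; 1.0 Hz gives 16 points, ≈1.2% — within the
  pipeline tolerances but the reason analytic tests use 0.5/1.5 Hz).
- **Ground truth** for expected mean ODBA per state uses the exact
  phase-averaged expectation E|a·sinθ + N(0, σ)| (error-function form)
  plus the rectified-noise contribution on the other two axes, rather than
  the additive approximation 2a/π + σ√(2/π) per axis, which overstates
  rest-state ODBA when σ is comparable to a. Noise-free recovery of the
  expected FMR_ACC is ~0.2%; with default noise and gravity wander, ~0.5%
  (tested at 1% and 3% tolerances respectively on 6-h deployments).
- **DLW** simulation inverts the two-pool equation exactly: given a true
  rCO₂ (default 2200 L/day), body water fraction (0.65), true DSR (1.03)
  and k_d (0.18 /day), it derives k_o, then synthesizes equilibration and
  final enrichments over an 8–11 day interval, with optional multiplicative
  enrichment noise (default 1%). Noise-free round trip is exact to 1e-6;
  at 1% noise the median absolute rCO₂ error over 1000 replicates is ~4.4%
  (the amplification reflects the k_o − DSR·k_d difference, as in real DLW).
- **GPS** is a small-step random walk at the walk speed during active
  seconds, stationary otherwise.

All randomness comes from `numpy.random.default_rng([seed, stream])` with
fixed stream IDs per channel (behavior, accel, GPS, DLW), so outputs are
deterministic per seed and channels are independent.

## Limitations

- The calibration intercept/slope and the swim constant are fixed inputs
  from captive respirometry; the package propagates, not re-estimates, them
  (though `fit_calibration` can refit from user-supplied points).
- Two-pool DLW assumes the plateau (not intercept) method and a single
  cohort DSR by default; isotope fractionation beyond the 0.0062 term is
  not modeled.
- Spherical distances and slerp interpolation ignore ellipsoidal shape and
  sea-ice drift; movement rates are lower bounds between fixes.
- The gait model is a single-axis sinusoid; real ODBA spectra are broadband,
  so generator recoveries validate the numerics, not the biology.
- With n = 6 animals the regressions and paired test have little power;
  the statistics module reports them as published but draws no new
  inference.
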