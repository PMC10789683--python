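# Methods

## The estimation problem

During mechanical ventilation, part of the driving pressure distends the
lung and part displaces the chest wall; the split is governed by the
tidal pleural-pressure swing ΔPpl. The package estimates ΔPpl from the
central venous pressure swing ΔCVP. Transmission of pleural pressure
into the superior vena cava is attenuated by an unknown,
patient-specific factor, so a calibration is obtained from an occlusion
test (OT): with the airway closed at end-expiration and the rib cage
gently squeezed (target ≈ 10 cmH₂O), no gas flows, alveolar pressure
follows pleural pressure, and

κ = ΔPaw/ΔCVP = ΔPpl/ΔCVP.

During ventilation on unchanged settings the estimate is then
ΔPpl ≈ κ·ΔCVP, with both deltas read between an inspiratory and an
expiratory hold. The identity at the core of the method — and the
package's central invariant — is that for *any* transmission factor
T = ΔCVP/ΔPpl the estimate is exact when transmission is linear and
stable between the OT and the tidal measurement: κ·ΔCVP =
(1/T)·(T·ΔPpl) = ΔPpl. Everything else (noise, cardiac interference,
transmission drift) degrades that identity, which is why the tests are
structured around it.

## Simulator model

A single-compartment linear respiratory system:

- Series elastances: 1/Crs = 1/CL + 1/Ccw.
- Volume-controlled breaths: constant inspiratory flow; passive
  expiration following exp(−t/τ) with τ = R·Crs. The expiratory profile
  subtracts its non-emptying tail so each breath returns exactly to the
  end-expiratory volume; this keeps hold pressures closed-form (an
  expiratory hold reads exactly total PEEP, an inspiratory hold exactly
  PEEP + TV/Crs).
- Signals: paw = PEEP + V/Crs + R·flow (+ squeeze during occlusion);
  dppl = Ppl_ee + V/Ccw (+ squeeze); pes transmits a fraction k_es of
  the pleural swing (esophageal-balloon fidelity); cvp = CVP_ee +
  T·(pleural swing) + cardiac sinusoid + white noise.
- Occlusion test: volume frozen at the end-expiratory level, a smooth
  cosine ramp to a 2-s squeeze plateau. During occlusion Δpaw = Δdppl
  holds sample-wise by construction (the estimator never sees the ramp
  shape, only windowed plateau means — it must not depend on it).

Per-study sampling: subject-level parameters (weight, CL, R, esophageal
transmission, heart rate, cardiac amplitude) persist across a subject's
six conditions; chest-wall compliance is drawn once per chest-wall state
(one chest wall per animal), the transmission T once per subject (the
null model: T independent of volume status and abdominal banding), and
baseline CVP per condition, sorted so it rises monotonically with the
volume state as in the experimental protocol (low → normal → high;
within each, normal chest wall then abdominal band).

### Default parameters (units, value, rationale)

| parameter | default | why |
|---|---|---|
| weight | 43.2 ± 1.8 kg | adult-sized pig model |
| tidal volume | 8.0 ± 0.5 mL/kg | volume-controlled protective settings |
| PEEP | 6 cmH₂O | fixed across all conditions |
| respiratory rate / I:E | 20 /min, 1:2 | typical for normocapnia at this TV |
| CL | 30 ± 7 mL/cmH₂O | post-lavage lung of an adult-sized pig |
| Ccw normal / banded | 89 ± 22 / 37 ± 15 mL/cmH₂O | abdominal banding roughly halves chest-wall compliance |
| airway resistance | 10 ± 2 cmH₂O·s/L | intubated large animal |
| esophageal transmission k_es | 0.9 ± 0.1 (truncated 0.7–1.1) | balloons under-read by ~10% with scatter; makes the 0.8–1.2 validity filter bind realistically |
| transmission T | 0.45 ± 0.15 (truncated 0.2–1.0) | centres κ = 1/T near 2.2 with condition spread |
| baseline CVP | 7.5 → 19.7 mmHg across conditions (×1.36 → cmH₂O) | rises with volume loading and abdominal pressure |
| heart rate / cardiac amplitude | 88 ± 17 bpm / 2 ± 0.5 cmH₂O | dominant CVP artifact to be averaged out |
| pressure noise SD | 0.3 cmH₂O, white | transducer/quantization floor; not tuned to any output |
| hold / OT squeeze duration | 3 s / 2 s | ≥ 2 cardiac cycles per window at 80 bpm |
| sample rate | 100 Hz | typical monitor export |

Pressures stated in mmHg (CVP, abdominal pressure) are converted at the
prior layer with 1 mmHg = 1.36 cmH₂O.

### What the simulator does *not* emulate

No closed-loop cardiovascular model (stroke volume, preload indices are
descriptive covariates at most), no lung-injury heterogeneity,
recruitment or airway closure, no spontaneous breathing, no transducer
drift, and cardiac interference is a pure sinusoid rather than a full
venous waveform (a-c-v morphology). Passing tests therefore demonstrate
that the *estimation chain* is correct and robust to the modelled
disturbances — not that CVP transmission is linear and stable in a real
patient, which is precisely the physiological assumption the method
rests on.

## Signal reading

Holds are located annotation-first (the maneuvers are operator-triggered
events, as in the experiment); flow-threshold detection
(|flow| < 1e-4 L/s for ≥ 1 s) is a fallback for unannotated records.
Plateau pressures are means over the last 50% of a window (skipping
post-occlusion equilibration). CVP is instead averaged over the largest
whole number of cardiac cycles that fits, end-aligned with
fractional-sample interpolation, so the cardiac oscillation cancels
regardless of the sample grid. The cycle length is estimated from the
windowed CVP autocorrelation (unbiased normalization; first strong local
maximum in the 0.4–2 s lag band, since end effects can push harmonic
peaks above the fundamental), refined by a least-squares sinusoid fit
over frequency. If no periodicity is detectable the reading degrades to
a plain mean — correct for cardiac-free traces, warned about when a
known cycle exceeds the window.

## Numerical and design choices

- Validity band [0.8, 1.2] is inclusive at both ends, so a ratio
  population of 0.9 ± 0.1 sits interior to it.
- κ is computed from endpoint deltas of windowed means (baseline vs
  squeeze plateau), not a regression over the ramp; the ramp shape is
  deliberately not part of the contract.
- Occlusion tests with |ΔCVP| < 0.5 cmH₂O raise a calibration failure
  rather than produce an unstable κ; such conditions are accounted as OT
  failures in the exclusion cascade.
- One OT per condition, applied only to that condition's tidal
  measurement; κ is never reused across conditions (transmission is
  assumed stable only over minutes).
- Tidal ΔPaw is plateau minus total PEEP (both zero-flow readings), not
  peak minus set PEEP.
- ΔCVP during ventilation is read at the same hold windows as the other
  channels (hold-synchronized), not from dynamic waveform extremes.
- Exclusion cascade: direct-Ppl/Paw failures first, then esophageal
  ratios among the remainder, then CVP failures; the three comparisons
  (Pes vs d-Ppl, κ·ΔCVP vs d-Ppl, Pes vs κ·ΔCVP) drop pairs
  independently, so their n's differ.
- Bland–Altman uses the simple independent-pairs formula pooled over
  repeated measures (bias, SD of differences, bias ± 1.96 SD), matching
  how such studies usually present per-animal repeated conditions; a
  repeated-measures-corrected LoA (one-way variance decomposition) is
  available behind a flag.
- rmcorr follows the ANCOVA definition: within-subject centering, common
  slope, r = sign(slope)·√(SS_model/(SS_model+SS_error)),
  df = N − n_subjects − 1, p from the t transform. p-values are reported
  unadjusted with their df.
- Compliance partitioning returns CL as missing when the pleural swing
  consumes the entire driving pressure (degenerate partition).
- Degenerate inputs fail loudly: non-physical mechanics, n_subjects < 2,
  zero within-subject variance in rmcorr, windows shorter than the
  sample spacing.

## Problem sizes used by the test suite

The suite runs studies of 2–10 subjects for functional checks, 100
seeded occlusion tests for calibration accuracy, a 1,000-replicate Monte
Carlo for noise propagation (checked against first-order error
propagation through κ·ΔCVP, including the calibration-noise term), and a
250-subject study (500+ replicates per stratum) for the null-model check
that accuracy is independent of volume status and chest-wall compliance.
These sizes give comfortably stable estimates at the asserted tolerances
while keeping a full run under a minute on one core.

## Known limitations

- The simulator's linear, instantaneous transmission makes exact
  recovery achievable; real venous compliance is nonlinear near vessel
  collapse and the method's accuracy at CVP extremes is untested here.
- How long κ remains valid after an occlusion test is unknown; the
  simulator holds T constant within a condition, so calibration drift is
  out of scope.
- The cardiac-cycle averaging assumes a quasi-periodic cardiac artifact;
  arrhythmia would push readings toward the plain-mean fallback.
- Absolute pleural (and hence absolute transpulmonary) pressure is out
  of scope by design: only tidal swings are estimated.
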