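# Methods

## Scope and model

The package estimates beat-to-beat systolic and diastolic blood pressure
(SBP/DBP, mmHg) from a finger photoplethysmogram recorded over a
rest/exercise/recovery protocol.  The pipeline is: band-pass conditioning
and beat segmentation → skewness-based quality rejection → 17 pulse/SDPPG
features per accepted beat → z-score normalization → RReliefF selection →
windowed recurrent regression → agreement analysis.  Each stage is a module
with a stable text-format interface (CSV + JSON sidecars), so stages can be
run, inspected and tested in isolation.

## Synthetic study conditions

Real beat-level exercise data with continuous reference pressure are rarely
shareable, so the generator emulates the study conditions and provides exact
per-beat ground truth (pressures, fiducial samples, artifact flags).

**Trajectories.** Heart rate follows a first-order relaxation (τ = 60 s)
from the resting rate toward the Karvonen target
(maxHR − restHR)·intensity + restHR with maxHR = 220 − age, intensity 0.7;
SBP relaxes from a 115 mmHg baseline toward +40 mmHg during exercise and
back (τ = 60 s); DBP stays at 72 mmHg plus a ±3 mmHg slow drift.
Beat-to-beat Gaussian noise: 2 mmHg (BP), 1.5 bpm (HR).  Each phase draws
from its own seeded sub-stream, so changing one phase's duration leaves the
others' noise unchanged.

**Waveform.** Each beat is a sum of log-normal-shaped pulses (Gaussian in
ln t, so each peaks exactly at its nominal time): a systolic pulse
(amplitude A1, peak t1 = 0.13 s after the foot), a small fixed mid-systolic
shoulder (0.25·A1 at t1 + 0.09 s) and a reflected diastolic pulse
(A2 = RI·A1 at t1 + ΔT).  The shoulder carries no latent information; it
gives the second derivative the conventional five-wave a–e systolic
microstructure that the smooth two-pulse sum lacks, which matters because
the fiducial detector defines the waves operationally as alternating SDPPG
extrema.  The latent→waveform map is fixed and invertible on clean beats:
A1 = 0.02 a.u./mmHg · (SBP − DBP); ΔT = 0.24 s − 1.2 ms/mmHg · (SBP − 115);
RI = 0.45 at rest/recovery and 0.15 during exercise (the attenuated second
peak of exercise, consistent with lower arterial-wall elasticity at high
pulse pressure).  A least-squares inversion of measured (A1, ΔT) recovers
SBP with RMSE < 3 mmHg at the default noise, so the downstream model
provably has signal to learn.

**Artifacts.** With per-beat probability 0.25/0.70/0.17
(rest/exercise/recovery), a beat is corrupted by baseline wander (0.1–0.5 Hz
sinusoid, amplitude ≥ A1) plus 1–3 negative-going spike transients — the
typical optical-probe-motion signature — and flagged.  Negative transients
and large symmetric wander drive the beat's skewness toward or below zero,
which is exactly the failure mode the SSQI targets.  No per-sample sensor
noise is added by default (`ppg_noise_sd = 0`): beat-level BP/HR noise and
artifacts carry the realism, and the clean-limit geometry stays exact for
sample-level fiducial tests.

**What the generator does not emulate:** real pulse-shape variability
between subjects, respiration coupling, sensor drift, calibration error of
the reference device, and the waveform-BP relationship of actual
vasculature.  Passing tests therefore demonstrate the pipeline's internal
correctness and its ability to recover a known latent pressure signal —
not clinical accuracy on human data.

## Numerical and design choices

- **Segmentation.** Zero-phase Butterworth band-pass 0.5–8 Hz (order 2,
  forward–backward); upstrokes picked on the first difference with an
  adaptive height threshold (25% of the 98th percentile of positive slopes)
  and 0.3 s minimum spacing; feet are the preceding filtered-signal minima,
  refined to the raw-signal minimum within ±5 samples because the 8 Hz
  low-pass rounds the foot corner by a few samples at 125 Hz.  Beats outside
  [0.3, 2.0] s are dropped.
- **SSQI.** Population (1/N) moments, per beat.  Default acceptance
  threshold 0 (clean pulses skew positive).  The SVM mode (linear SVC over
  ssqi, beat length, gain-normalized peak-to-peak amplitude) exists because
  a single fixed threshold is not optimal when the SSQI distribution shifts
  between phases; its three-statistic design is this package's choice.
- **SDPPG.** Savitzky–Golay differentiation, 9-sample window at 125 Hz
  (scaled with fs), polynomial order 4, deriv = 2: order 4 keeps the
  second-derivative error of pulse-band sinusoids (≤ 5 Hz) under 1%,
  where order 3 exceeds 3% at 5 Hz.  Waves a–e are the first five
  alternating extrema (max, min, max, min, max) after the foot; a must be
  positive and b negative or the beat is excluded.
- **Diastolic peak.** Most prominent local maximum (prominence ≥ 5% of the
  systolic amplitude) after the dicrotic minimum.  When the reflected wave
  is merged into the systolic decay — the typical exercise morphology — the
  e-wave time serves as the diastolic surrogate and the beat is flagged;
  outright exclusion would starve the exercise model.  Flagged beats' ΔT is
  a surrogate, not the latent reflection delay, so latent-recovery tests
  use unflagged beats only.
- **Amplitude reference.** Pulse amplitudes are measured relative to the
  beat's foot value; SDPPG amplitudes b–e are normalized by a, a itself kept
  raw.  Per-beat reference BP is the median of the step-function reference
  channel over the beat span.
- **Z-score.** Per-feature mean and sample SD (ddof = 1) fitted on the
  chronological training portion only and reused for validation/test;
  constant features (e.g. sample-quantized wave times on perfectly regular
  synthetic beats) are flagged and excluded with a warning.
- **RReliefF.** All instances serve as anchors in deterministic order
  (random anchor subsampling available, seeded); Manhattan distances, ties
  broken by instance index; rank weights exp(−(rank/σ)²) normalized over
  the k neighbours; target/feature differences range-scaled to [0, 1].
  Elimination is strictly of negative scores — zero is kept.
- **Windows and split.** 10-beat windows, stride 1; a rejected or failed
  beat breaks the run; the target is the final beat's reference pressure.
  The 70/15/15 split is chronological within each recording-phase, and
  windows sharing source beats with an earlier partition are dropped, so no
  beat leaks across the boundary.  A seeded shuffled split is available as
  a flagged alternative.
- **Network and training.** BiLSTM(100) → LSTM(200) → LSTM(400) →
  LSTM(800) → linear head, implemented in numpy (float64) with manual BPTT:
  Glorot initialization (forget-gate bias 1), Adam at lr 0.004, batch 256,
  global gradient-norm clipping at 5, MSE loss, up to 850 epochs with
  best-test-loss checkpointing (early stopping by checkpoint, since long
  training on small data overfits).  Targets are standardized with
  training-set statistics and predictions mapped back to mmHg, so the fixed
  learning rate behaves identically across phases with very different
  pressure ranges.  All randomness descends from one integer seed;
  repeated runs are bit-identical on CPU.
- **`scale` parameter.** Uniformly shrinks hidden units and the epoch
  budget; the `ci` preset (scale 0.25, 2 subjects, 10-min phases) is the
  desk-scale configuration used by the test suite and the acceptance
  script, while `paper` keeps the full-size settings.
- **Metrics.** `R = 1 − MSE_model/MSE_standard` is a coefficient-of-
  determination-style score (named `r_score`, not a Pearson correlation);
  "SD" is the sample standard deviation of errors; RMSE is reported
  alongside.  The accuracy verdict |ME| ≤ 5 and SD ≤ 8 mmHg uses inclusive
  bounds, as standards state limits as maxima.  The elasticity utility
  E = (3/8)(1 + 2r₀/h₀)·Δp/(Δh/h₀) links the attenuated exercise second
  peak to reduced wall elasticity.

## Known limitations

- Separate models per phase and target; the exercise phase usually yields
  too few runs of 10 consecutive accepted beats at a ~70–80% rejection rate,
  so its model is skipped with a warning — the same starvation effect that
  degrades exercise tracking in practice.  End-to-end accuracy checks
  therefore use the recovery phase, which combines real SBP variation
  (relaxation from ~155 to 115 mmHg) with a workable acceptance rate.
- The chronological pooled split is one of several defensible protocols;
  per-subject splitting is not implemented.
- The window length (how many beats of context the regressor sees) is
  configurable, not learned; 10 beats is the default.
- Synthetic-data results bound what the pipeline can do under ideal,
  known-model conditions; they are not evidence of accuracy on human data.
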