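# Methods

This note documents the models, algorithms and defaults of `vigileeg`: what
each stage of the pipeline computes, which choices were genuinely open, and
what passing the test suite does and does not establish.

## Synthetic resting-EEG generator (`vigileeg.synth`)

### Latent vigilance trajectory

The per-second stage sequence is a first-order Markov chain over
(0, A1, A2, A3, B1, B2/3, C). The default transition matrix is the sticky
chain T = s·I + (1−s)·1πᵀ with stickiness s = 0.9 and stationary mix
π = (0.18, 0.26, 0.08, 0.05, 0.14, 0.29, 0). This construction makes the
stationary distribution explicit (it is exactly π) and gives geometric stage
dwell times of roughly 1/((1−s)(1−πᵢ)) ≈ 12 s — the slow waxing and waning
of arousal that 1-min interval metrics assume. Stage C has zero stationary
mass by default: sleep onset is not reached in a 20-min resting recording of
an awake participant. π was chosen so that relaxed wakefulness (A1) and
delta/theta drowsiness (B2/3) are the two most frequent stages, matching the
clinical picture in depressed adolescents, while keeping the total A-stage
share safely below one half (see the threshold discussion below) and every
decision boundary of the classifier populated.

### Signal rendering

Each of the 25 EEG channels is a sum of three band-limited Gaussian noise
carriers (delta-theta 2–7 Hz, alpha 8–12 Hz, beta 13–30 Hz; order-4
zero-phase Butterworth on white noise, normalized to unit RMS) multiplied by
a per-second gain envelope. Gains come from a stage × band × scalp-region
table (µV RMS); envelopes are cross-faded at second boundaries with a
raised-cosine kernel of ≈100 ms so stage transitions do not inject
broadband clicks into the segment periodograms. The default gain table
encodes the staging signatures:

* A1: posterior alpha 20 µV vs frontal 5 µV (posterior dominance);
* A2: frontal 14 vs posterior 12 (anterior spread, ratio inside the
  (1, 1.5] substage window);
* A3: frontal 16 vs posterior 10 (frontal dominance);
* B1: low-voltage (alpha 3, delta-theta 5);
* B2/3: delta-theta 18, i.e. RMS ≥ 2× its alpha; stage 0: beta 8, low
  amplitude overall; C: like B2/3 plus a 13.5 Hz spindle burst on central
  channels.

Gain magnitudes were fixed once from a signal-to-noise analysis of the
staging rules: a 1-s Hann periodogram band-power estimate has a relative SD
of roughly √(2/(2·#bins)) per channel (≈45% for the 5-bin alpha band),
shrinking ≈√5 when averaged over a 5-channel region of interest. The
defaults place each stage's discriminating feature several such SDs from its
decision boundary — separable on average, with genuine overlap second by
second (A2/A3 sit deliberately close to their ratio cut points).

### EOG, ECG, artifacts

The EOG channel carries a broadband floor (8 µV RMS, 0.5–15 Hz), a slow
drift floor (5 µV RMS, 0.1–1 Hz), slow eye movements — 0.2–0.6 Hz
oscillations of 140–200 µV peak-to-peak, 3–8 s long, Poisson-placed at 10
events per minute of drowsy (B-stage) time — and blink transients (raised-
cosine pulses, ~200 µV, 0.2–0.35 s) at 12 per minute of wake time. SEM
events never occur during wake seconds and blinks never during drowsy
seconds; this contract is what lets classifier tests use the event lists as
ground truth. Blinks leak into frontal EEG channels (gain 0.6 at Fp1/Fp2,
0.24 at F3/F4), consistent with the near-equal amplitude of blink artifacts
at Fp electrodes and EOG in real recordings. The ECG channel is a ±800 µV
QRS-like impulse train at 70 bpm with 5% beat jitter; a 15 Hz low-passed
copy leaks into every EEG channel at gain 0.05 (cardioballistic coupling is
mechanically low-passed). Gross artifacts are 600–1000 µV 1–10 Hz bursts on
at least eight channels, one second long, at 1/min; their second indices are
recorded in the ground truth.

What the generator does **not** emulate: volume-conducted spatial
correlation between channels (each channel's background is independent),
1/f spectral slopes, non-stationarity within a second, real eye-movement
morphology, or electrode drift. Consequences: independent channel noise is
the *hardest* case for ICA-based artifact separation (there is no low-rank
background subspace), but the easiest case for region-averaged band power
(averaging reduces variance by √channels). Passing tests therefore show the
chain is correct under the stated statistical structure, not that its
numeric agreement would transfer unchanged to real recordings.

### EDF output

Recordings are written as 16-bit EDF (1-s data records, physical units µV,
±4000 µV range → ≈0.12 µV quantization step) with a TSV sidecar (1-based
second, true stage, artifact flag). The writer is a minimal EDF implementer;
round-trips are verified in tests against mne's independent EDF reader.

## Preprocessing (`vigileeg.preprocess`)

* **Filtering**: zero-phase order-4 Butterworth band-pass 0.5–70 Hz plus a
  50 Hz notch (Q = 30) on EEG and ECG. The EOG channel keeps a 0.1 Hz
  high-pass edge instead: an order-4 zero-phase 0.5 Hz high-pass attenuates
  a 0.3 Hz slow eye movement to ~2% amplitude, which would make the
  0-versus-B1 distinction impossible downstream. Recordings shorter than 3×
  the low-edge impulse-response scale (6 s at 0.5 Hz) are rejected.
* **Segmentation**: non-overlapping 1-s segments, trailing partial second
  discarded. Segments are 0-based internally and 1-based in all emitted
  tables.
* **Artifact rules** (replacing visual inspection, thresholds configurable):
  a segment is an artifact if any EEG channel exceeds ±100 µV, jumps more
  than 50 µV between samples, or is flat (range < 0.5 µV). Flags carry
  machine-readable reasons and are monotone in their thresholds.
* **Stereotyped-artifact removal**: FastICA on the EEG channels; a component
  is excluded when its time course correlates (|r| > 0.6) with the slow
  (0.1–1 Hz) EOG, the fast (1–15 Hz) EOG, or the ECG. Band-splitting the EOG
  reference matters: blink components correlate weakly with raw EOG whenever
  slow drift and eye movements dominate the reference variance. The 0.6
  default reflects a measured ceiling: with independent per-channel
  background EEG, an artifact component's time course carries projected
  background noise, capping attainable |r| near
  √(leak_var/(leak_var+noise_var)) ≈ 0.7 at realistic blink amplitudes.
  Background components score below 0.2, so the margin is comfortable.
* **Graphoelement screening**: spindles are sigma-band (12–16 Hz) envelope
  exceedances of 2× the recording median lasting 0.5–3 s with an absolute
  10 µV floor — the upper duration bound and floor reject sustained
  beta-rich wakefulness, which is elevated sigma activity but not a spindle;
  K-complexes are biphasic 0.5–4 Hz deflections > 100 µV peak-to-peak with
  lobes of compatible duration. Detections overlapping artifact-flagged
  segments are discarded (high-amplitude bursts trivially satisfy both
  criteria). Flagged segments become eligible for stage C.

## Vigilance staging (`vigileeg.classifier`)

Band powers are Hann-tapered 1-s periodograms integrated over inclusive
1 Hz bins, averaged over region-of-interest channels (posterior alpha: P3,
P4, Pz, O1, O2; frontal alpha: Fp1, Fp2, F3, F4, Fz; delta-theta: all EEG
channels). Source localization of the original tool is deliberately replaced
by this sensor-space surrogate: the anterior–posterior alpha shift that
defines the A-substages survives in channel space, and every ROI is
configurable. No claim of numeric fidelity to VIGALL is made — its
band edges, thresholds and inverse-solution parameters are not published.

Adaptive thresholds are fitted per recording on artifact-free segments
(≥ 60 required): alpha and delta-theta thresholds are 2.0× the 25th
percentile of the respective feature; the SEM peak-to-peak threshold is
5.0× the 25th percentile of the 3-s slow-EOG window amplitude. A low
reference quantile is used rather than the median because the median is not
robust to the composition it is meant to normalise: in alpha-rich
recordings — the clinical norm, and a 2σ fluctuation of the default chain —
the A-stage share exceeds one half, the median lands inside the A-stage
alpha mass and the threshold overshoots by an order of magnitude; likewise
the recording-median SEM amplitude is inflated by the SEM events themselves.
The 25th percentile is a noise-floor statistic under all compositions that
occur in practice. All statistics are scale-equivariant, making the stage
sequence invariant under global amplitude rescaling (standalone
`detect_sem` keeps an absolute 100 µV default for single-segment use).

Expected error modes at the defaults, visible in the examples: A2 ↔ A1/A3
confusion (the power-ratio window (1, 1.5] is ≈1 relative SD wide) and
B1 → 0 misses in B1 seconds not covered by a slow eye movement. Both are
inherent to the decision list, not implementation artifacts.

## Outcome metrics (`vigileeg.metrics`)

The numeric stage mapping (0 → 7 … C → 1) is a consistency-checked
assumption, not a published constant: it reproduces the magnitude and
ordering of the study's printed mean-vigilance descriptives (an A1-heavy
baseline with mean level ≈ 4) and follows the wakefulness-to-drowsiness
ordering of the stages.

Interval labels are modal stages over sliding 60-s windows (window k =
segments k…k+59, 1-based), ties broken toward the drowsier stage
(conservative for a drowsiness index); windows with fewer than 30
artifact-free segments are unscorable. The arousal stability index evaluates
its criteria over three equal thirds of the timeline ("first/second/last
10 min" is contradictory for a 20-min recording — with literal 10-min
windows the second and last coincide; a literal `minutes` mode is provided
for 30-min recordings). Criteria are evaluated ascending (deepest, earliest
decline first), so a globally alpha-rich recording cannot mask an early
B2/3 episode; the printed-table (descending) order is available as an
option, and the two differ exactly on all-wake recordings (7 vs 8). If no
criterion matches, the B1 rules are re-evaluated with B1 and B2/3 pooled,
and failing that the score is 7. Both the interval and a segment-fraction
counting mode are provided.

One documented subtlety: the monotonicity property "an earlier decline never
scores higher" is exact in segment-fraction mode but can be violated at
knife-edge cases by the interval mode's discretization (thirds of 241
windows are 80/80/81, and a modal label flips on a ±1-segment margin);
property tests therefore run in segment-fraction mode, and the interval
mode is validated on worked examples.

## Statistics (`vigileeg.stats`)

Routine tests delegate to scipy (t-tests, exact small-sample Wilcoxon p,
chi-square, Pearson) and pingouin (mixed ANOVA); the package authors the
noncentral-t machinery, the Wilcoxon normal approximation with tie
correction and continuity-corrected Z, and all effect-size attachments.
Design choices:

* **MDE / power**: exact noncentral-t, power(δ) computed from the
  noncentral CDF with an underflow guard on the opposite tail, solved by
  Brent root-finding to 10⁻⁶ in d. This reproduces the study's printed
  design values (1.366 for 9 vs 10; 0.70 and 0.66 for 18 and 20 pairs).
* **Equivalence**: 95% noncentral-t pivot CI for pooled Cohen's d;
  EQUIVALENT iff both bounds fall strictly inside (−SESOI, +SESOI). The
  pivot CI agrees with a 10⁵-replicate bootstrap within 0.05 in tests. The
  study's own printed CIs could not be reproduced under either pooled or
  unpooled conventions and are not asserted.
* **Paired tests**: the study prints t(16) for its paired tests, but the
  printed statistics are only consistent with n = 9 pairs (df = 8); this
  package always uses actual pair counts and reports the actual df.
* **ANOVA effect size**: d = 2f with f = √(η²p/(1−η²p)); the conversion is
  printed alongside so no reader mistakes it for a mean-difference d.
* **Multiple testing**: none is applied, matching the analysis this package
  mirrors; `analyze` runs a fixed battery and reports everything it runs.

## Study pipeline (`vigileeg.pipeline`)

`run_study` simulates a 9 + 10 cohort with pre/post recordings per
participant. Per-participant arousal traits are Gaussian log-tilts
(SD 0.15) of the wake-stage mass, shared across timepoints — this induces
the within-subject correlation a paired design exploits. A treatment effect
is a further wake tilt at post; the documented calibration is that a tilt of
1.2 at 10-min recordings yields a generator-level paired effect of
|dz| ≈ 1.5 on mean vigilance. BDI-II depression scores are drawn from a
truncated normal (mean 31.5, SD 11, range 0–63) with a configurable
correlation (default −0.5) to B2/3 occurrence, exercising the
depression–arousal correlation analysis.

Two modes: `trajectory` (latent stage sequences scored directly; used for
statistical experiments) and `full` (signal rendering, preprocessing, ICA
and staging per recording). The calibration experiments run in trajectory
mode at reduced recording lengths — 200 null studies at 300 s for the
type-I error of the paired t (expected 5% ± binomial noise), 100 replicates
at 600 s for sign recovery of the injected effect — sizes chosen to give
stable Monte-Carlo estimates while the signal path is validated separately
on full-length recordings.

## Numerical notes

* Periodogram band edges are inclusive on the 1 Hz grid; the total-power
  band (0.5–70 Hz) integrates bins 1–70.
* `filtfilt` squares magnitude responses; all stated attenuations account
  for the double pass. Filter-quality tests measure away from edge
  transients.
* FastICA uses unit-variance whitening, tolerance 10⁻⁴, up to 1000
  iterations, seeded; reconstruction with no excluded components is exact to
  numerical precision.
* All simulation randomness flows from explicit integer seeds through
  numpy Generators; fixed seeds give bit-identical trajectories, signals and
  reports.
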