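# Methods

## Problem and overall design

Wearable activity monitors record raw triaxial acceleration in g, but two
monitors worn simultaneously do not report identical signals: sensor
sensitivity (gain), zero-g offset, analog low-pass filtering, quantization
and clipping all differ between models. This package quantifies the
practical consequence of such differences for activity-type recognition:
a classifier trained on features from one device may lose accuracy when
applied to another device's data, and whether it does depends on the
*kind* of features used.

The pipeline has three stages:

1. **Shaker calibration** — simulated orbital-shaker trials with a known
   centripetal-acceleration ground truth quantify the inter-device output
   difference directly.
2. **Feature extraction** — time-domain (TD) and frequency-domain (FD)
   feature vectors are computed on 20-s windows of the vector magnitude
   (VM) of simulated wrist-activity bouts.
3. **Transfer evaluation** — random-forest activity classifiers are
   trained per device and feature set, and evaluated same-device and
   cross-device under leave-one-subject-out (LOSO) cross-validation.

The central mechanism is a gain-invariance asymmetry: a uniform gain `c`
rescales every TD magnitude feature (mean, SD, percentiles) by `c` while
leaving the FD shape descriptors (dominant frequency, band-power ratio,
cumulative-spectral percentiles f10/f90) unchanged. A TD model therefore
inherits the training device's calibration; an FD model largely does not.

## Shaker model and oracle

An orbital shaker translates its tray in a horizontal circle of radius
`r` (default 0.0508 m) at platform speed `rpm` without rotating it. A
mounted, non-rotating accelerometer therefore sees

- in-plane axes: `A·cos(ωt + φ0)` and `A·sin(ωt + φ0)` with
  `ω = 2π·rpm/60` and `A = ω²r` (converted to g with `g = 9.81 m/s²`),
- gravity axis: constant 1 g,

so the triaxial VM is constant at `√(A² + 1)`. Platform speeds are
configured in rpm — defaults {40, 80, 140, 200, 240} — because the
published centrifugal-acceleration table is reproduced by integer rpm
values with `g = 9.81`, whereas the rounded nominal Hz labels
(0.7/1.3/2.3/3.3/4.0) are not; the Hz labels are retained for reporting.
At 200 rpm the closed form gives 2.2715 g where the reference table
prints 2.272 g (last-digit rounding of an unprinted intermediate); the
tests allow this half-ulp.

**Peak extraction.** The analysis window (default the second minute of a
2-min trial, excluding spin-up) is partitioned into half-revolution
segments of `fs·60/(2·rpm)` samples; the per-segment maximum of the
absolute in-plane signal is the "peak" (two per revolution, one on either
side of the 0-g baseline), and their mean is compared with the oracle.
Segment-max extraction was chosen over zero-crossing detection because it
is robust to noise. At 80 Hz the sampling grid bounds the peak error of an
ideal trial below 0.5% at every default speed; the acceptance suite
verifies this bound.

**Device comparison statistic.** Trial-level mean VMs are compared with a
two-sided permutation test (default 10 000 shuffles, seeded), with the
trial as the exchangeable unit; the permutation p-value includes the
observed statistic, so its floor with 3+3 trials is ≈0.1 and with 10+10
trials far below 0.05. A trial-level permutation test was chosen as the
simplest defensible self-contained analogue of a mixed-model contrast on
repeated trials. Percent difference uses device A (the reference device)
as denominator, stated in all reports.

## Device model

Applied per axis in order: gain → offset → single-pole low-pass (optional)
→ additive white Gaussian noise → uniform mid-tread quantization over
±`range_g` (optional) → clipping to ±`range_g` (default ±6 g, the dynamic
range of the monitors being emulated). Real monitor filters are
proprietary, so the simplest parametric stand-ins are used; the model is a
configurable abstraction of a sensor signal path, not a reverse-engineered
device.

Defaults:

| parameter | device A ("AG") | device B ("GE") | rationale |
|---|---|---|---|
| gain | 1.00 | 1.06 | sensitivity mismatch |
| offset (g, per axis) | 0.00 | −0.02 | zero-g offset mismatch |
| noise σ (g) | 0.01 | 0.01 | MEMS noise floor at 80 Hz |
| low-pass / ADC | off | off | hardware-specific, exposed in config |

The B-device parameters were fitted once so that its mean-VM elevation
over device A *increases* with shaker speed, from ≈4.0% at 40 rpm to
≈5.8% at 240 rpm — the 3.5–6.5% increasing pattern reported for real
hardware. A pure gain produces a flat elevation and a positive offset on
all axes produces a *decreasing* one (and slightly exceeds 8% at the
lowest speed), so the gain-plus-negative-offset combination is the
smallest model with the right signature. It remains an acknowledged
approximation: the real inter-device peak differences are not a pure
gain/offset law.

## Activity-bout generator

Each of the eight conditions (computer work, cleaning, throwing, vacuuming,
walking at two speeds, running at two speeds) is a sum, per axis, of

- sinusoidal **harmonics** `(f, a, cv)` with slowly varying amplitude
  (per-second lognormal envelope with coefficient of variation `cv`),
  distributed over the axes with fixed weights (1.0, 0.6, 0.3) and
  independent phases;
- Poisson-timed **bursts** (200-ms half-sine pulses in random 3-D
  directions) for intermittent movement;
- white **baseline** noise; plus 1 g on the gravity axis.

A per-(subject, activity) multiplicative vigour factor
`exp(N(0, subject_cv))` creates between-subject variability. Defaults
follow the qualitative structure of the emulated protocol: walking is
rhythmic with step harmonics inside the 0.6–2.5 Hz locomotor band
(1.9 Hz slow, 2.4 Hz brisk), running is rhythmic above it (2.7/3.0 Hz,
larger amplitude), vacuuming is a fast low-amplitude repetitive movement
(3.9 Hz), cleaning is intermittent (1.2 bursts/s of 0.45 g over a weak
1.9 Hz ambulatory component — deliberately overlapping slow walking in
amplitude, the dominant cross-device confusion channel), throwing is
sparse large bursts, and computer work is near-still. `subject_cv` is 0.2
for locomotion and 0.3 for the unconstrained activities.

The generator emulates the *feature-space geometry* of the protocol — the
relative rhythmicity and magnitude of the eight conditions — not
biomechanics: there is no gait dynamics, soft-tissue artefact, posture
change or device orientation drift. Consequently the synthetic transfer
effect is cleaner and larger than on human data (cross-device TD accuracy
drops by roughly 30 points under the default mismatch versus ~8 points
reported for real monitors), and passing tests demonstrate the mechanism
and the pipeline's correctness, not hardware-level effect sizes. The
same-device accuracies (~94–96%) are in the range reported for real
wrist data.

**Seed policy.** All randomness flows from one master seed through named
child streams (`SeedSequence` keyed by hashed tags). The paired devices in
a study share the true-signal stream (simultaneous wear); sensor-noise
streams are keyed by device *parameters*, so two identical device models
record byte-identical signals and any parameter difference decouples the
noise.

## Features

Computed on the VM channel of each 20-s window (per-axis extraction is
available behind the `channel` argument but is not the default; a single
channel keeps the feature count equal to the canonical TD/FD lists).
Windows are cut from the last 60 s of each 2-min bout — 3 per bout, 24 per
single-speed activity across 8 subjects, 48 for the merged walk and run
classes — with a floor rule discarding any trailing remainder.

- TD: sample mean, SD (n−1), percentiles (linear interpolation), lag-1
  autocorrelation `Σ(xₜ−x̄)(xₜ₊₁−x̄)/Σ(xₜ−x̄)²` (0 for a constant window).
- FD: periodogram of the demeaned window, no taper, normalized so spectral
  power sums exactly to the biased variance (Parseval is an identity, not
  an approximation, under this normalization); mean of the raw signal;
  total power; argmax frequency (ties toward the lower bin); inclusive
  band power in 0.6–2.5 Hz; band ratio (0 when total power is 0); f10/f90
  as the smallest frequencies where cumulative power reaches 10%/90%.
  The "spectral percentile" reading of f10/f90 follows the cumulative-power
  description of the feature set; resolution is fs/n = 0.05 Hz.

## Transfer evaluation

Random forest (500 trees, √d features per split, unlimited depth, fixed
seed); hyperparameters are exposed in `ModelSpec`. LOSO is at the subject
level to avoid same-bout leakage, and the held-out subject is excluded
from the training table in *both* same-device and cross-device cells, so
all four cells per feature set are computed on identical folds. The eight
cells {FD, TD} × {A→A, A→B, B→B, B→A} share the classifier seed.
Accuracies are reported in percent to one decimal; same-vs-cross cell
pairs are compared with a pooled two-proportion z-test (z defined as 0
with p = 1 when the pooled proportion is degenerate).

The headline property — the TD cross-device drop strictly exceeds the FD
drop — is checked over master seeds 0–9 and holds in ≥9/10; the
acceptance script recomputes the same sweep from its `--seed`.

## Numerical choices and edge cases

- Half-open windows `[start, end)`; sample indices by rounding
  `t · fs`.
- Quantization is uniform mid-tread with step `2·range_g / 2^bits`.
- The low-pass is a single-pole IIR initialised at the first sample to
  avoid a spin-up transient.
- Permutation p-values use the add-one convention (never exactly 0).
- The two-proportion z-test is compared against the exact conditional
  (hypergeometric) oracle on the mid-p scale with documented tolerance
  0.2 at n ≤ 12 — the discreteness at such n dominates the normal error.
- Problem sizes in the tests and acceptance script are the study defaults
  (8 subjects × 8 activities × 2 devices × 120 s at 80 Hz; 10 trials per
  shaker speed; 10-seed transfer sweep), chosen to match the emulated
  protocol while keeping a full run in minutes on one core.

## Known limitations

- Whether the original feature extraction used VM or per-axis channels is
  not documented; VM is the default here and the choice is configurable.
- The gain/offset device model cannot reproduce non-monotone per-speed
  peak differences observed on real hardware.
- Human-protocol accuracy values from real devices are not reproducible
  from synthetic data; the pipeline reproduces the qualitative contrast
  (FD transfers, TD does not), not the printed accuracies.
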