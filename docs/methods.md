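# Methods

This note documents the models, conventions, and design choices behind the
package, in the spirit of the model-documentation pages of simulation and
statistics libraries. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The paradigm and what the generator emulates

The simulated experiment is an unattended probe paradigm: a lateralized
target whose color is drawn trial-by-trial from one of two blockwise
target-color pairs (red/green or blue/yellow), discriminated either by
color or by orientation in alternating blocks, with an irrelevant probe in
the opposite hemifield drawn from five colors (the four possible target
colors plus one color that is never a target). Relative to the block's
pair, a probe is *PC* (matches the present target color), *DC* (matches
the distracting alternative), the extra never-target color, or a
*non-target* color. Each subject runs 6 blocks per task × 180 trials with
a 300 ms stimulus and a uniform 1000–1200 ms inter-stimulus interval at a
254.31 Hz sampling rate. Block order honors the pseudorandomization rule
(the pair alternates every block, the task changes every second block)
with the four possible orders cycled across subjects. With the probe
uniform over five colors this yields 216 expected trials per type per
task, and 27 expected occurrences of each unique display (target color ×
orientation × probe color) within the three blocks sharing a color pair.

### Behavior model

RT = base + DC cost · 1[color-task DC] − repetition benefit · 1[repeat]
\+ coupling · (per-trial early-amplitude deviate) + Gaussian noise,
truncated at 50 ms; correctness is Bernoulli. Defaults: base 400 ms,
sd 60 ms, DC cost 12 ms, repetition benefit 40 ms, accuracy 0.95 — chosen
so every task × trial-type cell stays under 410 ms mean RT and above 92%
accuracy, the regime the analysis assumes (fast, highly accurate
performance). The deviate (sd 0.8 µV, coupling 50 ms/µV) is shared with
the EEG synthesis: trials whose early distractor negativity happens to be
larger respond faster. This shared-deviate construction is a generator
assumption built to produce the fast/slow amplitude pattern the RT-split
analysis targets — it is a property of the simulation, not a claim about
mechanism. With these defaults the latent amplitude–RT correlation is
about 0.5, so the fast-minus-slow early-amplitude contrast is several
tenths of a µV — the scale on which the split analysis operates.

### EEG model

Each trial adds, at the analysis channels PO3/PO7, a fixed biphasic
probe-evoked template (Gaussian positivity at 100 ms, negativity at
170 ms; morphology is configurable and carries no condition information)
plus boxcar condition deltas:

- early window 73–96 ms: amplitude −0.6 µV + per-trial jitter, on
  color-task DC trials only;
- late window 167–254 ms: −1.2 µV on PC trials (scaled by 0.5 in the
  orientation task, where color is task-irrelevant) and −0.5 µV on
  color-task DC trials.

Amplitudes are at the few-tenths-to-1 µV scale typical of feature-based
attention difference waves. Noise is white (sd 6 µV) plus 1/f (sd 3 µV,
exponent 1), independent per channel; blink transients (120 µV Gaussian
bumps, 40 ms width, rate 0.05/trial) hit all scalp channels; mastoids
carry noise only. With the default 100 µV rejection threshold the blink
rate puts the rejection fraction near 5%, matching what a well-behaved
adult EEG session produces. The generator does **not** emulate alpha
oscillations, spatially correlated noise, ocular drift, channel
covariance, or non-stationarity — so passing tests demonstrate the
correctness and calibration of the *analysis* under the generator's
assumptions, not robustness to every property of real EEG.

Boxcar deltas (rather than smooth bumps) make the injected contrast
exactly recoverable: with noise off, the mean of the DC-minus-non-target
difference over the early window equals the injected amplitude to
float precision, which anchors the linearity tests of the whole chain.

## Conventions

- **Windows** are left-closed right-open on the sample grid everywhere
  (epochs [−200, 700), baseline [−150, 0), effect windows, mean
  amplitudes, the tested range). At 254.31 Hz the epoch holds 229 samples.
- **Time origin**: the onset sample is the first sample at or after
  `onset_s × f_s`; indexing is 0-based. Template injection and epoch
  extraction share this convention, so injected and measured windows
  align exactly.
- **Re-referencing**: acquisition is assumed online-referenced to the
  right mastoid; subtracting weight × (recorded left mastoid) from every
  channel implements the linked-mastoid equivalent. The weight defaults
  to 0.5 and is configurable, since "weighted mean of the mastoids"
  admits different weightings.
- **Artifact rejection** screens max-minus-min over the full epoch on
  *all* scalp channels (not only the analysis pair); mastoids are the
  reference and are not screened. The threshold defaults to 100 µV,
  configurable over the 70–115 µV range typical of per-subject settings.
- **Eligibility**: incorrect and out-of-range-RT trials are excluded from
  ERP averages; incorrect trials still count against accuracy.
  No filtering is applied in preprocessing — the acquisition band-pass is
  emulated in the generator only, and statistics run on unfiltered data;
  the 23 Hz Gaussian smoother (σ_t = √(ln 2 / (2π² f_c²)) ≈ 8.15 ms) is
  display-only and flags its output as such.

## Statistics

The two-way within-subject ANOVA uses the standard balanced decomposition
with each effect tested against its subject-interaction error term. The
Greenhouse–Geisser epsilon is the classical estimator from the scatter
matrix of orthonormal-contrast scores (Helmert contrasts; ε = 1 exactly
for 2-level effects); corrected *p*-values use ε-scaled degrees of
freedom, and the corrected *p* is floored at the uncorrected *p*. The
implementation is validated against pingouin's independently coded
general-linear-model routine to |ΔF| < 1e−6 on random designs, and against
the paired-*t*-squared identity for 2-level factors. Degenerate inputs are
handled explicitly: sums of squares at the level of float rounding noise
give F = 0, and a zero-variance paired difference yields p = 0 (flagged)
or p = 1 rather than a division error.

The sliding scan assigns each tested sample the mean of the
`window_samples`-wide window starting there (left alignment; a centered
alignment is available as an option, since "sample-by-sample with a
3-sample window" does not pin the alignment), runs the ANOVA per window,
and applies the corrected-alpha run-length rule: intervals are maximal
runs of ≥ 5 consecutive windows with p below
`1 − (1 − alpha0)^(2 f_c / f_s)` (0.0200 at the default rates). Windows
that would run past the tested range are skipped. GG correction is applied
inside the scan by default with a switch to disable it, since either
reading of the procedure is defensible. The window mean is tested (not
"all three samples individually significant" — the alternative reading);
the choice is recorded here and exposed through `window_samples`.

Trailing design decisions in the splits: the RT-median split excludes
trials exactly at their display's median (only "faster" and "slower"
trials are tagged); assigning ties to the slow bin is available as a
sensitivity option. Quartiles are rank-based with deterministic boundary
handling so bins have integer sizes. Splits are computed after behavioral
filtering but before artifact rejection; conditional averages use the
intersection with artifact-free epochs.

## Source stage

The MNLS inverse `W = Lᵀ(LLᵀ + λI)⁻¹` operates on toy forward models
(random full-rank, ring geometry with distance-decaying gains, or
identity). λ defaults to `trace(LLᵀ)/n_sensors × 0.01`; the stage makes no
claim of numerical equivalence to any production source-analysis package —
it reproduces the *structure* of the analysis (distributed inverse on
averaged data, ROI strength as mean |current|, array repositioning as
inverse-then-forward projection) with fixed-orientation scalar sources, no
depth weighting, and no noise-covariance whitening.

## Problem sizes of the simulation studies

The property suites and `scripts/acceptance.py` run dataset ensembles at
sizes chosen to balance statistical resolution against desk-scale runtime:

- **Effect recovery / RT-split sign recovery**: 22-subject datasets at the
  full per-cell trial counts (6 × 180 per task) on a compact 4-channel
  montage (PO3, PO7, both mastoids) — the montage does not enter the
  pooled-channel statistics beyond re-referencing and rejection. The test
  suite uses 50 datasets; the acceptance script 20.
- **Null control**: effect-free datasets with reduced trial counts
  (2 blocks × 30 trials), because the false-positive level of an exact
  F test does not depend on the trial count; 200 datasets in the test
  suite, 40 in the script.
- **Repetition-benefit recovery** is assessed per pipeline run against
  that run's own standard error. The estimator carries a small downward
  bias (well under one standard error at these trial counts) because the
  anticipatory-RT exclusion clips more of the faster repeat distribution
  than of the slower switch distribution.

## Known limitations

- The generator's effect amplitudes, noise levels, and the amplitude–RT
  coupling are stylized; per-trial amplitude variability of attention
  effects in real data is not well constrained, so these remain
  configurable rather than canonical.
- The ANOVA machinery is restricted to balanced, complete two-way
  within-subject designs (no imputation, no between-subject factors).
- No cluster-based permutation statistics; the corrected-alpha run-length
  rule is the only multiplicity control, as in the analysis the package
  implements.
- HDF5 round trips store voltages as float32; analyses that difference
  large offsets should not rely on sub-µV precision after a round trip.
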