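# Methods

This note documents the models, parameter choices and numerical conventions
behind `plight_gaze`, and what the synthetic validation does and does not
establish.

## Stimulus model

**Procedural walker.** Biological motion is stood in for by a deterministic
sum-of-sinusoids skeleton: 15 markers at canonical joint positions, each
oscillating at the gait fundamental and its second harmonic, limb markers
swinging more than trunk markers and left/right limbs in anti-phase.
Signals are evaluated at the frame index modulo the gait period, so
periodicity is exact to the bit — every downstream computation
(autocorrelation, scrambling, ROI geometry) depends only on periodicity and
dot geometry, not on biomechanical fidelity. Defaults: 4 s clips at 120
fps, gait period 100 frames (≈ 833 ms), 15 dots. The dot count is a
conventional choice for point-light walkers; trial clips span roughly 4° of
visual angle per figure.

**Dominant period.** Each dot's x and y signal is mean-centered; the biased
sample autocorrelation (normalized to 1 at lag 0) is averaged over all dots
and axes, and the integer-lag argmax inside [250 ms, 2000 ms] is returned,
rounded to the nearest millisecond. The biased estimator's linear taper
makes the smallest period multiple the global peak; its cost is a possible
±1-frame shift for long, flat-peaked periods (150 frames → 1242 rather than
1250 ms on a 480-frame clip). No interpolation is used: integer lags keep
the estimator exactly checkable against a brute-force lag scan.

**Phase scrambling.** Per dot, an offset is drawn uniformly from ± half the
dominant period (833 ms → ± 417 ms, rounded half-up), converted to whole
frames, and the dot's one-period template is shifted cyclically. Cyclic
(wrap-around) shifting — rather than truncation — preserves each dot's
visited positions and frame-to-frame displacement multiset exactly, so
local motion energy is identical between scrambled and intact stimuli.
Sub-frame offsets are not simulated; at 120 fps they are far below gaze
measurement resolution.

**Rotational control.** Frame 0 is treated as a rigid planar point set at
depth 0 and rotated about the vertical axis through its *centroid* at
constant speed 2π per gait period, rendered by orthographic x-projection.
The axis placement and projection are this package's choices: an upright
walker's spine is close to the dot centroid, and orthographic projection
keeps the control exactly checkable (frame 0 reproduced at every full
revolution, x-offsets negated at half). No depth foreshortening is
simulated.

**Trial sets.** 60 trials in 6 blocks of 10; the biological side is exactly
counterbalanced (30 left / 30 right, seeded order); controls are scrambled
or rotational per a mix fraction (default 0.5); inter-stimulus gaps are
drawn uniformly from 1.5–2 s, during which a central attention-getter is
assumed. Clips are recentred on ± width/4 so the two dot clouds never
overlap on a 1920×1080, 23-inch screen viewed from 60 cm (≈ 39.5 px/deg,
linear small-angle conversion).

## Gaze generator

The generator emulates a 30 Hz remote binocular tracker. Gaze is an
alternating fixation/saccade process:

* during inter-stimulus gaps gaze rests on the screen center;
* each trial's first on-stimulus fixation starts at onset + latency, drawn
  from a normal (SD 150 ms within participant) truncated at one sample
  interval;
* fixations target a random dot of one side, the biological side with
  per-participant probability `p_bio` decided **per fixation** (looking
  time accrues per fixation in preferential-looking data); durations are
  Gamma(shape 4) with mean 350 ms; saccades last 40 ms with linear
  interpolation between targets;
* both eyes get independent Gaussian position noise (default 0.15°);
* tracking loss forms alternating tracked/untracked runs with geometric
  lengths (untracked-run parameter 0.4, i.e. mean ≈ 2.5 samples), the
  tracked-run mean set so the long-run tracked fraction equals `p_valid`.

A ground-truth event log (fixations with sides, per-trial first-fixation
latencies, realized participant-level parameters) accompanies every
recording; it is the truth set for detector recall and metric-recovery
tests.

**Participant heterogeneity.** Participant-level parameters are drawn from
normals truncated *symmetrically* around the preset mean (rejection within
± min(3σ, distance to the admissible bounds)), so preset means are
recovered without truncation bias even near the [0, 1] boundaries. The
between-participant SDs are not reported quantities; they were calibrated
once against the reported standardized effect sizes at the study group
means: `p_bio` SD 0.08 (with ≈ 2.5-point within-participant measurement
noise this yields Cohen's d ≈ 0.9 for the 54.5% vs 61.9% preference
contrast), latency SD 230 ms (d ≈ 0.55 for 649 vs 521 ms), `p_valid`
SD 0.13. Because the TD valid-time preset (0.892) sits close to 1, the
symmetric truncation compresses that group's spread and the valid-time
effect size comes out nearer 0.95 than the reported 0.68 — a known
limitation of bounding a normal at a hard ceiling.

**Cohort presets** (group means carried by the calibration presets):
ASD-like `p_bio` 0.545, `p_valid` 0.800, latency 649.1 ms, n = 121;
TD-like 0.619, 0.892, 521.3 ms, n = 40. Covariates: age from truncated
normals (ASD 14.6 ± 8.0 on [6, 55]; TD 16.4 ± 13.3 on [6, 63]), gender
76% / 65% male, IQ (ASD only) 98.5 ± 20 truncated to [60, 136], and 29
opaque symptom-subscale scores (N(50, 10); the diagnostic total uses
7.6 ± 1.7 on [4, 10]), independent of the gaze parameters — the null
configuration for correlation-calibration tests. Per-participant seeds are
spawned from the master seed by participant index (`SeedSequence.spawn`),
so cohorts are reproducible and participants independent.

**What the generator does not emulate:** saccade main-sequence dynamics,
microsaccades, smooth pursuit of the moving dots, calibration drift, head
movement, or any real coupling between symptoms and gaze. Passing tests
therefore demonstrate that the *pipeline* recovers known ground truth and
that the statistics are calibrated — not that real data would show these
effects.

## Fixation detection

A binocular individual-threshold scheme. Per eye, angular speed between
consecutive tracked samples (deg/s); pairs spanning an untracked sample are
undefined, never interpolated. The cutoff iterates mean + 3·SD of the
sub-cutoff speeds from all defined speeds to a fixed point (relative
tolerance 1e-3); a degenerate constant distribution converges to that
constant. A sample is fixational if both eyes are below their cutoffs on an
adjacent defined interval; a defined above-threshold interval or a tracked
saccadic sample breaks the run, as does an untracked run longer than 3
samples. Runs with fewer than 3 tracked samples are discarded; the centroid
is the mean cyclopean (two-eye average) position of tracked samples, which
halves independent noise. The cited family of binocular-individual-threshold
algorithms is specified here as this concrete, testable variant.

Detector recall against the truth log is ≥ 0.95 for truth fixations the
count rules can represent (≥ 3 tracked samples, no internal gap > 3);
fixations mostly swallowed by tracking loss are unrecoverable by any
detector honoring those rules. Recall is insensitive to noise in
0.1–0.5° up to event-level granularity.

## Metrics

Per frame, each side's ROI is the union of 3.7°-radius circles around its
dots; membership ties between overlapping ROIs go to the side of the
nearest dot (exact ties to the biological side, documented and exercised).
Looking time accrues per tracked fixation sample at that sample's time and
cyclopean position; preference is the *pooled* time ratio over all trials
(the ratio-of-totals reading of the metric). A fixation is assigned to an
ROI when ≥ 50% of its tracked samples fall inside (robust to dots drifting
out from under a fixation); per trial, the earliest assigned fixation per
side defines that side's latency from stimulus onset, and only trials with
any assigned fixation enter the first-fixation denominators. Valid time
counts samples with at least one tracked eye *and* an on-screen position,
over stimulus windows only; off-screen samples count against it. No
center-of-screen gating is applied at onset.

Note one structural property: the per-side latency metrics exceed the
generator's orienting-latency preset by construction, because the side not
fixated first is only reached after at least one further fixation. The
preset is recovered (within one 33.3 ms sample interval, under lossless
tracking) by the latency of the trial's first ROI fixation regardless of
side; under tracking dropout the measured latency inflates slightly because
some first fixations are lost — a real phenomenon in low-valid-time
recordings.

## Statistics

* **ANCOVA**: ordinary least squares `metric ~ group + age + gender`
  (no interactions; covariates constant in a subset are dropped), type-II
  sums of squares, F for the group term; partial η² =
  SS_group / (SS_group + SS_resid); Cohen's d from raw group means and
  pooled SD (not covariate-adjusted — the reproducible default when the
  adjustment status of a reported d is unstated).
* **Signed-rank tests**: zero differences dropped, mid-ranks on ties,
  two-sided p from the normal approximation with continuity and tie
  corrections (standard at n of 40–121); exhaustive sign enumeration serves
  as the test oracle at n ≤ 12. All-zero difference vectors are flagged
  degenerate with p = 1.
* **Partial Spearman**: ranks of x, y and covariates; x- and y-ranks
  residualized on covariate ranks by least squares; t-based p on
  n − 2 − k df. Verified identical to `pingouin.partial_corr`.
* **BH adjustment** is applied to exactly the five primary group tests;
  raw and adjusted p are stored side by side; no other family is adjusted.
* **Severity tertiles**: stable rank (ties broken by participant order),
  splits at n/3 and 2n/3 with remainders to the later groups — n = 121
  gives (40, 40, 41).
* **IQ strata**: [60, 85), [85, 116), [116, 136]; identical to the integer
  closed ranges 60–84 / 85–115 / 116–136, well-defined for non-integer
  synthetic IQs.

The model surface (`PreferentialLookingModel` → `fit()` →
`PreferentialLookingResults`) wraps the same battery; `summary()` prints the
five primary comparisons.

## Problem sizes and runtime

Validation runs use the full study geometry — 60 four-second trials at
30 Hz — with cohort sizes 121/40 for calibrated-mean recovery (five seeded
replicates each, ~1,000 simulated participants per acceptance run) and
reduced cohorts (≤ 40 participants) for structural and property tests.
Statistical calibration properties (null grids, power, p-uniformity) run on
directly drawn participant-level tables (100–200 replicates) rather than
rasterized gaze, since they exercise the statistics, not the simulator.
A full acceptance run completes in a few minutes on one CPU.

## Known limitations

* The walker is kinematically stylized; it shares periodicity and dot
  geometry with motion-captured walkers, nothing else.
* Preference and valid-time recoveries are exact in expectation but carry
  cohort-level sampling scatter of ~0.3–0.6 percentage points at the study
  sizes; recovery tolerances of ±1 point reflect that scatter.
* Valid-time effect sizes are inflated relative to the reported d (see the
  truncation note above).
* The severity grid and correlation grid are validated for calibration
  (null behavior, cell counts) and for chance-level detection at the preset
  means, not against any real symptom-gaze coupling.
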