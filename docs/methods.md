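# Methods

`pdec` analyzes smooth pursuit eye movements (SPEM) recorded while a
participant simultaneously performs an internal mental task — a dual-task
probe of *perceptual decoupling*, the attenuation of sensory-driven
processing when attention turns inward. The package covers the whole chain:
experimental-design generation, synthesis of binocular 1000-Hz gaze/pupil
recordings with known ground truth, event detection, pupillometry cleaning,
per-sample pursuit metrics, 0.5-s time-binning with hierarchical
missing-data exclusion, and a planned-contrast statistics layer. This note
documents the models, parameters, and the design decisions that were
genuinely open.

## The task model

The external task is circular pursuit: a dot on an imaginary circle of
radius r = 5.4 degrees of visual angle (dva), moving counterclockwise at
v = 6.8 dva/s, starting at 12 o'clock. In screen-centered, +y-up
coordinates the target is

    angle(t) = pi/2 + (v / r) * t,     position(t) = r * (cos angle, sin angle)

so the angular speed is omega = v/r ≈ 1.259 rad/s and the path length per
second is exactly 6.8 dva.

The internal task is a 2 (modality: arithmetic, visuospatial) x 3 (workload:
single-task control, low, high) within-subject design. Per modality there
are 30 blocks (10 per workload), each of 9–11 trials; a trial is one mental
operation announced by a 600-ms auditory cue, followed by a 3–3.8-s
operation period, giving inter-onset intervals uniform on the
{3600, 3700, …, 4400} ms grid (mean 4 s). Arithmetic blocks add 1–2 per
trial from a 10–40 start (low) or subtract 3–4 from a 65–99 start (high),
with every running result kept strictly inside (10, 100). Visuospatial
blocks move a patch through a 3x3 (low) or 4x4 (high) matrix with
direction cues that never cross the border and never immediately reverse
the previous cue. Control blocks replay the same kinds of cue streams but
they are to be ignored.

Open choices resolved here (the sources state only the aggregate facts):

* **Block lengths** are drawn balanced — per workload level three 9s, four
  10s, three 11s — so each level totals exactly 100 trials and each
  modality 300 (600 overall). A fully random draw would only match these
  totals in expectation.
* **Control-stream assignment**: whole control blocks reuse a low-style or
  high-style cue stream (5 + 5 per modality), rather than mixing styles
  within a block.
* **Task order** is counterbalanced by participant-id parity.
* Operand/direction sampling is uniform over the allowed values with
  bounded resampling on constraint violation — the simplest process
  consistent with the constraints.

## The oculomotor simulator

The generative model is deliberately *phase-based and velocity-driven*: the
eye is a point on the target circle whose phase advances at `gain * omega`,
starting `lag_ms` behind the target. This makes the two pursuit parameters
independently measurable downstream:

* between saccades the eye's path speed is exactly `gain * 6.8` dva/s, so
  median velocity gain recovers `gain`;
* under gain 1 the gaze-to-target distance is the constant chord
  `2 r sin(omega * lag / 2)` (≈ 0.68 dva at 100 ms), so median GTD recovers
  the lag.

Catch-up saccades are endogenous: whenever the noise-free GTD exceeds
`catchup_trigger_dva` (default 1.0 dva) a corrective saccade is scheduled
that lands on the target at its offset time. Anticipatory saccades occur at
a Poisson rate but only while the eye is near the target (within 60% of the
anticipatory landing lead, default 0.9 dva ahead); a far-lagging eye makes
catch-ups, not anticipations — and, importantly, a saccade that lands
"ahead" from far behind would *reduce* the distance and therefore *be* a
catch-up under the operational definition. For the same reason the
ground-truth log labels every non-micro saccade by the distance change its
true endpoints produce, not by the scheduling mechanism. Microsaccades are
small (0.2–0.8 dva) random phase jumps.

All saccades use a raised-cosine velocity profile over 25 ms (peak velocity
`2 * amplitude / duration`, e.g. 96 dva/s for a 1.2-dva saccade), which
comfortably exceeds the 22 dva/s / 4000 dva/s² detection thresholds for the
amplitudes the simulator produces; saccades are never scheduled inside
blink-padded zones. These two choices implement the simulator's contract
that injected events are detectable by design.

Positional noise is temporally *correlated* (white noise smoothed with a
20-ms Gaussian kernel, scaled to sd 0.02 dva per eye): a model of slow
drift/tremor rather than white sensor noise. The correlation is what keeps
the velocity estimate nearly unbiased — differentiating white positional
noise at 1000 Hz would swamp the 6.8 dva/s pursuit signal, while the
correlated default adds ≈ 0.5 dva/s of velocity noise and biases median
speed by well under one percentage point of gain. Eyes are the cyclopean
trace ± half a fixed interocular offset (0.15 dva) plus independent noise.

Blinks (Poisson, default 0.1 Hz, 150 ms) blank gaze and pupil on both eyes
and add 20-ms partial-occlusion pupil ramps on their shoulders, so the
100-ms padding rule has something real to swallow.

Pupil diameter is `baseline + tonic(load) + phasic + noise`: baseline 4 mm;
tonic offsets ordered single (0) < low (0.10) < high (0.20 mm); a phasic
dilation kernel `(t/tp)^a exp(a (1 - t/tp))` with peak `tp` = 1.25 s after
cue onset and shape `a` set from the requested width (1 s FWHM), zero in
the control condition (cues are ignored). The peak lands in the third
0.5-s bin. Tonic/phasic magnitudes are plausible workload-sized effects
(tenths of a millimeter); they are study conditions, not fitted values.

What the simulator does *not* emulate: main-sequence amplitude-duration
scaling, pursuit-onset latency dynamics, head movement, calibration error
fields, gaze-angle pupil foreshortening, or genuinely binocular
(vergence) dynamics. Passing recovery tests therefore shows the pipeline
is correct under a controlled oculomotor model — not that it handles every
artifact of real recordings.

## Event detection

Velocity is the norm of a 5-point central difference of the
binocular-average position; acceleration is the same operator applied to
speed. Tracker parsers do not publish their exact filter, so this choice is
ours and is isolated in one function. A saccade is a maximal run of speed
> 22 dva/s that also shows |acceleration| > 4000 dva/s² within the run and
lasts ≥ 6 ms; runs inside padded blinks are never saccades. Amplitude is
the straight-line start-to-end distance; amplitudes strictly below 1 dva
are microsaccades. Blinks are maximal invalid/pupil-missing runs padded by
exactly 100 ms per side; merged events keep the outermost raw bounds so the
pad stays exact. Detected onsets sit at the velocity-threshold crossing,
3–5 ms after the true ballistic onset for default amplitudes — within the
5-ms accuracy the recovery tests demand.

## Pupil pipeline

Order is fixed: (arbitrary-units → mm if a calibration is supplied; the
artificial-pupil slope is rig-specific, so there is deliberately no
default) → centered 20-sample moving average, truncated at edges and at
missing-data gaps → linear interpolation across padded blink intervals
(never extrapolating: edge blinks stay missing) → exclusion of samples
more than 3 SD from the participant's mean and of samples during
saccades. The 3-SD reference window is all of the participant's smoothed
task data (configurable); binocular PD is the two-eye mean, or the single
valid eye. A constant series (SD 0) disables the outlier rule with a
warning rather than excluding everything or nothing silently.

## Pursuit metrics

* **GTD** = Euclidean distance between mean-eye gaze and target; samples
  with GTD > 6.8 dva (the target's 1-s travel) are treated as "lost the
  target" and excluded.
* **VG** = 100 · gaze speed / 6.8, on SPEM-labelled samples only; samples
  slower than 0.5 dva/s are fixations and excluded from VG.
* **Disparity**: conjunctive rule — excluded only when the left-right
  distance is both > mean + 3 SD *and* > 60 mm on screen. The 60-mm bound
  is interpreted as on-screen millimeters at the 88-cm viewing distance
  (≈ 3.9 dva); the sources mix units without a conversion statement.
* **CUS/AS**: a non-micro saccade is catch-up iff the distance to the
  target at its offset time is smaller than at its onset time, with the
  target evaluated at those two times (it moves during the saccade). The
  exact tie — a measure-zero event — goes to anticipatory.

## Binning and exclusion

Seven 0.5-s bins per trial, [0, 3.5) s from cue onset; later samples are
discarded. Medians per bin for PD/VG/GTD; CUS/AS rates are onset counts per
second. Missingness is tracked per metric family (SPEM, saccade, PD), and
exclusion cascades bottom-up with a strict > 50% rule: bins by sample
missingness, then trials by excluded-*bin* fraction, blocks by
excluded-trial fraction (within participant × modality), participants by
excluded-block fraction (pooled over modalities). The "child-count" reading
of the upper levels is a documented choice (raw-sample fractions would
differ only when bins are partially missing in a correlated way). The
operation is idempotent, and lowering the threshold can only exclude more.
Unanswered dual blocks are dropped from eye analyses (the eye record does
not reflect the intended internal task); incorrectly answered blocks are
retained.

## Statistics

The contrast layer is an explicit two-stage participant-aggregate analysis:
trial-level bin medians are averaged to one value per participant ×
workload × bin, then each bin gets the three planned paired comparisons
(single−low, single−high, low−high) with Bonferroni correction over the
tests actually run in that bin (families never span bins), a
paired-difference Cohen's d_z, and a JZS Bayes factor. This is a
transparent surrogate for mixed-model marginal-means machinery; numerical
agreement with model-based estimates is not claimed, qualitative recovery
of condition effects is.

The manipulation-check ANOVA (2 modality × 2 workload on percent-correct
blocks) is a hand-rolled classical repeated-measures sums-of-squares
decomposition, each effect tested against its subject-by-effect
interaction; it is cross-checked in the tests against both an independent
brute-force decomposition and pingouin.

The JZS Bayes factor marginalizes the noncentral-t likelihood over a
Cauchy(0, √2/2) prior on the standardized effect size by adaptive
quadrature; the test oracle uses the algebraically distinct inverse-gamma
g-mixture representation, and the two agree to well under 1%. Reported
evidence bands: < 3 weak, 3–20 moderate, 20–150 strong, > 150 very strong.

The a-priori power routine finds the smallest n whose exact noncentral-t
power reaches the target; with dz = 0.4, alpha = .05 one-tailed, power .80
it returns n = 41 (two-tailed would give 52; the one-tailed reading is the
one consistent with the published figure, and the ambiguity is noted here
rather than silently resolved).

Null calibration is verified by simulation: with no condition effects the
raw (pre-Bonferroni) false-positive rate across 1000 simulated experiments
is 5% ± 2%.

## Problem sizes and numerical choices

Simulation studies in the test suite use desk-scale sizes chosen as the
smallest that make the assertions statistically stable: 100 trials per gain
for VG recovery, 30 per lag, 200 default trials for detection recovery,
1000 replicates for null calibration, and 40 participants × 4 trials per
condition (pupil timecourses only, without full gaze synthesis) for the
tonic-PD ordering recovery — the quantity under test there is the contrast
layer, not the gaze machinery. Tolerances mirror the recovery guarantees:
±1 VG percentage point, ±0.05 dva on the lag chord, ≤5 ms onset error,
sensitivity ≥ 0.95, FDR ≤ 0.05.

Degenerate inputs are handled explicitly: zero-SD outlier rules warn and
disable; monocular disparity warns and excludes nothing; empty binned
tables refuse to serialize; flat ANOVA cells give F = 0; contrasts with
fewer than 3 complete pairs are skipped and logged; a catch-up trigger at
the noise floor warns about saccade storms.

## Known limitations

Single-eye validity flags are treated jointly (a blink blanks both eyes);
purely monocular artifacts are out of scope. The simulator's pursuit gain
is constant within a trial, so slow gain drifts are not modelled. The
two-stage statistics ignore trial-level random variance beyond what
averaging absorbs, which is exactly the trade-off accepted when forgoing
mixed models. The hierarchical exclusion assumes the canonical 7-bin
structure when judging trials by their bins.
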