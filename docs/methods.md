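# Methods

## Geometry and coordinate conventions

The projection screen (defaults: 1400 × 1050 px, 2.03 × 1.52 m, viewed from
2.0 m) is mapped to visual angle with the small-angle convention
`extent = degrees(size / distance)`. This convention was chosen because it
reproduces the 58.15–58.16° horizontal extent quoted for this simulator
class; the tangent convention would give 53.9° and is rejected. The same
convention yields 43.54° vertically; quoted vertical extents of 43.61° for
identical dimensions are not reproducible under either convention, and the
discrepancy is recorded here rather than resolved. Screen-degree
coordinates have their origin at the screen centre (+x right, +y up); pixel
coordinates are top-left row-major, and the converters handle the y-flip.
With the default geometry horizontal and vertical degrees-per-pixel agree
within 1% (near-isotropic pixels).

## Event detection

**Differentiation.** Velocity is computed with central differences on the
raw 100 Hz position samples; no smoothing by default (an optional
moving-average window exists but is off). At 100 Hz with a 30 °/s saccade
threshold, raw central differences are adequate: 0.1° position noise maps
to ~7 °/s velocity noise, far below threshold. Velocity is undefined at
trace ends, at invalid (tracking-loss) samples and at their immediate
neighbours; traces shorter than three samples raise an error.

**Saccades.** Candidates are maximal runs of gaze speed above
`saccade_vel_thresh` (30 °/s). Runs separated by a single sub-threshold
sample are merged (a single dip at 100 Hz is unresolvable); runs shorter
than 2 samples are discarded as noise; runs never merge across invalid
spans. Run boundaries are then refined outward while speed keeps strictly
decreasing, so onset/offset land on the kinematic start and end of the
movement rather than the threshold crossing — this is what makes amplitudes
exact on noise-free data. The refinement stops below a floor of 1e-6 °/s so
that floating-point dust in perfectly still synthetic segments cannot drag
a boundary outward. The amplitude criterion (`saccade_amp_thresh`, 1°) is
applied to the chord — the onset-to-offset displacement — while the arc
length (summed inter-sample path) is kept separately; arc ≥ chord always.
The threshold applies to combined gaze (eye + head), not eye-in-head,
because the object of study is the gaze trajectory on the screen.

**Classification.**

* *Blink*: dominant axis vertical (|Δy| > |Δx|) **and** peak velocity above
  `blink_peak_vel_thresh` (1000 °/s). Blinks are removed from the retained
  saccade list; their time interval is absorbed by the surrounding
  fixation, but their samples are excluded from the fixation centroid —
  eyelid artifacts are not gaze, and including them can displace a centroid
  by more than the object-matching tolerance.
* *Curved*: arc − chord > `curved_excess_thresh` (15°), an absolute excess
  in degrees, not proportional. Curved saccades are kept and flagged:
  slower curved vertical saccades frequently directly precede object
  fixations, and removing them would lose detections.
* *Off-screen*: any gaze sample outside the screen rectangle, or the event
  touches a lost-signal span (with a two-sample halo, since the
  central-difference velocity is undefined next to invalid samples and runs
  are truncated there).

**Fixations** are the complement of retained saccades within each valid
span; fixations and saccades share boundary samples, so their durations
tile the valid trace time exactly (verified to one sample period on random
synthetic traces). Centroids are mean gaze position; pixel centroids are
derived through the geometry. Zero-length complements (saccade at a span
edge) are dropped. Smooth pursuit is deliberately not modelled — all
inter-saccadic sections count as fixations.

**Head movements** use the same detector on the head channel with
`head_vel_thresh` = 6 °/s and `head_amp_thresh` = 3°.

**VOR exclusion.** A head movement is vestibulo-ocular — and excluded from
head-movement counts — iff, over the movement's own interval, the
eye-in-head displacement on the dominant head axis has the opposite sign
and compensates at least `vor_min_compensation` (default 0.5) of the head
displacement. This directly encodes the defining property that such
episodes add no gaze amplitude. An alternative operationalization — pairing
separately detected eye events with head events by temporal overlap and
opposite net sign — was implemented first and rejected: during the
completion phase of a large combined eye–head gaze shift the eye
counter-rotates to hold the landed gaze while the head finishes, which
produces exactly such an overlapping opposite-sign eye event and would
wrongly exclude genuine head contributions to gaze. Filtering never
increases the head-movement count.

## Reaction times

Per object, the first brake/indicator press inside the response window
(object onset to onset + 10 s, or to the end of the object's track if
shorter; 10 s is a package choice, generous against the ≤ 4 s latencies in
play) gives the manual RT; the earliest fixation with onset at or after the
object onset whose centroid falls within |Δx| ≤ 1.24°, |Δy| ≤ 1.66° of the
object position gives the fixation RT. Object position is evaluated at the
fixation onset by default (objects move); evaluating at the closest
approach within the fixation is a configurable alternative. Fixation RT is
measured to fixation onset — the fixation is the unit of "seen" — rather
than to the first within-tolerance gaze sample. The first-detection RT is
the minimum of the two modes. Each response is assigned to at most one
object, earliest onset first (drivers produce one action per event); a
warning is raised only when this greedy rule leaves a later object with no
response although a response in its window was claimed by an earlier one.
RTs are reported in milliseconds. Shrinking the tolerance box can only
reduce the number of matches (verified property).

## Summaries, coding and models

Per subject × course: mean fixation duration (ms), mean saccade amplitude
(deg), saccade count, fixation-location variance as the sample (n−1)
variance of centroid pixel coordinates per axis (missing, not zero, with
fewer than two fixations), VOR-excluded head-movement count, and median RT
per eccentricity over detected objects only.

Codings: eccentricity 0 = close/1 = far; course 0 = field/1 = ancient;
game experience as two mutually exclusive dummies (moderate, extensive)
against the minimum-experience baseline; gender 0 = male/1 = female;
malaise 0/1; age exactly mean-centred. Two-way interactions are plain
products of the coded main effects; the product of the two game-experience
dummies is identically zero and never formed. Coding is idempotent, and an
already-coded table passes through unchanged.

Model fitting is delegated to statsmodels — a random-intercept MixedLM
(REML) with subject as the grouping factor, and a binomial GLM for 0/1
outcomes — since fitting itself is standard numerics; the bespoke, tested
surface is the coding, the metric definitions, and the decision rule that
flags a mixed-model fixed effect as significant when |t| > 2. Singular
designs (constant or collinear columns) raise a rank-deficiency error
before fitting. Under the null, the |t| > 2 rule empirically rejects a
given term in ≈ 4–5% of replicates (close to the two-sided normal 4.6%),
which the test suite checks by Monte Carlo.

## Synthetic data generator

The generator's defaults encode the study conditions: 100 Hz sampling,
600 s per course, eight hazardous events (the full crossing of
{boar, ball} × {left, right} × {close, far}) plus four signs/breakdown
cars, scheduled in evenly spaced slots with jitter and a feasibility check
(an over-full schedule raises a configuration error).

* **Saccades** are minimum-jerk; each saccade's duration is set from the
  main-sequence law v_peak = v_max (1 − e^(−A/scale)) with v_max = 500 °/s
  and scale = 14°, using the analytic minimum-jerk relation
  v_peak = 1.875 A / D. The law holds exactly (to 1e-6) in the ground
  truth before noise. v_max and scale are free, realistic parameters of the
  generator, not measured truth. Background amplitudes are
  1.5° + Gamma(2, 3°) capped at 28°, mostly 1–10°; fixation durations
  Gamma-distributed with mean 0.45 s, clipped to [0.3, 0.9] s so that
  events stay separated and the detection oracle is well defined.
* **Eye–head sharing**: gaze shifts above 20° recruit the head, which
  carries the excess amplitude (minimum 3.5°) along the saccade direction
  with a 50 ms lag and its own slower velocity law; the eye counter-rotates
  after gaze lands while the head completes. The 20° threshold and 50 ms
  lag are plausible placeholders — the literature motivates the existence
  of head recruitment above roughly 20°, not an exact sharing function.
* **VOR episodes** are out-and-back head turns (4–8°) with the eye
  compensating fully, so gaze stays put; each episode contributes two
  counter-phase head movements that detection must exclude.
* **Blinks** are paired fast vertical excursions (30° down and back in
  40 ms each, peak > 1100 °/s even after sampling), exercising the blink
  exclusion rule.
* **Curved saccades** travel a circular arc whose length exceeds the chord
  by 16–21°, with duration set from the law on the arc length — they land
  where a straight saccade would, but appear above the main sequence.
  Curving is applied by deterministic thinning at the configured 2.9%
  fraction of all saccades, so the realized fraction is exact rather than
  binomially noisy.
* **Objects and responses**: per object, a fixation latency is scripted
  (base 874 ms + 1244 ms × eccentricity − 187 ms × course + 853 ms ×
  eccentricity × course, plus N(0, 100 ms) noise and an optional
  per-subject shift), the planner lands a saccade on the object's track at
  exactly that moment, and a manual response follows at a 300 ms motor
  delay — so first-detection ≤ manual by construction. A configurable
  fraction (default 5%) of objects is instead answered manually 150 ms
  *before* fixation, exercising the manual-first branch. Background
  saccades are kept ≥ 3° away from a pending object's track so the scripted
  fixation is always the earliest match.
* **Noise** is added last: Gaussian position noise (SD 0.1°, typical
  video-oculography) on the eye channel and 0.02° on the head channel; gaze
  remains the derived sum. Ground truth stores pre-noise values.
* **Cohorts**: ages uniform on [20, 75]; game-experience group
  probabilities decay with age (younger → more experience), qualitatively
  matching the confounding the analysis must handle; gender balanced;
  driving experience tied to age. For model-level testing,
  `generate_cohort_table` simulates the subject × eccentricity × course
  response table directly from the coded design with chosen fixed-effect
  magnitudes, a subject random intercept, and residual noise — the default
  magnitudes are the published manual-RT model values (eccentricity
  +1300.19 ms, eccentricity × course +956.03 ms, subject SD 311.22 ms,
  residual SD 448.70 ms) used as simulation truth.

What the generator does **not** emulate: smooth pursuit, microsaccades,
torsion, photorealistic scenes, vehicle dynamics, genuinely curved
real-world saccade dynamics (the arc construction is geometric), head
re-centring drift (head offsets persist between movements, so eye-in-head
values can grow unphysiologically large over long drives without affecting
any detected quantity), or any physiological model of simulator sickness
(malaise is a plain Bernoulli outcome for logistic-fit testing). Passing
tests therefore certify the pipeline's algebra and decision rules on
signals with these idealized properties, not performance on real
recordings with drift, calibration error, or pursuit.

## Problem sizes

The test suite and the acceptance script run at desk scale by shortening
drives, not by changing defaults: partition checks use 100 (tests) / 50
(script) drives of 30 s; oracle-equivalence checks 6 drives of 80 s each
for the noise-free and noisy conditions; VOR checks 50 drives of 30 s with
an elevated episode rate; reaction-time checks 5 drives of 80–120 s;
mixed-model recovery 20 replicates and null calibration 200 replicates of
the full 73-subject cohort table. The full default drive (600 s) is used in
the examples.

## Known limitations

* The vertical screen extent cannot be reconciled with the quoted value
  (see Geometry); the horizontal extent anchors the convention.
* Detected peak velocities are sampled central differences and
  underestimate the analytic peak of short saccades by up to ~15%; the
  main-sequence ordering is preserved (Spearman ρ > 0.95) but absolute
  detected peaks should not be compared against the generator law.
* With 0.1° position noise, detected event boundaries can shift by one to
  two samples, so reaction times recovered from noisy traces carry up to
  ~20 ms error; noise-free recovery is exact to the sample.
* The |t| > 2 rule is a fixed decision convention; it is calibrated (~5%
  type-I error) but makes no multiple-comparison adjustment.
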