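# Methods

## Gesture model

A gesture is a goal-directed articulator movement modelled as a critically
damped point attractor with unit mass,

    x'' = -ω² (x − T) − 2ω x',

where `T` (mm) is the target position and `ω` (s⁻¹) the natural frequency;
the abstract spring stiffness is `k = ω²`.  Critical damping is the natural
choice for speech gestures: the approach to the target is monotone (no
articulator overshoot/oscillation) and the solution is closed-form.  From
state `(x₀, v₀)` at activation onset,

    x(t) = T + (A + Bt) e^(−ωt),  A = x₀ − T,  B = v₀ + ωA,

with velocity and acceleration differentiated analytically.  From rest the
peak velocity is `|x₀ − T|·ω/e`, reached at `t = 1/ω` independent of
amplitude.  These identities give the model its signature behaviours:

* scaling the **target** scales peak velocity proportionally without
  changing movement timing (target undershoot = smaller and slower, not
  shorter);
* scaling the **stiffness** `ω²` makes movements faster *and* shorter;
* **rescaling** (amplitude × f, ω × 1/f) leaves peak velocity invariant;
* **phasing** < 1 starts the next gesture early; because the state is
  carried across the attractor switch, the current movement is truncated —
  chiefly its deceleration phase and displacement — while the peak
  velocity, reached earlier, is essentially untouched.

Syllable trains place closing-gesture onsets on a fixed cycle grid (the
controlled repetition rate); the opening gesture starts at
`phasing × closing activation` after each closing onset and runs until the
next cycle.  Truncation by state carry-over (continuity) was chosen over
resetting the articulator state, which would teleport the articulator.

Ground-truth landmarks are computed from the analytic piecewise solution:
onset = the velocity zero-crossing at the movement turnaround (or the
activation onset if already moving towards the target), peak velocity = the
interior acceleration root, target = the first velocity zero-crossing after
the peak (created by truncation or by the opening gesture).  Roots are
bracketed on a fine grid (≤ 1 ms) and refined with Brent's method to
1e-9 ms.

Note one composition effect relevant to interpreting phasing: in a *train*,
earlier release also changes the posture from which the next closing starts,
so steady-state peak velocities shift slightly with phasing.  The pure
truncation signature is therefore evaluated on the first gesture of a train
(identical starting state), where the <5% peak-velocity invariance holds.

## Measurement chain

* Zero-phase 4th-order Butterworth low-pass on position, then
  central-difference velocity and acceleration (one-sided at the ends).
  Default cutoff **30 Hz**.  20 Hz — a common field choice — proved
  inadequate here: the truncation transient of fast DDK gestures leaks into
  the filter support and biases the acceleration zero-crossing (the peak-
  velocity landmark) by up to ~17 ms on noiseless signals; at 30 Hz all
  calibrated conditions recover every landmark within one sample (4 ms at
  250 Hz).
* **Peak velocity**: the acceleration zero-crossing at the dominant
  directed-velocity extremum, located as the root of a linear fit over ±3
  samples (a plain two-sample interpolation scatters by ~8 ms under 0.1 mm
  position noise because the velocity plateau is flat).
* **Onset/target**: exact velocity zero-crossings rarely exist on noisy or
  asymptotic signals, so the operational reading is the nearest point
  (before/after the peak) where the directed velocity falls to
  `max(noise floor, 1% of the peak)`, linearly interpolated; with a sign
  change in the bracket the true zero-crossing is interpolated instead.
  If noise keeps the velocity above threshold on one side, the closest
  approach to zero is used.  Defaults: noise floor 2 mm/s, fraction 0.01.
* **No-gesture guard**: peak directed velocity below 5 mm/s (just above
  the velocity noise SD of the default chain: 0.1 mm white noise → ≈
  4.5 mm/s after filtering and differencing) raises an error rather than
  producing a landmark from an absent movement.  Within the search window
  the *interior* local maximum of directed velocity is preferred over a
  maximum sitting exactly on the window edge, which is a truncated view of
  a neighbouring movement.
* Landmark search windows in the pipeline run from 80% of the gap since the
  previous constriction to 10% of a cycle after it.  Movement polarity is a
  property of the whole train (every /pa/ closure raises the lower lip), so
  it is inferred once per trial from the sign of (mean position at the
  constriction onsets − overall mean position).  The outermost 4 samples
  of a trace are excluded (filter edge transients).
* Variables are definitional: acceleration phase = peak − onset,
  deceleration phase = target − peak (the two partition the activation
  interval exactly), displacement = |x(target) − x(onset)|, peak velocity =
  |v| at the landmark, stiffness index = peak velocity / displacement
  (s⁻¹).  Displacement below 0.1 mm (the positional resolution) makes the
  stiffness index undefined and is an error.
* The target landmark of a monotone critically damped approach is
  asymptotic; the threshold choice therefore moves the measured
  deceleration phase and displacement.  For an isolated untouched gesture
  at the 1% threshold the measured stiffness index is ≈ 1.004·ω/e.  The
  threshold is an exposed configuration knob.

## Acoustic variables

Computed from annotation tiers only (no audio DSP — the labels in this
paradigm are manual).  Cycle selection discards the first three cycles of
each train (prosodic-boundary effects) and keeps ten, re-indexed 1–10 as
the centred cycle-position covariate.  Voicing-during-closure is **strictly**
greater than 20 ms of voiced time inside the closure; exactly 20 ms counts
as vowel coarticulation.  Voiced spans inside the closure are summed by
default (a contiguous-only mode exists).  Frication-during-closure is the
binary label passed through without any threshold.

## Synthetic cohort

The generator emulates the study design: 12 controls (one condition) and 12
patients (OFF and ON, order counterbalanced 6/6), 2 repetitions × 3
syllables × 13 simulated cycles, 2160 analysed tokens.  Per group ×
syllable cell the generating parameters are set so that the *expected*
measured variables equal the published group means:

* cycle period ← syllable-duration mean;
* ω ← 1000 / acceleration-phase mean;
* closing activation ← accel + decel mean (the opening gesture truncates
  the closing one there, reproducing the short deceleration phases);
* movement amplitude ← peak-velocity mean × e / ω;
* closure fraction ← voicing-ratio mean (the vowel is fully voiced, plus a
  voiced span at closure onset: > 20 ms with the cell's
  voicing-during-closure probability, else a 5–15 ms coarticulatory
  remnant);
* binary probabilities ← the published proportions, realised through
  speaker-level logit intercepts (SD 0.8) whose marginal mean is
  numerically bias-corrected back to the target proportion.

Three free kinematic parameters cannot match four published kinematic
means: displacement (and hence the absolute stiffness index) is *emergent*
from truncation.  Its group ordering matches the published tables; its
absolute level does not, and no claim is made that it should.

The published ON /ka/ peak-velocity mean is missing from the source table
(only its SD is printed); it is imputed as the OFF mean × 0.723, the mean
ON/OFF ratio of the /pa/ and /ta/ cells.

**Variability.**  Published group coefficients of variation are split
70% / 30% (log-scale variance) between speakers and cycles.  Speaker scores
are standard-normal draws made once per speaker and shared across that
speaker's conditions — exactly the random-intercept + independent-token
structure the statistical stage assumes.  (A trial-level variance component
was deliberately *not* included: it would cluster the 10 cycles of a train
beyond what a speaker random intercept captures and invalidate the level of
the likelihood-ratio tests; real DDK data may well contain such clustering,
which is a caveat on transferring the simulation results to real
recordings.)  Lognormal draws are mean-corrected so cell means are
unbiased; the per-cycle frequency multiplier is additionally compensated so
the mean *acceleration phase* (1/ω) stays on target.  Per-cycle multipliers
are winsorised at ±2 SD (adjacent syllable cycles do not make 3-sigma tempo
jumps), and several tails are truncated on physiological grounds — every
token in the emulated study was produced and hand-measured: speaker-level
peak velocity is floored at 20 mm/s and movement amplitude at 2 mm (a stop
closure must occlude the tract), each cycle's attainable peak velocity
(accounting for truncation before 1/ω) at 20 mm/s and its amplitude at
1.5 mm, and each cycle's opening gesture must recover at least 85% of the
way back to rest before the next closing onset (otherwise one slow opening
collapses all subsequent movements).

Additive white Gaussian position noise (default 0.1 mm SD) is applied
before smoothing.  All randomness flows from one seeded generator; speaker
scores are drawn first, in fixed order, before any token-level draw, so a
seed fully determines the cohort.

**What the generator does not emulate**: audio, aerodynamics, horizontal
movement components, trial-level drift or fatigue, within-train tempo
curves, voicing as a continuous process, and any correlation between the
nine variables beyond what the mass-spring kinematics induce.  Passing
tests show the *pipeline* is correct and the *procedure* is calibrated
under these conditions, not that real EMA data meet them.

A fast token-level path (`simulate_token_table`) draws the nine variables
per token directly from the same generative quantities (closed-form
truncated-gesture kinematics, lognormal cycle jitter, an extra 5%
measurement-like noise) without synthesising trajectories; it exists so
that the 500-replicate simulation studies of the statistical stage run in
minutes.  A test checks that the two paths agree on group means.

## Statistical stage

For each outcome and one DBS contrast at a time (control vs OFF — between
speakers; OFF vs ON — within speakers):

    y ~ DBS × POA + cycle_position_centred + (1 | speaker)

with deviation (sum-to-zero) coding, fitted by maximum likelihood (not
REML, so LRTs between fixed-effect specifications are valid).  Continuous
outcomes are natural-log-transformed then z-scaled over the analysis set
("log first" is the conventional reading of scaled-log; z-scaling after a
log is affine, so it does not change the LRTs); the stiffness index, a
ratio of logged quantities, is z-scaled without a log.  Binary outcomes use
a mixed logit.  Selection: LRT of the interaction (df = 2) against the
additive model; if not significant at the corrected α, LRT of the DBS main
effect (df = 1).  Non-convergence is flagged on the result, never silent;
random slopes are out of scope (they do not converge reliably at this
design size).  Contrasts are unweighted sum-to-zero even in the unbalanced
control-vs-OFF comparison.

The fitters are in-package: a profiled-ML linear mixed model (closed-form
GLS per variance ratio, 1-D optimisation) and a Gauss–Hermite (25-node)
mixed logistic regression with analytic gradients.  Both are pinned against
references in the test suite — statsmodels `MixedLM` (live) and `lme4`
`lmer`/`glmer nAGQ=25` values (frozen from a seeded dataset the test
regenerates) — and exist because the simulation studies need thousands of
fits within minutes.

**Multiplicity.**  Dunn–Šidák per family: m = 4 acoustic → α = 0.0127,
m = 5 articulatory → α = 0.0102 (levels reported to 4 decimals).  One
structural caveat, documented rather than hidden: the two-stage selection
gives each outcome two asymptotically independent ~α-level chances to
declare a DBS effect, so the *terminal-decision* family-wise error is
≈ 2mα′ ≈ 0.09–0.10 per family no matter how the tests are implemented.
The null-simulation study therefore checks what the Šidák correction
actually promises — that the family of interaction tests and the family of
main-effect tests each keep their family-wise error within the binomial
bound on 0.05 — and additionally reports the terminal-decision rate.

**Order effects** are exploratory, flagged as such: starting from the
additive model, control-vs-OFF tests a 3-level split
{control, OFF(OFF-ON), OFF(ON-OFF)} against the 2-level DBS factor (df 1);
OFF-vs-ON tests the DBS × order interaction, then the order main effect.

**Simulation studies** (the fast token path): the null study uses the
within-subject OFF-vs-ON contrast — the design's central comparison, and
the one whose LRT reference distribution is well calibrated at 24 clusters
(between-subject LRTs at this cluster count are known to run
anticonservative).  Power studies inject a main effect of 0.5 total
log-scale SD (detection across 200 replicates) and a DBS × order
interaction of 0.75 SD.  Problem sizes — 500 null replicates, 200 power
replicates — match the intended precision of the binomial bounds.

## Numerical and degenerate-input conventions

Times are absolute trial milliseconds, positions mm, velocities mm/s,
ω s⁻¹; sample indexing is 0-based; the default sampling rate is 250 Hz
(typical for the sensor class, configurable).  Ties at equal velocity
extrema break to the earliest sample.  Trajectory files must be strictly
increasing uniform grids (tolerance 1e-6 ms).  Fewer than 13 cycles, empty
windows, non-positive values before a log, probabilities outside [0, 1],
and unknown modification modes are errors with named trials where
applicable; a cycle period too short for ω (target approached to < 95%
before the next onset) is the truncation regime under study and warns
instead of failing.

## Known limitations

* Landmark localisation precision degrades on slow, flat-peaked movements
  (the hypokinetic ON /ka/ cells): the median peak-velocity timing spread
  under 0.1 mm noise grows to ~10–15 ms there, an inherent property of
  locating a zero of a nearly-flat derivative.  Human labellers face the
  same geometry.
* Displacement/stiffness absolute levels are emergent, not calibrated (see
  above); only their orderings are meaningful.
* The generator's independence assumptions (no trial-level clustering, no
  cross-variable residual correlation) are favourable to the statistical
  procedure; real recordings need not satisfy them.
* The control-vs-OFF contrast rests on 24 clusters; its LRT p-values
  should be read with the usual small-sample caution.
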