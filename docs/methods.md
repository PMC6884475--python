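# Methods

`lanecue` reproduces, end to end and without human data, a simulated-driving
experiment on sensory substitution for lane keeping: when the near road is
occluded, can a binaural auditory rendering of vehicle lateral position
restore lane-keeping accuracy after training, without disturbing steering
stability?  This note documents the models, the parameters that matter, and
the choices made where the underlying design was open.

## Task and protocol

A vehicle travels at a constant 80 km/h (22.222 m/s) along a winding road
with a 3.5 m lane; the driver's only control is the steering wheel.  The
protocol is a balanced group comparison: 45 synthetic participants, 15 per
group, each completing 5 pretest, 40 training and 5 posttest trials of one
minute (3600 steps at 1/60 s).  Pretest and posttest trials always run
under normal driving (ND) for every group; the training session runs under
the group's condition:

- **ND** — near road visible, audio carries no information;
- **VO** — near road occluded (no lateral-position cue at all);
- **SS** — near road occluded, lateral position sounded binaurally.

Every trial uses a freshly generated course.  All randomness descends from
a single master seed through `numpy.random.SeedSequence` keyed on
(master seed, group, participant, session, trial), so the whole experiment
and any single trial are exactly reproducible.

## Road course

Courses are sequences of piecewise-constant-curvature segments: straights
(50–150 m, uniform) alternating with circular bends whose curvature
magnitude is uniform in [1/180, 1/80] m⁻¹ and whose turning direction
strictly alternates.  Bend lengths are drawn from the same 50–150 m range
as straights — the bend-length distribution is a free choice, and this one
gives several bends per one-minute trial at 80 km/h.  There are no clothoid
transitions: curvature steps at segment joints, the simplest model
consistent with "bends and straights".  The default course length is
1500 m, comfortably above the 1333 m travelled per trial.  Geometry is
planar; poses come from the closed form of the constant-curvature arc, and
point-to-centreline projection is an O(1) segment-walking search that is
exact because the centreline is C¹ (heading-continuous).  Ties at joints
resolve to the smaller arc position.  Sign conventions everywhere: positive
curvature = left bend; positive deviation = left of lane centre.

## Vehicle

A kinematic bicycle — no slip, no lateral tire dynamics — which is adequate
at 80 km/h on curvature ≤ 1/80 m⁻¹ and exactly deterministic: road-wheel
angle δ = steering-wheel angle / 15, yaw rate v·tan(δ)/L with wheelbase
L = 2.7 m, semi-implicit Euler at the fixed 1/60 s simulation step (heading
first, then position, so per-step displacement is exactly v·dt).  The wheel
is clamped at ±2π rad and slew-limited at 2π rad/s.  These are commodity-car
values, exposed in the config.  A trial whose deviation exceeds 3 lane
widths is flagged off-road but runs to completion, as a human trial would.

## Auditory code

Deviation d (m, +left) maps to per-ear levels in dB of attenuation from the
maximum tolerable level:

    left = −50 + 25·d,  right = −50 − 25·d,

each clamped to [−100, 0] dB.  Clamping is a package choice: 0 dB is the
"maximum tolerable" ceiling and −100 dB a silence floor; with the printed
base (−50 dB) and gain (25 dB/m) the invertible range |d| < 2 m covers the
lane.  dB values are amplitude-referenced (factor 10^(dB/20)); the inverse
map d = (left − right)/(2·25) is exact in the unclamped range and saturates
(with a flag) outside it.  The WAV rendering holds each 1/60 s frame's
amplitude over its 735 samples at 44.1 kHz (zero-order hold, no click
suppression): it is a diagnostic, not a calibrated stimulus.

## Driver model

Participants were human; the synthetic agent is this package's model of
them, built on the classical two-level account of steering: a *compensatory*
feedback process using near-road lateral position (it determines accuracy)
and an *anticipatory* feedforward process using far-road curvature preview
(it determines stability).  Per perceptual sample the agent forms

- `far_curvature`: course curvature at s + v·preview_time (preview_time
  1 s, the typical tangent-point lead), noise SD 6·10⁻⁴ m⁻¹;
- `heading_error`: heading minus path tangent, noise SD 4.5·10⁻³ rad;
- a deviation estimate: the true deviation with visual noise (SD 0.06 m)
  under ND; under SS, the encode→decode round trip of the true deviation
  plus decoding noise; under VO, nothing (the compensatory term falls back
  to zero and only the heading loop restrains drift — this is what
  sustains the VO deficit).

The wheel command is

    sw = k_ant·R·atan(L·κ_far)  −  k_comp·d̂  −  k_head·ψ̂  +  motor noise,

with k_ant = 1 (dimensionless, exact geometric feedforward), k_comp =
0.12 rad/m, k_head = 3.5 rad/rad.  Linearised about the lane centre the
compensatory loop is second-order with natural frequency ≈ 1.2 rad/s and
damping ≈ 0.8 — a deliberately human-like, not servo-like, bandwidth.

Four stages make the loop behave like a person rather than a controller:
percepts are sampled and held at 4 Hz (`perceive_interval` 0.25 s); the
deviation estimate passes through a running average with time constant
`est_tau` = 0.5 s (people smooth uncertain position cues; mechanically,
this keeps percept noise from appearing as high-frequency wheel velocity
and contaminating the stability metric); commands traverse a 0.2 s
reaction-delay line; and the arm is a first-order lag (`arm_tau` 0.1 s)
with per-step motor noise (SD 0.012 rad).

Anticipation is *timed*, not early: the previewed curvature refers to the
road 1 s ahead, so the feedforward is buffered until the car — net of
reaction delay, arm lag and mean percept staleness — reaches the previewed
point.  Without this alignment the agent steers a full second before each
bend and swings ~2.5 m wide at every entry.

**Learning.**  Exploiting the auditory channel is modelled as exponential
decay of the decoding-noise SD over training trials:

    σ_audio(t) = σ_min + (σ₀ − σ_min)·exp(−λ·t),

σ₀ = 1.2 m, σ_min = 0.06 m (the visual noise level — a fully trained
listener reads the cue about as well as a sighted driver reads the road),
λ = 0.12 per trial.  This is the simplest monotone mechanism that produces
the observed training curve; modelling learning as a gain change instead
would be an equally defensible alternative.

**Individual differences.**  Each participant's parameters are drawn once
from normal distributions around the defaults (SDs roughly 10–15% of the
mean, learning rate 25%, truncated at validity bounds), seeded by group and
participant index.

All control gains and noise SDs were calibrated once, jointly, so that the
default cohort reproduces the qualitative group-level pattern (occlusion
deficit, training recovery under SS, overlapping stability distributions),
and then frozen as the package defaults.

## Metrics

- **SDLP** (m): sample standard deviation of the signed lateral deviation
  over the whole trial.  Sample vs population SD is a convention choice;
  at N = 3600 the difference is negligible.
- **SWV** (deg/s): per curve-negotiation window, the maximum absolute
  steering-wheel velocity (central finite difference at 60 Hz, no
  smoothing); averaged over windows.  A window is a maximal run of records
  whose centreline projection lies in a bend — no lead-in/lead-out margin.
  With no bends the metric is a missing value, not zero.

Lower is better for both.

## Statistics

The design is a balanced split-plot: condition (3 levels, between) crossed
with a two-level repeated factor (first/last training trial, or last
pretest/first posttest trial).  `mixed_anova` computes the classical sums
of squares with the conventional degrees of freedom (interaction (2, 42)
for 3×15×2), Greenhouse–Geisser correction via Box's ε̂ from the pooled
within-level covariance (identically 1 at two levels, where sphericity is
vacuous), and partial η² = SS_effect/(SS_effect + SS_error).  A significant
interaction (α = 0.05) licenses simple main effects — the within effect
inside each group, F(1, 14), and the between effect at each level,
F(2, 42) with the one-way error at that level — and, where the between
effect is significant, all pairwise comparisons using t statistics on the
stratum's pooled error (df 42), adjusted by Shaffer's modified sequentially
rejective Bonferroni procedure.  For three groups Shaffer's achievable
truth counts are {0, 1, 3}, giving the threshold sequence α/3, α, α — at
least as powerful as Holm, which the test suite asserts.  All p-values are
two-sided.  Zero-variance inputs define F = 0, p = 1, ε = 1.

A Monte-Carlo utility (`simulate_null_type1`) draws whole experiments from
a null generative model (subject intercept + iid noise, no effects) and
confirms the interaction test's type-I error sits at the nominal 5%.

## What the generator does and does not emulate

The synthetic cohort reproduces: the occlusion deficit in SDLP, its
training-dependent recovery under auditory substitution, approximate
condition-independence of SWV, and the absence of interference (SS agents'
posttest equals their pretest).  It does **not** model: general motor-skill
learning (pretest trials show no warm-up trend), carry-over of training
across sessions (so the posttest VO deficit seen in humans has no
counterpart here — a VO agent under restored vision is simply an ND agent),
fatigue, attention, gaze, or speed control.  Passing tests therefore show
that the pipeline's geometry, encoding, metrics and inference behave
correctly and that the two-level control model is *sufficient* to produce
the headline pattern — not that human drivers implement it.

## Numerical notes and problem sizes

Fixed step 1/60 s throughout; no adaptive integration.  Course projection
uses a hint-seeded local search (the trial runner advances the hint every
step).  The default full experiment is 45 agents × 50 trials × 3600 steps
(~1.5 minutes on one core); unit tests use shorter trials and smaller
cohorts, and the type-I simulation uses 200 replicate experiments drawn
directly at the metrics level (no driving simulation needed under the
null).
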