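# Methods

This note documents the models, numerical choices and known limitations
of the `emgsynergy` simulation toolkit.  Everything stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted beyond what the code reproduces.

## EMG envelope model

The controller consumes *envelopes*: rectified, low-pass-filtered,
amplified surface EMG from an antagonistic forearm pair, normalized per
channel to 0 at rest and 1 at a nominal contraction.  The synthesizer
(`emg.synthesize_emg`) models an envelope as a first-order lag toward
scheduled plateau amplitudes (time constant = the burst's `rise_time`,
default 50 ms; the same constant governs decay to rest) plus additive
Gaussian noise truncated at zero (default sd 0.02 envelope units).  The
hardware preamplifier's true filter characteristics are not public, so
the lag model is a documented stand-in chosen to match
rectify-and-low-pass semantics; truncation keeps rest segments
non-negative with mean ≤ sd, which is what the Threshold deadband γ
(default 0.1, "just above the noise level") relies on.  All stochasticity
flows from a single integer seed per trace; traces are bit-reproducible
across runs.

## Synergy and mappings

`desired_joints` evaluates x_d[k] = A_k sin(E_M + φ_k) + b_k for the six
joints in the order (x_F1, x_F2, x_T1, x_T2, x_T3, x_T4); the default
parameter family ships in `data/default_config.yaml`.  Properties tested:
2π-periodicity, |x_d[k] − b_k| ≤ A_k, constant posture joints at
1.257/0.450 rad.

**Rhythmic.**  E_R = π sat(ωE) for δ=0 and 2π sgn(E) − π sat(ωE) for
δ=1, with sat applied to the product ωE (the distinction is immaterial
because sat clamps at ±1).  Range [−2π, 2π]; both branches meet at
π sgn(E) when |ωE| = 1, so a δ switch there is continuous.  The switch is
driven by the *measured* reference joint x_F2: δ goes 0→1 when the joint
reaches the level it holds at synergy phase π (the contact-stroke end)
and 1→0 at its phase-0 level (the cycle start).  For a reference sinusoid
with φ = −π/2 these levels are exactly the joint's maximum b+A and
minimum b−A; with the shipped φ_F2 = +1.571 the roles of the two levels
are swapped (the phase-π level is b−A = 0.581 rad).  The phase-based
definition is the one that makes the contract–relax ratchet advance the
phase monotonically — defining the switch on the literal extremes would
make relaxation retrace the contact stroke and counter-rotate the object.
Switch detection uses a tolerance band (default 2 % of the joint's
peak-to-peak range) with edge triggering: a switch fires only when the
joint *enters* a band, so parking at an extreme cannot chatter.

One inherent artifact is faithfully reproduced: after the δ→0 switch near
the cycle start, the residual relaxation tail maps to a small positive
contact-stroke phase and retraces it backwards, producing occasional
small backward rotations in Rhythmic operation.  A deliberately aborted
mid-stroke contraction produces a large one — the failure mode the
Threshold mapping is structurally immune to.

**Threshold.**  E_T holds while |E_E − E_F| ≤ γ and otherwise moves one
step toward the dominant channel.  The step equals the sample period
(1 ms), so the synergy phase rate is exactly ω rad/s and ω is the single
speed knob.  ω defaults to 3.0 (also the Rhythmic scaling, where it means
one third of nominal contraction spans a half-stroke).  Under sustained
one-channel activity ωE_T is strictly monotone, which is the
no-counter-rotation guarantee the benchmark verifies over 100 seeded
trials.

**Strokes.**  Phases [0, π) mod 2π are the contact stroke, [π, 2π) the
return stroke (half-open so each boundary belongs to one stroke).

## Kinematics and the task object

Each digit is a planar two-link chain: base at the origin, extension
along +x, palm-ward flexion toward −z.  Segment lengths (45/25 mm
proximal+middle/distal) are configuration, not measurement — no
dimensions are published for the hand — so Cartesian quantities are
verified as properties (closure, periodicity, frame invariance, stroke
partition at endpoints A and B), never against printed coordinates.  The
thumb uses the same two-link treatment (x_T2 proximal, x_T1 distal) with
the constant CMC angles folded into its base pose.

The 35 mm-diameter cylinder is placed by least-squares-fitting a circle
of its radius to the ideal contact-stroke fingertip arc, then nudging the
center radially until path/surface interference does not exceed the
configured grip depth (`bite_mm`, default 2.5 mm).  This guarantees the
whole contact arc grazes the surface and fixes the rotation sign so that
forward traversal unscrews (β > 0).

## Plant and contact

Joints are decoupled linear second-order systems
ẍ = k_m v − b_v ẋ + τ_contact/J (defaults J = 1 kg·mm², b_v = 20 /s,
k_m = 40 rad/s² per V, |v| ≤ 12 V), integrated semi-implicitly (damping
implicit) at the 1 kHz EMG rate; the implicit damping keeps the free
response unconditionally stable at stiff contact.  All plant constants
are stand-ins: the study plant was physical hardware and published no
constants, so closed-loop claims rest on properties and the geometry
oracle, not on hardware timings.

Contact is kinematic no-slip with hysteresis.  The cylinder engages when
the fingertip, during a contact stroke, touches or penetrates the surface
by at most the engagement band (3 mm), and stays engaged while the tip
remains within the band on either side of the surface; a tip far inside
the rim is treated as slipping past out of the contact plane (the planar
model's return path may cross the disc).  While engaged, the tangential
tip displacement between consecutive samples rolls the cylinder by
Δβ = s/r.  Penetration produces a radial spring force (0.1 N/mm) mapped
to joint torques through the digit Jacobian; the tendon readout is the
flexion-tendon load max(0, −τ)/r_pulley with a 10 mm moment arm — tendons
pull, never push.  The hysteresis plus the engaged-to-engaged
displacement rule removes a nonphysical artifact (band-edge flicker
rectifying controller dither into net rotation) that a memoryless
band test exhibits.

## Controller

V = −C sat(K_I ∫e dt + K_P e + K_D ė) with sat(s) = clamp(s/ε, −1, 1)
per joint; the drive stage applies polarity −1 because the simulated
motor gain is positive.  Defaults K_P = 8, K_I = 2, K_D = 0.2, C = 12 V,
ε = 0.05, K = 0.02 rad/N were frozen once from the sweep in
`scripts/tune_gains.py` on the nominal plant — reproducibility over
hardware realism.  The integrator halts while the manifold is saturated
(anti-windup; prevents limit cycles at stroke reversals) and ė is a
20 ms filtered finite difference.  Free-space steady-state RMS tracking
error at the default Threshold speed is ~1×10⁻³ rad per sinusoidal
joint, comfortably inside the boundary layer ε.

The two baseline laws (proportional open-loop V = C_IL E, and the hybrid
force-velocity form V = −C_MC sat(S_MC) with a configurable weighted-sum
manifold — its published description gives only the outer form, so the
weights are explicit configuration) drive a single closure joint.  Since
a 1-DOF hand cannot rotate a grasped object, the benchmark emulates the
wrench pattern: while gripped, a modeled arm turn advances β at 1 rad/s
up to a 1 rad wrist excursion per re-grasp.  With the canned grip-cycle
schedule this yields ~11 s completions, an order-of-behavior match to
1-DOF prostheses; the numbers are emulation outputs, not predictions.

## Synergy derivation pipeline

`synthesize_trials` emulates 40 Hz data-glove recordings of repeated
unscrewing: the truth sinusoid family (glove-named columns; FJ1b→x_F1,
FJ2→x_F2, TJ1→x_T1, TJ2→x_T2, near-constant TJ3/TJ4, small-amplitude
nuisance FJ1a/FJ3) at a per-trial cadence 1 ± 20 % Hz over 5 cycles, plus
0.02 rad angle noise (defaults).  What it does *not* emulate: sensor
drift and crosstalk, inter-subject amplitude differences, within-trial
tempo changes, or non-sinusoidal waveform detail — so passing recovery
tests show the pipeline is correct and well-conditioned, not that human
recordings are this clean.

`normalize_time` estimates each trial's cycle rate (prominence-based
peak counting on the reference joint, refined by a bounded
single-sinusoid least-squares frequency fit) and resamples every trial
to one cycle per unit of normalized time with a cubic spline — linear
resampling would bias amplitudes down by O((samples/cycle)⁻²), visible
at 40 samples/cycle.  `pca_contributions` eigendecomposes the covariance
of the mean-centred concatenated joint matrix (covariance, not
correlation: the loadings are then convertible to the per-joint
percentage contributions); on default synthetic data PC1 carries ~95 %
of the variance, versus ~73 % reported for real recordings — real hands
are messier than the generator, and the acceptance check is therefore
the one-sided bound PC1 > 0.70.  `fit_sinusoids` finds one shared
frequency (grid 0.5–1.5 cycles/unit, 101 points, then bounded scalar
refinement to xatol 10⁻¹⁰ on the highest-variance joint) and solves each
joint by linear least squares on a sin/cos/constant basis; amplitudes
are forced non-negative by phase flip, phases wrapped to (−π, π], and a
column with amplitude < 10⁻⁹ is reported as (A=0, φ=0, b=mean) by
convention.  `joint_space_error` is the mean absolute relative error
with samples |recorded| < 0.05 rad excluded; the metric is
ill-conditioned for joints whose trajectories cross zero (e.g. the thumb
MCP with b = 0), which is why recovery acceptance is stated on
parameters, not on this metric.

## Benchmark arithmetic

`percent_improvement` computes 100·(t_ref − t_new)/t, rounded to the
nearest integer half-away-from-zero, with the denominator (`new` or
`reference`) explicit because the published comparisons use both
conventions.  The package ships the human study's printed group-mean
completion times as a small reference table (`STUDY_GROUP_MEANS_S`) and
`reported_improvements` recomputes every derived percentage (177, 62,
32, 19, 21, 26, 9) and the 11.37 s able-bodied prosthetic-group mean
from them; the group-mean average is done in decimal so the half-cent
case rounds as printed arithmetic does.

The geometry oracle (`predicted_cycle_rotation`) integrates the no-slip
relation along the ideal fingertip path (1.75 rad per cycle with the
default configuration) and predicts completion in
(6 rad ÷ Δβ/cycle)·(2π/ω) ≈ 7.2 s; closed-loop trials land within 10 %
(measured ~3–6 % fast, mostly because completion occurs mid-stroke while
the prediction charges whole cycles).

## Problem sizes

Default test and acceptance runs use: 100 (tests) / 25 (acceptance
script) seeded Threshold trials at 1 kHz with a 60 s timeout; 20 (tests)
/ 5 (script) derivation round-trip seeds at 10 trials × 5 cycles × 40 Hz;
tracking characterization over 20 s.  These sizes make the full suite
run in about a minute on one CPU while keeping every Monte-Carlo bound
far from its threshold.

## Known limitations

* Planar, single-digit contact: the thumb is simulated kinematically but
  the cylinder is rolled by the first finger only; real unscrewing
  shares load between digits.
* The contact model has no friction cone or slip; rotation is purely
  kinematic within the engagement band.
* Plant constants, digit dimensions and baseline-hand parameters are
  plausible stand-ins, so absolute completion times are not comparable
  to human-subject timings — only orderings, properties and the printed
  arithmetic are.
* The Rhythmic mapping's small post-switch retrace (see above) slightly
  inflates its backward-event count relative to ideal operation.
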