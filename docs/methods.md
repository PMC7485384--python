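# Methods

## Model overview

`standreflex` simulates a person standing on a horizontally translating
platform in the sagittal plane and asks how much of the observed balance
behaviour delayed proprioceptive reflexes can explain.  The pipeline has
five stages: a rigid-body plant, Hill-type muscles, a reflex controller
gated by a center-of-mass (COM) dead zone, an episode protocol with an
effort objective and stance constraints, and a lexicographic particle swarm
optimizer that identifies controller parameters.  An evaluation stage
correlates simulated joint angles and moments against experimental (or
synthetic pseudo-experimental) recordings.

## Plant

Seven rigid segments — trunk (including head and arms), two thighs, two
shanks, two feet — connected by revolute hips, knees and ankles, with the
trunk floating.  Nine generalized coordinates: trunk x, trunk y (at the hip
joint), trunk pitch (forward positive), and six joint angles
(flexion/dorsiflexion positive, zero upright).  Left and right controls are
mirrored, so effectively six degrees of freedom matter.  Equations of motion
are assembled from analytic point Jacobians (M(q) q̈ = Q) and solved
directly; a 9x9 dense solve per step.

Anthropometry defaults to an 80 kg, 1.80 m adult using standard literature
mass/length/inertia fractions:

| segment | mass (kg) | length (m) | COM from proximal | gyration |
|---|---|---|---|---|
| trunk+head+arms | 54.24 | 0.846 | 0.45 L | 0.30 L |
| thigh (each)    | 8.00  | 0.441 | 0.433 L | 0.323 L |
| shank (each)    | 3.72  | 0.443 | 0.433 L | 0.302 L |
| foot (each)     | 1.16  | 0.274 | mid-sole | 0.475 L |

Every entry is overridable through the `build_plant` config.  The ankle
joint sits 5 cm behind the shank axis (`ankle_back`), so the standing plumb
line passes anterior to the ankle as in humans; without this offset the
whole-body COM sits directly over the ankle and realistic plantarflexor
tone would push the body over backwards.

Foot–platform contact acts at a heel and a toe point per foot: a unilateral
linear spring–damper normal force (30 kN/m, 300 N s/m per point) and
stick–slip friction implemented as a tangential spring anchored, in the
platform frame, where the point first touched, clipped at the Coulomb limit
mu*Fn (mu = 1).  The anchor formulation was chosen over velocity-regularized
Coulomb friction because the regularization stiffness mu*Fn/v_eps of the
latter is unconditionally unstable for a ~1 kg foot at the 1 ms fixed step.
Anchors living in the platform frame make a sticking foot follow the
platform exactly.

Soft joint-range stops (2000 N m/rad, 10 N m s/rad) bound each joint; the
knee's extension stop sits at 0 rad so the stance leg can rest against its
lock, which is both anatomically sensible and the only stable knee operating
point under tonic extensor drive.

The platform is driven kinematically — its trajectory is imposed, not
simulated — because its 1000 kg mass (kept as metadata) makes the reaction
of an 80 kg body negligible.

Integration is semi-implicit Euler at a fixed dt = 1 ms.  A fixed step
makes the reflex delays exact integer lags; 1 ms resolves the stiffest
retained dynamics (contact, ~300 rad/s) with margin.  Passive contact-free
energy drift is < 0.05% over 1 s (tested to < 0.1%).

## Muscles

Nine four-element Hill-type muscles per leg: iliopsoas, gluteals, rectus
femoris, biceps femoris long and short head, vastus, gastrocnemius, soleus,
tibialis anterior.  Each has a contractile element (CE) with bell-shaped
force–length (width 0.56, floor 0.05), a Hill force–velocity curve
(curvature 5, eccentric plateau 1.5 F_max, v_max 12 l_opt/s, soleus 6), a
quadratic-toe series elastic element (reference strain 0.04), a parallel
elastic element above l_opt, a buffer element below l_opt (1-w) that
prevents CE collapse, and normalized CE damping 0.1.  Pennation is a scalar
force-projection factor.  The CE velocity solves the force balance
F_SEE = pen (F_CE + F_PE + damping − F_BE) by safeguarded Newton iteration
to a residual below 1e-6 F_max, clamped at ±v_max.  Activation follows
first-order excitation–contraction coupling with 10 ms rise and 40 ms fall
time constants (exact exponential update).

Muscle routing uses constant signed moment arms (hip ±8 cm, knee 4–6 cm,
ankle 4–5 cm), so l_MTU = l_ref − Σ r_j φ_j; joint moments are F_SEE r_j.
Published parameters are used where printed: rectus femoris (l_opt 8.1 cm,
F_max 1200 N, slack 35 cm, pennation 0.5), biceps femoris short head
(l_opt 12 cm, F_max 1200 N, slack 10 cm, pennation 0.7), tibialis anterior
F_max raised to 4000 N (its activation stays low, so realized force remains
physiological).  Iliopsoas and gluteals are *lumped groups* of all
uni-articular hip flexors/extensors and carry group-level strengths
(2500/3000 N); with single-muscle strengths they cannot servo the ~54 kg
trunk.  Remaining values follow the reflex-walking muscle model family.

In the upright reference posture the CE sits at 0.8 l_opt with the tendon at
slack (`ce_ref`).  Operating on the ascending force–length limb means tonic
activity contributes genuine long-term joint stiffness (the slope of the
force–length curve seen through the taut tendon); at the optimal length the
slope vanishes and stance creep is much faster.  This is a deliberate model
calibration, stated here because every stance result depends on it.

## Controller

Per muscle: u = clamp(u0 + g_eff F̂_SEE(t−Δt) + g_eff (l̂_CE(t−Δt) − l_off)⁺,
0.001, 1), with force normalized by F_max and CE length by l_opt (the
published offset bounds 0.2–1.1 only make sense on the normalized scale).
Length feedback contributes only while the delayed normalized CE length
exceeds the offset.  Delays are per muscle (TA 35, soleus 44, gastrocnemius
54, vastus 100, biceps femoris heads 60, rectus femoris 82, hip muscles
40 ms), realized as exact integer-step lags.

g_eff implements the intermittent dead-zone law: with heel/toe contact
coordinates (platform frame) and edge distances x_heel, x_toe, the gain is
0 for COM inside [heel + x_heel, toe − x_toe], ramps linearly to −G over a
band z_heel x_heel on the heel side and to +G over z_toe x_toe on the toe
side, and saturates beyond — one scalar gain per muscle and modality whose
sign flips between heel and toe side.  The printed piecewise law has
inconsistent heel-side inequality directions; the continuous
piecewise-linear reading is implemented.  The dead-zone edge geometry is
frozen at the start of muscle control (the feet do not move on the platform
afterwards), and the COM signal is instantaneous by default with an optional
configurable sensing delay (20/100 ms variants).

## Episode protocol and scoring

Each episode: 1 s of joint-angle PD control toward the nominal stance
(muscles active underneath; per-joint gains 600/900/1500 N m/rad with small
ankle damping — the light foot forbids large explicit damping at dt = 1 ms),
1 s of muscle-only quiet stance, then the platform follows the perturbation
signal until t_total = 110 s.  Episodes stop early if the chest point drops
below 0.7 m.  Because the raw initial state rings on the contact springs
for several seconds, a PD-held pre-settle (default 10 s, not part of the
protocol timeline) precedes phase 1 so that the muscle handoff happens at
equilibrium.  The default nominal pose and tuned feedforward levels were
calibrated jointly so that the settled COM sits ~4 cm ahead of the ankle —
just above the deepest admissible heel-side dead-zone edge, because backward
falls are the least recoverable failure (the center of pressure can only
retreat to the heel, 7 cm behind the COM, while it can advance 16 cm to the
toes).

Scoring: effort f(z) is the time-average over the 100-s evaluation horizon
(starting at perturbation onset, t = 2 s) of the summed squared activations
of all 18 muscles.  Constraints: survived duration (past onset) > 100 s,
final chest height > 1.3 m, and mean *absolute* ankle excursion relative to
the platform < 0.05 m (the published integrand is formally signed; the
absolute value is used so slipping cannot cancel out).

## Perturbation signal

Random square pulses: amplitudes drawn i.i.d. uniformly from
{−5, −2.5, 0, 2.5, 5} cm and durations from {0.25 … 1.5} s, concatenated to
the requested length.  Amplitudes are absolute platform positions by
default (an incremental mode exists).  The sampled platform profile follows
the piecewise-constant target with a trapezoidal velocity profile — speed
capped at 1 m/s and acceleration at 5 m/s² — because a kinematically driven
platform must have finite velocity *and* acceleration: a pure slew-rate
limit would command instantaneous 1 m/s velocity jumps, i.e. unbounded
impulsive forces through the feet.  Signals round-trip
through a two-column time/position CSV, and a window (e.g. 100 s starting
at 53.73 s) can be extracted from a longer recorded trace.

## Optimization

The decision vector stacks u0 (9), force gains (9, absent in the
length-only architecture), length gains and offsets (9+9, absent in the
force-only architecture) and the four dead-zone parameters: 40 / 31 / 22
dimensions.  Bounds: u0 in [0.001, 1], gains in [−3, 3], offsets in
[0.2, 1.1], edge distances in [0, 0.10] m, transition fractions in [0, 1].
Candidates are scored by single shooting (one full episode) and compared
lexicographically: tier 1 is the summed normalized constraint violation
(duration shortfall / 100 s + chest shortfall / 1.3 m + excursion excess /
0.05 m), tier 2 the effort; any feasible candidate beats any infeasible
one.  The swarm is a standard global-best PSO (inertia 0.72,
cognitive = social = 1.49, velocity clamp 20% of range, reflection at the
bounds), deterministic under a fixed seed, with optional warm-start
particles.  Tuned presets shipped with the package were produced by a
staged run of this optimizer (quiet stance first, then half-amplitude, then
the full signal — a curriculum that finds the narrow feasible region much
faster than a cold start); the published parameter tables are shipped
unchanged as the reference presets.

## Evaluation

Experimental tables (CSV: time_s, hip/knee/ankle_deg, hip/knee/ankle_Nm)
are low-pass filtered with a zero-phase second-order Butterworth at 16 Hz
at their native rate, then linearly resampled onto the simulation time
points, and correlated signal-by-signal with Pearson's r (two-sided p from
the t-transform with n−2 degrees of freedom).  Zero-phase filtering avoids
lag bias in r; simulation output is noise-free and unfiltered.  Simulated
moments are net muscle moments per joint, averaged over the two legs.

## Synthetic data

The reference perturbed-standing dataset is emulated by corrupting a
simulated episode with band-limited Gaussian measurement noise: angle SD
0.1°, moment SD 2 N m, low-passed below 5 Hz, written at 100 Hz.  The noise
stands for the band-limited random component of processed optical motion
capture and inverse dynamics; systematic soft-tissue artifact is neither
white nor removable by correlation and is deliberately excluded.  The angle
magnitude is calibrated to the least-excited channel: this model stands
with its knees resting against their extension stop, so knee-angle
excursions are a few tenths of a degree, and a noise floor above that would
swamp the knee channel no matter how good the controller is.  The generator does **not** emulate
marker-level data, ground-reaction forces, EMG, inter-subject variability,
or un-modeled control channels (vision, vestibular); tests passing on
pseudo-experiments therefore demonstrate that the pipeline machinery is
correct and discriminative, not that the model reproduces any particular
human subject.

## Chaos, reproducibility, and how the checks are designed around it

Reflex-stabilized standing is a barely-stabilized chaotic system: two
trajectories differing in the last bit diverge visibly within tens of
seconds, so whether a 110-s episode ends upright can depend on the last
digit of a parameter or on instruction-level arithmetic details.  Three
design consequences:

* The engine is compiled for a *generic* CPU target and the mass-matrix
  solve is a hand-written Cholesky factorization rather than a
  LAPACK/BLAS call, so trajectories are bit-identical across machines and
  processes as far as the toolchain allows (they are exactly repeatable
  within a process in any case).
* The tuned presets were selected by requiring feasibility over an
  *ensemble* of perturbation signals simultaneously (worst-case
  lexicographic score over several generator seeds), which selects
  controllers whose stance attractor is deep rather than candidates that
  merely thread one specific episode.  Even so, survival of any single
  full-length episode under a new perturbation draw behaves
  statistically (roughly a 50-80% success probability per draw for the
  shipped presets).
* Checks that need a surviving reference episode (pseudo-experiment
  generation) rejection-sample the perturbation draw deterministically
  until every reference controller stands, and the end-to-end
  identification check seeds its swarm with the tuned preset plus small
  jittered copies, so one flipped marginal trajectory cannot fail the
  whole pipeline.

## Numerical choices and degenerate inputs

* Fixed dt = 1 ms everywhere; delays must be integer multiples of dt
  (validated at setup).
* CE-velocity root finding: monotone residual, safeguarded Newton within
  [−v_max, v_max], 80-iteration cap, velocity-bound clips counted and
  reported on the episode result.
* Dead zones whose heel edge passes their toe edge are rejected; dead-zone
  evaluation is continuous everywhere including ramp widths of zero.
* Zero-variance series make Pearson r undefined and raise.
* Episode scoring of a numerically failed candidate (non-finite state)
  marks it maximally infeasible instead of crashing the swarm.

## Problem sizes used by the shipped checks

Verification episodes run the full 110-s protocol at 1 kHz with 100 Hz
logging.  The acceptance script's swarm refinement uses 6 particles x 4
iterations warm-started from the tuned base preset, and the analytic PSO
benchmark uses 20 particles x 100 iterations; both sizes are chosen so the
whole script replays the pipeline end-to-end in minutes on one CPU.  The
in-repo tuned presets themselves come from the larger staged optimization
described above.

## Known limitations

* No muscle short-range stiffness, no velocity term in the spindle model,
  no vestibular/visual channels, no reflex modulation — by design, to
  isolate what delayed force/length feedback alone can do.
* Constant moment arms; attachment geometry is a documented default, not
  subject-specific.
* The published optimized parameter tables were found on a different plant
  (different anthropometry and muscle constants); shipped verbatim as
  reference presets, they do not stabilize this model, and re-optimized
  tuned presets are provided for it instead.
* Stance robustness is bounded by the heel-side geometry: perturbation
  sequences that throw the COM behind the heels are unrecoverable without
  stepping, which the model cannot do.
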