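# Methods

## System and coordinate conventions

The simulated system is a planar elbow with the shoulder locked and the
upper arm vertical.  The elbow sits at the origin of a world frame with
x anterior and y up; the elbow angle θ is measured between the forearm
and the downward vertical, so θ = 0 is the arm hanging fully extended
and θ = π/2 a right-angle flexion.  The forearm long axis points along
(sin θ, −cos θ).  The forearm plus any hand-held load rotate as one
rigid body.

Default inertial/geometric parameters (`data/default_model.yaml`):
forearm mass m = 1.53 kg, COM distance l_c = 0.18 m, sagittal-plane
forearm inertia about the elbow I = 0.02 kg·m², load distance
l_l = 0.35 m, gravity g = 9.81 m/s².  Two readings of the inertia value
are supported: `inertia_about: elbow` (default) takes the tabulated
value as already referred to the joint; `com` treats it as a COM value
and adds m·l_c².  The magnitude of the tabulated inertia relative to
m·l_c² ≈ 0.0496 kg·m² makes the first reading the natural one, but the
choice is consequential for the inertial torque and therefore exposed.
The hand-load distance is likewise configurable; 0.35 m is the default.

## Reference trajectories

Point-to-point references are quintic minimum-jerk motions,
θ(t) = θ₀ + Δθ(10s³ − 15s⁴ + 6s⁵), s = t/T, with analytic derivatives,
sampled on a uniform grid (both endpoints included) at the control rate
of 121 Hz.  The study tasks are 0 → 1.57 rad in T = 1 s (fast, peak
acceleration ≈ 9.1 rad/s²) and T = 2 s (slow, ≈ 2.3 rad/s²).
Robustness perturbations are available as a compactly supported C²
bump (`rapid_change`) or a smoothstep hold (`intermittent`), both with
analytically consistent derivatives.

## Muscle model

Six Hill-type muscles actuate the joint.  Architectural parameters
(maximum isometric force, optimal fiber length, tendon slack length,
pennation) are transcribed from the openly documented arm26 planar
upper-limb model; the activation/deactivation time constants
(0.010/0.040 s) and maximum shortening velocity (10 l_opt/s) are the
standard Thelen-muscle defaults.  Force generation is

F = F_max [f_l(l̃) f_v(ṽ) a + f_p(l̃)] cos φ

with f_l(l̃) = exp(−(l̃−1)²/0.45), a Hill hyperbola force-velocity curve
(zero force at ṽ = −1, C¹ eccentric branch saturating at 1.4), and an
exponential passive curve (shape 4, strain 0.6 at F_max) that is zero at
or below slack.

**Geometry.**  Muscle moment arms and MTU lengths are low-order
polynomials in the elbow angle, valid on [−0.1, 1.8] rad (evaluation
outside is clamped with a warning).  The moment-arm quadratics are fits
to published elbow moment-arm magnitudes (biceps peaking ≈ 4–4.5 cm in
mid/late flexion, brachialis ≈ 2.5–3 cm, triceps a near-constant
2.1–2.4 cm); the MTU-length polynomials are the exact antiderivatives
of the negated moment arms — so the geometric identity
dL/dθ = −d(θ) holds analytically — anchored so each fiber is at its
optimal length at θ = 45° (mid-range), which places normalized fiber
lengths in a physiological 0.72–1.2 band over the task.  These
polynomials are a synthetic stand-in for the original model's
wrapping-surface paths and are the main acknowledged source of
quantitative tolerance in the reproduced numbers.

**Tendon.**  The tendon is rigid; the fiber absorbs all MTU length
change through a constant-thickness pennation model
(l sin φ = l_opt sin φ_opt).  This keeps the per-instant redundancy
problem algebraic and is the conventional simplification when the
control loop, not tendon elasticity, is the object of study.

**Activation dynamics.**  da/dt = (u − a)/κ with
κ = κ_act(0.5 + 1.5a) when u > a and κ = κ_deact/(0.5 + 1.5a)
otherwise.  The inversion used by the command generator selects the
branch by the sign of the demanded rate (the branches agree at zero
rate); excitations are clamped to [0, 1] and clamps logged.

## Control loop

Each 121 Hz control step: (1) read the fed-back (θ, θ̇) from the
forward model; (2) compute the gravity-compensation assist moment from
the fed-back angle (assist ON) and map it to cable tensions; (3)
inverse dynamics with PD feedback (k_p = 900, k_v = 60) gives the
required muscle moment, the assist moment entering as a credit; (4)
static optimization distributes it; (5) the target-activation rate
(backward difference, zero at t = 0) is inverted to excitations; (6)
forward dynamics advances one interval with excitations and tensions
held (zero-order hold).  The initial state is θ(0) = θ_ref(0),
θ̇(0) = 0, with activations set to the static-optimization solution of
the t = 0 demand, avoiding an artificial startup transient.

The literal sign reading of the inverse-dynamics equation (gravity and
assist subtracted wholesale) is available behind
`settings.literal_dynamics_sign` for comparison; the default form is
the one consistent with assistance *reducing* the muscle moment.

**Static optimization.**  min Σaᵢ² subject to the moment equality and
0 ≤ aᵢ ≤ 1 has KKT solution aᵢ = clip(λwᵢ/2, 0, 1) with wᵢ = dᵢ·capᵢ;
the scalar λ is found by bisection on the monotone piecewise-linear
constraint residual, giving an exact, deterministic solve (tolerance
1e-6 N·m on the equality).  If the demand exceeds total muscle
capacity a reserve actuator (quadratic penalty weight 1000) absorbs
the residual and a warning is logged; it engages only on infeasible
steps.  An independent SLSQP solve and a brute-force grid search serve
as cross-checks in the test suite.

**Integration.**  Adaptive RK45 with rtol 1e-6, atol 1e-8 and a
maximum step of 8 ms (configurable within 4–20 ms; results vary by
< 2 % RMS across that range).  A soft-stop check aborts with
diagnostics if θ leaves [−0.2, 2.0] rad.

## Exosuit

Cables are straight segments from an upper-arm strap anchor (fixed in
the world, since the upper arm is vertical) to a forearm strap anchor
rotating with the forearm.  Default flexor anchors: (0.04, 0.14) m on
the upper arm and (0.02, 0.15) m on the forearm (first coordinate
anterior offset, second along-segment).  A mirrored single anchor pair
cannot serve the extensor cable: beyond ≈ 25° flexion the mirrored
straight segment crosses to the flexion side of the joint and its
extension moment arm changes sign.  The default therefore routes the
extensor cable low and posterior, hugging the olecranon
((−0.04, 0.06)/(−0.04, 0.02)); the gravity-compensation task never
tensions it (τ_a ≥ 0 over the task range), so this choice does not
affect the reported metrics.  Mirrored or fully custom extensor
anchors remain configurable.

Interaction forces at the forearm strap are the taut cable's force
decomposed in the forearm frame (normal ⟂ axis, shear ∥ axis).  Because
the assist law depends only on θ, these forces are functions of angle
alone — slow and fast runs give identical strap forces at matched
angles.

## Metabolic model

Umberger-family energetics per muscle, with muscle mass
ρ F_max l_opt/σ (ρ = 1059.7 kg/m³, σ = 0.25 MPa): basal 1.2 W/kg;
activation+maintenance heat (128·FT + 25) W/kg scaled by A^0.6
(A = u if u > a else (u+a)/2), split 40 % activation / 60 % maintenance
with the maintenance share scaled by f_l above optimal length;
shortening heat with α_ST = 100/v̄_max,ST (v̄_max,ST = v̄_max/2.5) and
α_FT = 153/v̄_max scaled by A²; lengthening heat 0.3·α_ST scaled by A;
work rate Ẇ = −F_fiber·v_fiber with absorbed work clamped to zero by
default (`allow_negative_work` to disable).  Fast-twitch fraction
defaults to 0.5 (mixed arm musculature).  The five-term bookkeeping
identity Ė = Ḃ + Ȧ + Ṁ + Ṡ + Ẇ holds at every sample by construction
and is asserted in the tests.  Only the six modeled muscles contribute;
no whole-body basal term is added.

## Summary metrics

For a matched assist OFF/ON pair: RMS over the task window per channel;
"biceps-group activation" is the mean of the per-muscle RMS activations
over the three flexors (biceps long, biceps short, brachialis) —
a two-head biceps-only grouping is also computed; percent reduction is
100·(RMS_off − RMS_on)/RMS_off; strap-force peaks are maxima over the
assisted run.  The acceptance script evaluates, per speed/load
condition, matched OFF/ON pairs of 122 (fast) or 243 (slow) control
samples — the full task at the native 121 Hz rate, a few seconds of CPU
per pair.

## What the simulation does and does not show

The pipeline is fully deterministic: model knowledge is exact, the
redundancy solve is exact, and the excitation inversion anticipates the
activation lag.  Assisted runs therefore approach the theoretical
minimum of residual muscle activity.  A physical human-exosuit loop
(or a co-simulation with imperfect numerical coupling) retains more
assisted-phase activation from feedback corrections, co-contraction and
model mismatch, so the assist benefits computed here are best read as
upper bounds on each metric; directions of effect and load/speed trends
are the robust outputs.  Joint reaction forces additionally depend on
muscle force *directions*, which here come from effective straight-line
origin/insertion points rather than anatomical curved paths — reaction
magnitudes are indicative, not anatomical.  Strap interaction forces
depend on the cable pull angle at the forearm anchor and hence on strap
geometry details beyond the two anchor points.  Reaction forces are
reported as the force on the forearm in the world frame.

Known limitations: no tendon elasticity, no shoulder degree of freedom,
no joint-limit contact or passive joint structures, no Bowden-cable
friction or strap compliance, no muscle fatigue, and no wrapping
surfaces in the muscle geometry.
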