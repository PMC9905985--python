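# Methods

`armreach` simulates goal-directed reaching of a planar right arm driven by
antagonistic Hill-type muscle pairs whose passive elastic behaviour can be
stiffened to emulate ageing, and maps the consequences for reaching
accuracy over the arm's workspace.  This note records the model, the
numerical choices, and the reasoning behind the defaults, in the package's
own words.

## Rigid-body model

The arm is a planar chain of three moving segments — upper arm, forearm,
hand — attached to a fixed upper chest, with hinge joints at shoulder,
elbow and wrist.  Movement is confined to the horizontal plane, so gravity
exerts no in-plane joint torques.  The shoulder sits at the origin with the
chest bar along the negative x axis (contralateral side); angles are
counter-clockwise with flexion positive.

The equations of motion M(q) q̈ + C(q, q̇) q̇ = τ are the closed-form
Lagrangian terms of the planar chain, assembled in absolute segment angles
θᵢ = Σ_{j≤i} qⱼ where the kinetic-energy coupling is a constant matrix
A with M_θ[j,l] = A[j,l] cos(θⱼ−θₗ) + δ_{jl} Iⱼ and the velocity-product
term A[j,l] sin(θⱼ−θₗ) θ̇ₗ².  The joint-space forms follow by the linear
map θ = T q.  The implementation is validated in the test suite against an
independent symbolic Euler–Lagrange derivation (sympy) and by
forward/inverse round trips and energy conservation in free swing.

Joint ranges of motion are enforced by a stiff one-sided penalty torque
(200 N·m/rad) with damping (5 N·m·s/rad) engaged only beyond the limit.
A penalty keeps the vector field piecewise smooth for explicit
integration, and its stiffness is far below anything that would challenge
the 0.25 ms integration step.

Default geometry (standard adult-arm anthropometry): segment lengths
0.31 / 0.27 / 0.15 m (full reach 0.73 m, chest bar 0.44 m), masses
2.1 / 1.2 / 0.5 kg, centre-of-mass offsets at 45/43/40 % of segment
length, inertias 0.0182 / 0.0079 / 0.0010 kg·m².  Joint ranges: shoulder
0–180°, elbow 0–150° (flexion only), wrist ±40°.  The initial posture is
shoulder 60°, elbow 90°, wrist 0°, placing the endpoint at
(−0.209, 0.478) m, well inside the workspace.  All values live in the
versioned configuration (`armreach.config`), nothing numeric in the
dynamics kernels.

## Muscle model

Six Hill-type muscles, one flexor/extensor pair per joint, produce

    f_tot(l, l̇, t) = f_max [ f_a(l, l̇) a(t) + f_p(l) ]

- **Paths.** Straight-line equivalents with constant moment arms:
  l(q) = l₀ − r (q − q_init) with signed arm r (flexor positive), so the
  moment arm equals −dl/dq exactly.  At the initial posture every muscle
  sits at l/l₀ = 1; consequently, when the passive slack length is 1.0,
  any movement away from the initial angles stretches one muscle of each
  moving joint into its passive region.  Moment arms (17.25 / 14.4 /
  16 mm at shoulder/elbow/wrist) are sized against the joint ranges so
  the largest normalized elongation over the feasible joint box is ≈1.24,
  below the 1.26 bound at which passive force would engage in the
  reference scenario; the shoulder muscles undergo the largest relative
  length changes.
- **Active scaling.** f_a = f_l · f_v with a Gaussian force–length curve
  f_l = exp(−(l̄−1)²/0.45) (f_l(1) = 1) and a Hill-type force–velocity
  factor: concentric (1−s)/(1+s/0.25) for shortening fraction s of
  v_max = 10 l₀/s, eccentric plateau rising to 1.5 with initial slope 10.
  Both curves are injectable through the configuration.
- **Activation dynamics.** A third-order chain of first-order lags
  (τ = 15 ms each) maps excitation u ∈ [0,1] to activation a.  The chain
  is monotone and bounded: a stays in [0,1] for any admissible excitation
  signal, converges to constant u, and never jumps.
- **Passive element.** f_p(l̄) = s_p (e^{r_p(l̄−l_p)} − 1) above the slack
  length l_p, zero below; identical parameters for all six muscles within
  a scenario.  Nine scenarios are built in: a no-passive-force reference
  (l_p = 1.3, beyond the feasible length range, so f_p ≡ 0) and eight
  ageing scenarios A–H crossing s_p ∈ {0.05, 0.075}, r_p ∈ {5, 8},
  l_p ∈ {1.1, 1.0}.  Severity is ordered by the work
  s_p[(e^{r_pΔ}−1)/r_p − Δ], Δ = l̄_max − l_p, needed to stretch a muscle
  to the model's maximum normalized length; at the computed l̄_max ≈ 1.24
  the order is strictly A < B < ... < H.

The full simulator state is 24-dimensional: 3 angles, 3 velocities and
six 3-state activation chains, integrated jointly (no operator
splitting).

## Planning and control

Reaches track a straight endpoint path with the minimum-jerk profile
s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ (peak speed 1.875 d/T).  Reach duration follows
T = max(0.6 s, d / 0.5 m s⁻¹) — an average speed typical of comfortable
reaching — and the simulation continues through a 1.0 s homing window
after the plan ends.  The planner never clamps out-of-workspace targets.

The endpoint reference is converted once per reach to a joint-space
reference by damped-least-squares differential inverse kinematics
(damping 0.01 m, endpoint-feedback 50 s⁻¹, integrated at the control
rate, clamped to joint limits).  The chain's one-DOF redundancy is
resolved by minimum joint velocity plus a nullspace attraction (gain
5 s⁻¹, ramped with path progress) toward a goal configuration computed
beforehand by deterministic multi-start damped Newton — without the
attraction, greedy clamped IK gets trapped at joint limits for targets
that require strongly flexed final postures.  Velocities and
accelerations follow by central differences; during the homing window
the endpoint path holds the target and the IK settles exponentially
onto a feasible target posture, which serves as the homing reference.

The controller runs at 1 kHz with zero-order-hold excitations.  Each
step:

1. **Prediction.** The model's own dynamics are integrated over
   t_pred = n_pred · 1 ms holding the current excitations (a perfect,
   noise-free internal forward model).
2. **Desired torque.** τ_des = inverse-dynamics feedforward along the
   reference at t + t_pred plus per-joint PD correction on the predicted
   tracking error.  The seven tuned parameters are the three kp, three
   kd, and integer n_pred.
3. **Excitation inversion.** Per joint, the torque already produced
   passively at the predicted state is subtracted; the sign of the
   remainder selects the agonist (so the flexor and extensor are never
   co-excited, though activations may overlap); the required activation
   follows from the active force scaling at the predicted operating
   point (floored at 0.05 to avoid blow-up far from optimal length); and
   a first-order lead u = a_req + c_lag(a_req − a) with
   c_lag = max(3τ/t_pred − 1, 0) compensates the activation lag.
   Excitations clamp to [0,1]; unreachable demands saturate at 1.

Co-activation in simulations is therefore emergent: it arises when the
desired torque changes direction faster than activations decay, not from
planned co-excitation.

## Integration

The plant is integrated with fixed-step classical RK4, four substeps per
control period (h = 0.25 ms).  The fastest model time constants
(activation 15 ms; limit-contact frequency ≈ 200 rad/s) are resolved
with large margin, and halving the step changes the tracking error by
far less than 1 %.  The homing phase of a marginally tuned controller
carries low-amplitude agonist-switching chatter — a hybrid-system
effect — so the tiny homing-in error converges in absolute (≪0.1 mm)
rather than relative terms; well-tuned reaches settle smoothly.  The
prediction step inside the controller uses RK4 at the full 1 ms control
step, which is the dominant simulation cost.  A fixed-step integrator
was preferred over an adaptive stiff solver because the predictive
controller re-integrates the model at every control step, making
per-step adaptive restarts the bottleneck; the kernels are numba-compiled.

## Workspace and target sets

The workspace boundary is estimated from the forward-kinematic images of
the joint-box faces (dense per-face grids) outlined by a concave hull, so
every polygon vertex is itself the image of a feasible configuration;
Monte-Carlo containment (10⁵ random configurations) verifies the estimate
to the sampling resolution (≈1 mm).  Three target sets are generated:

- **(i) optimization sequence** — four targets near the distal-left,
  distal-right, proximal-right and distal-forward edges, where extreme
  joint angles make the tuning objective sensitive to passive force;
- **(ii) rectangular grid** — 0.05 m spacing over the workspace bounding
  box (targets outside the boundary are kept for plotting but excluded
  from aggregates);
- **(iii) boundary rings** — concentric arcs covering the distal boundary
  and a 0.20 m band inside it, split into the right subset (straight arm
  swept over the shoulder range) and the left subset (straight
  forearm+hand swept over the elbow range at full shoulder flexion).

## Metrics and failure taxonomy

The homing-in error e_h is the time-averaged endpoint–target distance
from the moment the planned trajectory reaches the target to the end of
the simulation; the movement error e_mv is the time-averaged deviation
from the planned path over the reach.  Both are reported in millimetres
and use trapezoidal time integration.  Per-joint co-activation is the
time average of min(a_flexor, a_extensor) over the whole movement — the
plain reading of simultaneous non-zero activation of the pair.

Failures are classified from the homing phase: a reach with e_h at or
below 1 mm is a success; otherwise it is **oscillatory** when the slope
of the distance-to-target signal changes sign more than 6 times with
peak-to-trough amplitude above 1 mm, else **stopping short**.  The
detector's thresholds are configurable; the taxonomy is descriptive,
mirroring the two failure morphologies the simulations produce (a static
force balance short of the target versus failure to stabilize).

## Control-parameter tuning

The seven parameters are optimized by an in-house mixed-integer genetic
algorithm (tournament selection of size 3, uniform crossover p = 0.7,
per-gene Gaussian mutation with σ = 10 % of range, integer-resampling
mutation for n_pred, 2 elites) minimizing the mean e_h over target set
(i).  Desk-scale defaults are population 40 and 60 generations; gain
bounds kp ≤ 1000 N·m/rad and kd ≤ 50 N·m·s/rad are set generously around
the feedforward-validity scale, and n_pred ≤ 25 steps.  Re-tuning an
ageing scenario injects the known baseline/reference optima into the
initial population; with elitism the result can never score worse than
the injected optimum.  The parameters shipped under
`armreach/data/control/` were produced by these seeded desk-scale runs
(provenance — seed, population, generations, objective — is stored in
each file).

## Synthetic study conditions, and what tests do not show

All inputs are generated programmatically: target grids from the
geometry, scenarios from the built-in table, and reaches from the
deterministic simulator (no random numbers outside tuning).  The model is
an idealization — noise-free sensing, perfect internal models, no
tendons or series elasticity, no short-range stiffness, steady-state
Hill curves, a single planned submovement per reach, and constant
moment arms.  Passing tests therefore demonstrate properties of this
idealized plant and controller, not of human reaching: in particular the
sub-0.1 mm accuracies are the noise-free ceiling, and the oscillatory
failures reflect PD feedback with delays rather than any measured
human behaviour.

## Known limitations

- Muscle paths with constant moment arms cannot reproduce posture-
  dependent moment-arm variation; relative elongations were calibrated
  at the joint-range extremes instead.
- The excitation inversion linearizes the third-order activation lag;
  at saturation (demands beyond capacity at u = 1) tracking degrades
  gracefully but the inversion error is uncontrolled.
- The workspace polygon is a sampled estimate; containment is exact only
  to the face-sampling resolution.
- The GA is desk-scale; tuned parameters are good local optima, not
  certified global ones, and re-runs with other seeds can find different
  gain vectors of similar objective.
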