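# Methods

`posturecoord` studies how in-phase and anti-phase hip–ankle coordination
modes self-organize when a standing body learns a supra-postural task — 
tracking a horizontally oscillating target with the head — by model-free
reinforcement learning.  This note documents the model, the reward design,
the learner, the analysis layer, and the numerical and design choices made
where the problem was genuinely open.

## Plant: planar double inverted pendulum

The standing humanoid is reduced to a sagittal-plane two-link chain: link 1
lumps both legs (ankle pinned to the ground), link 2 is the head–arms–trunk
(HAT) segment articulated at the hip.  Mirroring the two legs makes the
effective system 2-DOF, which is the regime the original 3D simulation also
operated in.

Aggregate anthropometry (default: mass 40.15 kg, stature 1.57 m, upright
whole-body CoM at 0.814 m) is resolved into segment parameters with fixed
fractions — legs 32 % of mass, HAT 68 %, leg length 53 % of stature, leg CoM
at mid-length — and the HAT CoM offset is solved exactly so the upright
whole-body CoM matches the prescribed height.  Segment inertias use the
slender-rod value about each segment CoM.  An added upper-body load (the
transfer experiment) is a point mass at the HAT CoM.

Dynamics are the standard manipulator equations
`M(q)q" + C(q,q')q' + G(q) = tau_active + tau_passive` with passive joint
spring-dampers `-K(q - q_neutral) - D q'` about the upright neutral.
Defaults: ankle stiffness 25 N·m/rad, hip stiffness 125 N·m/rad (the study's
baseline), damping 2 N·m·s/rad per joint (unspecified in the source
material; chosen as a small, physiologically plausible value and exposed in
config).  Active torques saturate at ±100 N·m.  Joint limits (ankle ±50°,
hip −120°/+45°) are enforced by clamping with velocity zeroing — a soft
treatment appropriate for trajectories that should never reach the stops.

Integration is fixed-step RK4 at 240 Hz with a control decimation of 4
(policy acts at 60 Hz).  The undamped, unactuated system conserves
kinetic + gravitational + elastic energy to ~1e-10 relative over 10 s,
which the test suite checks against a 1e-6 bound.

**Fall rule.** A step is a fall when the trunk reference height drops below
1 m.  The reference point is the trunk segment's geometric midpoint
(hip→head midpoint, 1.201 m upright), not the mass-weighted HAT CoM: the
planar mass split puts the HAT CoM at 1.0014 m upright (it must, given the
aggregate CoM constraint), so a 1 m threshold on the mass-weighted point
would fire at a ~3° lean and make the 0–0.2 m target excursion unreachable.
The segment midpoint is the closest planar analogue of the 3D torso body
the rule originally referred to, and leaves ~33° of combined lean before a
fall is declared.

**Center of pressure.** CoP is reported in meters relative to the ankle,
from the whole-body Newton–Euler balance: the ground-reaction wrench must
close the moment equation about the ankle pin, giving
`cop_x = (M_gravity - dH/dt) / F_z`.  In the static limit this is the
horizontal CoM projection (tested).  A momentarily unloaded foot
(`F_z <= 0`, only possible mid-topple) is logged as NaN CoP inside episodes
and raises in the public one-shot API.

## Task and reward

The target moves as `x(t) = -A cos(2π f t) + A` (range [0, 2A], default
A = 0.1 m); the chirp mode integrates the instantaneous frequency
`f(t) = f0 + r t`.  The per-step reward is

    R_total = α R_stay + β R_target + γ R_energy + γ R_torque
    R_stay   = (1 + ‖P_f0 − P_ft‖²)⁻¹          (≡ 1 here: the ankle is pinned)
    R_target = (1 + (x_target − x_head)²)⁻¹
    R_energy = − Σ_j |τ_j ω_j| Δt               (joules)
    R_torque = − Σ_j (τ_j / s)²

with `R_total = −1` whenever the trunk falls below the threshold,
overriding everything else.

Two scale choices required care:

* **Torque scale `s`.** With raw N·m torques the squared-torque term reaches
  O(10⁴) per step and the optimal policy is to fall immediately.  Training
  nondimensionalizes torques by the gravitational stall scale
  `s = M g H ≈ 619 N·m` (body weight × stature), the standard biomechanical
  normalization.  `compute_reward` defaults to `s = 1`, i.e. the printed
  arithmetic.
* **Tracking weight β.** The energy term is kept in physical joules — it is
  what makes the energetically cheaper coordination mode preferable — so at
  γ ≈ 20 it contributes O(1) per step for a fast-tracking policy, while the
  tracking term can gain at most ~0.04·β per step on a 0.1 m task.  α and β
  are not specified by the study; defaults α = 1, β = 2000 put the reward in
  the regime the study's results imply: every converged policy tracks
  (target–head r ≥ 0.97 in all its reported conditions) and the energy
  terms select *among* tracking solutions.  With a small β the
  energy-optimal policy simply ignores the target, which contradicts the
  reported phenomenology.

The policy observation is the fixed 8-vector
`[θ_ankle, θ_hip, ω_ankle, ω_hip, x_head, ẋ_head, x_target − x_head,
ẋ_target]`, scaled componentwise by fixed constants before the networks.

Training episodes last 20 s (evaluation 100 s), start from a small random
perturbation of upright (angles σ = 0.03 rad, velocities σ = 0.1 rad/s) and
a uniformly random target phase; falls terminate the episode.  The random
phase removes the otherwise-free post-fall reset (head and target both at
zero) and exposes the policy to every part of the cycle early.

## PPO learner

An actor–critic PPO with the clipped surrogate
`min(w_t Â_t, clip(w_t, 1±ε) Â_t)`, squared-error value loss, and GAE
(γ = 0.99, λ = 0.95; the advantage estimator is not specified by the study).
The actor is a Gaussian with a state-independent learned log-std; actions in
[−1, 1] scale to the torque limit.  Networks are tanh MLPs written directly
in NumPy (float32, orthogonal init, hand-derived gradients, Adam): no deep
learning framework is required, and the 8-D/2-D problem is comfortably
inside what a CPU BLAS handles.

Value targets are affinely normalized by running statistics before the
critic fit; returns on this task are O(10³) and a small-initialization
linear head would otherwise spend most of training climbing to that scale.

The learning rate adapts to a KL threshold of 0.002 (halve above 2×, grow
1.5× below ½×, bounds [1e-6, 1e-2]).  Advantages are normalized per update.
Per-update diagnostics record mean reward, fall rate, approximate KL, clip
fraction and the first-epoch ratio error (which must be 1 to float
precision: old policy = new policy before the first minibatch).

Because PPO on an unstable plant oscillates between good and degraded
policies, the trainer returns the best snapshot over the run, scored every
20 updates by short deterministic evaluation episodes (any fall
disqualifies the snapshot).  Training is bit-reproducible per seed on one
worker.

**Profiles.**  The `paper` profile mirrors the reported hyper-parameters:
hidden [256, 256], 8192 environments, minibatch 8192, horizon 32, 5 epochs,
5M steps.  The `desk` profile is the CPU-scale configuration every result
in this repository uses: hidden [96, 96], 256 environments, minibatch 2048,
3M steps, initial action std 0.2.  These sizes are the package's chosen
desk scale: large enough that the coordination phenomenology reproduces,
small enough that a single condition trains in about 1–2 minutes on one
core.  For desk-profile condition sweeps the initial exploration std
additionally scales with target frequency
(`0.2 + 0.05 (f − 0.2)`, clipped to [0.15, 0.3]): the torque modulation a
tracking policy must discover grows with the target's acceleration demand,
and a fixed noise scale either under-explores fast conditions or
over-perturbs slow ones.

## Coordination metrics

* **Mode**: Pearson correlation between the hip and ankle angle series;
  labels `in_phase` (r > 0.1), `anti_phase` (r < −0.1), `ambiguous`
  otherwise.  The dead band avoids noise-driven label flips; the sign is
  what carries the science.
* **Relative phase**: per target cycle, the ankle and hip peak times are
  extracted (series low-pass smoothed by a Hann kernel ~0.2 cycles wide,
  argmax refined by a least-squares parabola over ~0.25 cycles) and the
  printed convention `|t0 − t1| · f · π` is averaged over cycles, with the
  conventional lag `2π f |Δt|` reported alongside.  The printed formula
  gives π/2, not π, for a half-period lag; both are reported rather than
  silently "fixing" the convention.
* **Amplitudes**: per-cycle oscillation amplitudes (joint angles, torques,
  head) are estimated from the fundamental Fourier component of each cycle.
  For sinusoidal cycles this equals the half range; unlike the raw
  max − min it carries no extreme-value noise bias (5 % additive noise
  inflates a raw range by ~7 %, violating the 3 % recovery tolerance the
  fixture suite enforces).
* **Energy cost**: `Σ_t Σ_j |τ_j ω_j| Δt` in joules over the evaluation
  window, on physical torques.
* **Windowed correlation / transition frequency**: sliding Pearson r
  (default window 300 samples = 5 s at 60 Hz) against the chirp's
  instantaneous frequency; the transition frequency is the linear
  interpolation of the first positive→negative zero crossing, with an
  explicit no-transition result otherwise.
* Episode summaries drop the first two target periods as transient and
  refuse windows containing a fall.

## Synthetic fixtures

`synthetic.gen_coordination_pair` produces sinusoidal hip/ankle pairs with
prescribed frequency, amplitudes, peak lag and relative noise; head
position is computed through the plant's forward kinematics so fixtures are
geometrically consistent.  `gen_mode_switch_series` produces a chirp whose
hip–ankle lag flips to half the instantaneous period when the frequency
crosses a programmed value.  Torque channels are passive-stiffness proxies
(−k·θ), labeled non-dynamic: they give the energy metric aligned
torque/velocity series without solving the equations of motion.  The
generators are the oracle for the metrics layer (every fixture parameter
must be recoverable within stated tolerances), and identical seeds yield
identical logs to the byte.

What the fixtures deliberately do not emulate: learned-policy transients,
asymmetric or non-sinusoidal cycles, and torque–kinematics consistency.
Metric tests passing on fixtures therefore validate the estimators, not
the realism of any trained behavior.

## Experiments

`run_sweep` drives the four study factors — target frequency (0.15–1.50 Hz),
energy weight γ (0–40 at 0.4 Hz), hip stiffness (25–200 N·m/rad at 0.5 Hz),
and added upper-body mass (0–4 kg at 0.4 Hz) — plus the stiffness×frequency
grid, producing one tidy row per (condition, seed) with resumability by
condition hash and failure rows instead of silent gaps.  The added-mass
sweep never retrains: it evaluates a single policy trained on the fixed
frequency set (per-episode frequency sampling), which is the transfer test.
`run_chirp_eval` runs one continuously accelerating episode (default
0.036 Hz/s for 25 s) and locates the in-phase→anti-phase transition
frequency.  `make_report` renders the correlation/phase curves, CoP
summaries and the grid heat map.

## Desk-scale results, and what they show

The test suite trains, at desk scale, the two ends of the frequency sweep
(0.2 and 1.2 Hz, γ = 20, three seeds each) and the γ ∈ {0, 20} pair at
0.4 Hz.  Checked claims: the hip–ankle correlation is positive at 0.2 Hz
and negative at 1.2 Hz for the majority of seeds; converged runs track the
target with r > 0.9 (a run "converges" when its 100 s deterministic
evaluation is fall-free and yields analyzable oscillations); and the γ = 20
policies consume less energy than γ = 0 for the majority of seeds.  These
are direction-and-sign replications at a few hundredths of the original
compute budget, not numerical reproductions of the reported tables; the
full printed condition lists remain available through the `paper` profile
presets.

## Known limitations

* The planar reduction fixes the feet to the ground; `R_stay` is constant
  and CoP excursions are reported for plausibility only, with no foot-size
  constraint.
* Mode identity at intermediate frequencies (≈0.4 Hz) is genuinely
  bistable at desk scale: both coordination modes track well and their
  energy gap per step is small, so the seed decides which basin PPO lands
  in.  The majority-vote claims acknowledge this.
* The hip-angle sign convention allows a larger backward than forward
  range (the tabulated limits applied verbatim); motion amplitudes in all
  studied conditions stay far from either stop.
* Checkpoints are float32 NumPy archives; training across BLAS
  implementations is reproducible only on identical kernels.
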