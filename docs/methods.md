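# Methods

`myoarm` simulates a planar human elbow driven interactively (through
schedule files or programmatic controllers) in one of three actuation modes,
with a goal-directed flexion task on top. This note documents the model, the
defaults and why they were chosen, the numerical choices, and what the
synthetic fixtures do and do not establish about real data.

## Rigid-body model

The upper arm is fixed; the forearm-plus-hand is a single rigid link of
moment of inertia `I` about a frictionless hinge. The flexion angle θ is 0 at
full extension and increases counterclockwise (into flexion); the task runs
from 90° to 135°. The plane is treated as horizontal, so gravity exerts no
joint torque. Two passive torques act:

* **Ligament**: `T_lig(θ) = k_l (exp(c_l (θ_min − θ)) − exp(c_l (θ − θ_max)))`,
  a double-sided exponential that is negligible in mid-range and walls off
  the physiological range of motion (ROM) at both ends. Physiological ROM has
  two ends, hence the two-sided form.
* **Damping**: `T_damp = −b ω`. Damping exists in the modeled system
  expressly to make *stopping on a target* feasible; without it the success
  criterion below would be unreachable in a frictionless environment.

Equation of motion: `I ω̇ = T_active + T_lig + T_damp`.

Defaults: `I = 0.075 kg·m²` (forearm+hand scale), `b = 0.8 N·m·s/rad`,
ROM 10°–160°, `k_l = 4 N·m`, `c_l = 30 /rad`. The passive constants were
chosen jointly so that three properties hold simultaneously at the fixed
1/150 s step: (1) sustained maximal excitation overshoots θ_max by < 5°
(measured: ≈1.1°); (2) the wall stiffness at realistic penetration depths
stays inside the explicit integrator's stability region; (3) the ligament's
mid-range exponential tail at the target angle induces a drift slower than
the task's velocity criterion (with `c_l = 25` the residual tail at 135°
drives a ≈5·10⁻³ °/s creep, which silently defeats the 10⁻³ °/s success
threshold; `c_l = 30` puts the creep at ≈6·10⁻⁴ °/s).

## Actuators

All three modes share the straight-line geometry: each actuator runs from an
origin a distance `d_o` up the fixed upper arm to an insertion `d_i` from the
hinge along the forearm axis. The flexor spans the anterior side; its length
follows the law of cosines, `l_mt = √(d_o² + d_i² + 2 d_o d_i cos θ)`, and
shortens with flexion. The extensor inserts on the posterior extension of
the forearm (olecranon-like), mirroring the triangle (−2 d_o d_i cos θ), and
lengthens with flexion. A naive posterior line through the hinge would give
zero or negative moment arms; the mirrored-triangle realization is this
package's choice. Moment arms follow tendon excursion,
`r(θ) = d_o d_i sin θ / l_mt = |∂l_mt/∂θ|`, identical in form for both sides
and vanishing at the singular poses θ ∈ {0, π}, which the ligament keeps the
simulation away from.

Defaults: flexor `d_o = 0.28 m`, `d_i = 0.030 m`; extensor `d_o = 0.28 m`,
`d_i = 0.025 m` (origins near the proximal end of a 0.30 m upper arm;
moment arms ≈ 2.5–3 cm).

* **Torque mode**: `T = (u_f − u_e) t_max`, `t_max = 15 N·m`.
* **Force mode**: `T = u_f F_max r_f(θ) − u_e F_max r_e(θ)`, `F_max = 1000 N`.
* **Muscle mode**: Hill-type two-element models (below); the transmitted
  (tendon) forces are multiplied by the same moment arms.

## Hill-type two-element muscle

Each muscle is a contractile element (CE) in series with an elastic element
(SEE); there is deliberately no parallel elastic element (the model family is
two-element). The forms are the canonical closed-form-invertible ones:

* activation: `ȧ = (u' − a)/τ`, `u' = max(u, a_min)`, τ = 15 ms rising,
  50 ms falling; activation floor `a_min`.
* force–length: Gaussian `fl = exp(−((l_ce/l_opt − 1)/w)²)`, width `w = 0.45`.
* force–velocity: Hill hyperbola `(1 − v/v_max)/(1 + v/(v_max a_f))` for
  shortening (`v_max = 10 l_opt/s`, `a_f = 0.25`), clamped to zero above
  `v_max`; a smooth eccentric branch `f_e − (f_e − 1)/(1 − g v)` with the
  same slope at v = 0 and asymptote `f_e = 1.5`.
* SEE: zero below the slack length, `F = f_max c1 (exp(c2 ε) − 1)` above it
  (strain ε), `c1 = 0.02`, `c2 = 30` — compliant at low force, stiff at
  high force.

Series equilibrium closes the loop: the SEE force divided by the CE's
current strength `f_max · a · fl` is the required force–velocity factor,
which is clamped into `[0, f_e − 0.1]` and inverted in closed form to give
the CE velocity. The clamp (plus an `fl` floor of 0.01 and the activation
floor) makes the solve total: an overloaded tendon lengthens the CE at a
bounded rate, a slack tendon shortens it at `v_max`.

`f_max` is 1000 N (flexor) / 800 N (extensor); `l_opt = 0.10 m`.

**Stiffness and the activation floor.** The CE-length state relaxes toward
its series-equilibrium value with a linearized rate proportional to
(SEE stiffness)/(CE strength). At low activation this is the stiffest mode
in the model — the reason the system is "mathematically stiff". With a
floor of 0.01 the passive rate is ≈2000 s⁻¹, far outside the classical RK4
stability region at the fixed 1/150 s step (λ·dt ≈ 13). The defaults
therefore use `a_min = 0.05` together with a long tendon (slack ≈ 0.17–0.20 m
against a 0.10 m CE), which keeps λ·dt below ≈1 at rest and within the
stability region during task-speed movements. The cost is a visible passive
muscle tone (5 % of maximal force), which the rest calibration below absorbs.

**Rest calibration.** Tendon slack lengths default to "auto": at the task's
start angle each muscle is placed in isometric equilibrium at `a = a_min`,
and the two slack lengths are solved so the passive joint torques cancel
exactly. The side that is passively stronger (`f_max · a_min · r`) — the
flexor, with these defaults — rests on the *ascending* force–length limb, so
flexing (shortening) weakens it: the start posture is statically stable, and
flexion torque self-limits toward end range, which is what keeps the
maximal-excitation overshoot small. Away from the start angle the passive
torques no longer cancel (a structural property of any two-element model
with an activation floor), so the arm slowly drifts back toward 90° when
released — see the task discussion below.

## Integration

Classical fixed-step RK4 at `dt = 1/150 s` over the full coupled state
(θ, ω, and in muscle mode each muscle's `a` and `l_ce`), with the control
sample held constant across the step (zero-order hold, matching a discrete
human-in-the-loop sampling at the solver rate). After each step activations
are clamped into `[a_min, 1]` and CE lengths floored at 0.1 mm. Measured
behavior: observed convergence order ≈ 4.0 on passive trajectories, and
≤ 2.3·10⁻⁹ relative error against the closed form of the linear damped arm
over 1 s (the linear benchmark uses `b/I = 8/3 s⁻¹`, where 150 steps of RK4
truncation accumulate to ≈2·10⁻⁹; at `b/I ≳ 4` the accumulated truncation
itself exceeds 10⁻⁸, so a stricter bound would measure the benchmark, not
the integrator).

## Control streams and the synthetic EMG chain

* **Bang-bang** (keyboard/mouse semantics): a fixed excitation level, on/off
  intervals per side, at most one side active per sample (later-starting
  interval wins ties). Default level 1.0, configurable.
* **Proportional** (EMG semantics): graded `u_f, u_e ∈ [0,1]` per step;
  co-activation is representable and preserved end to end.

The synthetic EMG chain emulates a consumer sensor pipeline: activation
amplitude-modulates zero-mean Gaussian noise (raw interference at 1 kHz);
full-wave rectification and a first-order low-pass at 2 Hz produce the
linear envelope; a 10-bit ADC (3.3 V full scale) digitizes it; rest/MVC
calibration normalizes each channel into [0,1], block-averaged down to the
150 Hz simulation rate. The amplifier gain (3.3 V per unit activation RMS)
puts the MVC envelope near 80 % of ADC full scale. The real sensor's RC
constants and gain are hardware properties not reproduced here; recovery
numbers (Pearson r ≈ 0.96–0.97 for sub-hertz activation signals) are
calibrated to this chain, not to any physical sensor. The chain does not
model electrode placement, cross-talk, motion artifact, or the
high-pass/notch stages of real front ends, so passing recovery tests say
nothing about those failure modes.

## Goal-directed task

From θ = 90°, reach a target 45° further into flexion; a trial succeeds at
the first post-step state within ±2° of the target with |ω| < 0.001°/s, and
times out at 5 s. Success is evaluated once per integration step (the
original interactive loop can only observe at the solver rate); a tie
between success and timeout at the same step resolves to success. After
either outcome the arm and both muscle states reset to a fresh start
equilibrium; activation states do not persist across trials. All state
variables (excitations, activations, CE/SEE lengths, forces, moment arms,
passive torques) are logged every step.

The 0.001°/s velocity criterion is extremely strict and shapes the demo
controllers:

* **Proportional demo** (muscle mode): a PID-style excitation law with a
  co-activation bias near the target. Co-activation raises joint stiffness
  and intrinsic (lag-free) muscle damping; the slow integral term trims the
  steady bias left by the flexor/extensor strength asymmetry. Pure PD
  variants either limit-cycle through the 50 ms deactivation lag (high
  gains) or park 3–5° short (low gains). Defaults kp = 1.2 /rad,
  kd = 0.35 s/rad, ki = 1.2 /(rad·s), co-activation 0.5 within ≈12° of the
  target; completes the task in ≈1.3 s.
* **Bang-bang demo** (torque mode): a flexion pulse then a braking extension
  pulse. Pulse edges snap to the 1/150 s grid, so the settled angle moves in
  coarse quanta (~7° at full level) as an edge moves by one sample; the
  tuner therefore fixes the pulse times from a full-level rollout and trims
  the *level* — the one continuous bang-bang knob — using the exact
  proportionality of settled displacement to level in generator modes.
  In generator modes residual torque is identically zero after the pulses,
  so ω decays exponentially through the success threshold (≈1.2 s total).
  In muscle mode a bang-bang-only strategy cannot satisfy the velocity
  criterion with these defaults: the activation floor leaves a
  ~0.1–0.4 rad/s passive drift everywhere except the start angle, and
  without a continuous knob the sampled velocity cannot be landed inside a
  ~10⁻⁵ rad/s window. This is a structural consequence of a two-element
  muscle with an activation floor, and it mirrors the qualitative
  observation that fixed-level keyboard control is the crude mode while
  graded co-activation is what stabilizes the arm near the target.

## Fixtures and what they show

`myoarm make-fixtures` emits a demo TOML config, the tuned bang-bang
schedule (plus its level), a recorded proportional schedule (the
co-activation controller's closed-loop output, which replays open-loop to
the identical trajectory because the dynamics are deterministic), synthetic
EMG envelope traces, and a rest/MVC calibration. Everything is generated
programmatically; there are no measured data in the package. Passing tests
therefore demonstrate internal consistency and the documented emergent
behaviors of *this* model family at *these* scales — not fidelity to any
particular human arm, whose muscle parameters, ROM limits, damping and
inertia are not printed in the source material and are plausible stand-ins
here.

## Known limitations

* No gravity torque (horizontal plane); no parallel elastic element,
  pennation, history dependence, or calcium kinetics.
* Straight-line geometry only; no via-points or wrapping.
* The explicit fixed-step solver constrains the reachable parameter space:
  very low activation floors, stiff short tendons, or much stiffer ligament
  walls require a smaller step than 1/150 s.
* The trial engine is single-joint and single-target; no adaptive schedules
  or feedback displays.
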