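# myoarm

A scriptable, headless simulator of an interactive planar elbow — the kind
of "virtual arm" used in motor-control research, myoelectric-control
training, and neuromechanics teaching. A fixed upper arm and a mobile
forearm are connected by a hinge; lumped flexor and extensor actuators pull
on it through straight-line geometry; the user (here: a schedule file or a
programmatic controller, standing in for keyboard, mouse, or surface-EMG
input) drives it in closed loop through a goal-directed flexion task.

## The model in brief

Newton–Euler on one hinge,

```
I θ̈ = T_active(u, θ, state) + T_lig(θ) − b θ̇
```

with a double-sided exponential ligament torque bounding the range of motion
and viscous damping that makes stopping on a target feasible. Three
actuation modes map the two control signals `u_f, u_e ∈ [0, 1]` to
`T_active`:

* **torque generators**: `T = (u_f − u_e) t_max`;
* **force generators**: forces `u F_max` times the moment arms
  `r(θ) = d_o d_i sin θ / l_mt(θ)` of the straight-line paths (tendon
  excursion: `r = |∂l_mt/∂θ|`);
* **Hill-type two-element muscles**: a contractile element (CE) with
  first-order activation dynamics, Gaussian force–length and Hill
  force–velocity curves, in series with an exponential tendon (SEE).
  The transmitted force is the SEE force; the CE velocity comes from
  inverting the force–velocity curve at the force the tendon demands.

Everything integrates with classical fixed-step RK4 at 1/150 s, controls
zero-order-held per step. The task: move from 90° to a target 45° further
into flexion within 5 s; success requires |θ − target| ≤ 2° **and**
|θ̇| < 0.001°/s at a sampled step. Trials auto-reset, sessions log every
state variable every step. Control can be **bang-bang** (fixed level, only
timing/duration free — keyboard semantics) or **proportional** (graded,
co-activation allowed — EMG semantics), and a synthetic surface-EMG chain
(activation-modulated noise → rectification → 2 Hz linear envelope → 10-bit
ADC → rest/MVC normalization) turns activation traces into proportional
control streams.

See `docs/methods.md` for the full model description, parameter rationale,
and limitations.

## Worked example

```
$ myoarm make-fixtures --out demo --seed 0
fixtures written to demo (bang-bang level 0.7865)

$ myoarm simulate --config demo/demo_config.toml \
    --control demo/proportional_schedule.csv --kind proportional \
    --mode muscle --trials 4 --out demo/session
4 trials -> 4 successes; records in demo/session

$ myoarm summarize --session demo/session
 trial outcome  movement_time  peak_velocity  terminal_error
     1 success       1.266667     187.671287        0.352225
     2 success       1.266667     187.671287        0.352225
     3 success       1.266667     187.671287        0.352225
     4 success       1.266667     187.671287        0.352225
```

`make-fixtures` writes a demo configuration, a tuned keyboard-style
bang-bang schedule (flexion pulse then braking extension pulse, with the
fixed level that lands the arm on the target), a recorded proportional
schedule from a co-activating feedback controller, and synthetic EMG
envelope traces with their calibration. The session above replays the
proportional schedule against the Hill-muscle arm: each trial reaches the
135° target in 1.27 s, stopping within 0.35° of it (the `movement_time`
column is seconds; `peak_velocity` is deg/s; `terminal_error` deg). The
four trials are identical because the dynamics and the schedule are
deterministic — the trial engine resets the full state between trials.

Trial CSVs (`trial_1.csv`, …) contain per-step time, angle, velocity,
excitations, activations, CE/SEE lengths, muscle forces, moment arms and
passive torques; `config_resolved.toml` echoes the fully resolved
configuration, angles in degrees.

The same task under keyboard semantics:

```
$ myoarm simulate --config demo/demo_config.toml \
    --control demo/bang_bang_schedule.csv --kind bang_bang \
    --mode torque --level 0.7865 --trials 4 --out demo/kb_session
4 trials -> 4 successes; records in demo/kb_session
```

Library use mirrors the CLI: `myoarm.default_config()` /
`myoarm.load_config()` build a validated `RunConfig`;
`myoarm.run_trial(controller, cfg)` and `myoarm.run_session(...)` run
trials with any `(state, t) -> ControlSample` callable; the modules
`myoarm.muscle`, `myoarm.geometry`, `myoarm.dynamics`, `myoarm.control`
expose the primitives (force curves, moment arms, RK4 stepping, EMG chain).

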