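"""Reference controllers and schedule tuning for the goal-directed task.

Three ways of driving the arm are provided:

* :func:`schedule_controller` replays a pre-computed excitation stream
  open-loop (this is how keyboard/EMG recordings are simulated headlessly);
* :func:`coactivation_controller` is a graded state-feedback law with a
  co-activation bias near the target — the myoelectric-style strategy:
  simultaneous flexor/extensor excitation stiffens the joint so the arm can
  be stopped and held on the target;
* :func:`tune_bang_bang_schedule` constructs a fixed-level flex-then-brake
  pulse pair that completes the task in torque (or force) generator mode —
  the keyboard-style strategy, where only timing and duration are
  user-controllable.

Because control samples are zero-order held on the solver grid, pulse edges
snap to multiples of dt and the settled angle moves in coarse quanta as a
pulse grows by one sample.  The tuner therefore fixes the pulse *times* from
a full-level rollout and trims the fixed excitation *level* — a continuous,
legitimate bang-bang knob — using the fact that in generator modes the
settled displacement is, away from the ligament region, exactly
proportional to the level.
"""

from __future__ import annotations

import math
from typing import Sequence

from .control import ControlSample, bang_bang_stream
from .dynamics import ArmState, rk4_step
from .errors import ConfigurationError
from .task import Controller, initial_state

__all__ = [
    "schedule_controller",
    "coactivation_controller",
    "tune_bang_bang_schedule",
]

DEG = math.pi / 180.0


def schedule_controller(samples: Sequence[ControlSample], dt: float) -> Controller:
    """Controller replaying a per-step stream; holds the last sample after the end."""
    samples = list(samples)

    def controller(state: ArmState, t: float) -> ControlSample:
        if not samples:
            return ControlSample()
        k = min(round(t / dt), len(samples) - 1)
        return samples[k]

    return controller


def coactivation_controller(
    cfg,
    kp: float = 1.2,
    kd: float = 0.35,
    ki: float = 1.2,
    co_level: float = 0.50,
    co_width_deg: float = 12.0,
    i_max: float = 0.6,
) -> Controller:
    """Graded feedback excitation with near-target co-activation.

    The position error drives the agonist, the velocity term brakes, and a
    slow integral term trims the steady bias left by the flexor/extensor
    strength asymmetry (the activation floor's passive torques do not cancel
    away from the start posture).  Within ``co_width_deg`` of the target both
    muscles receive a common bias ``co_level``, so they co-contract and the
    joint stiffens — the strategy myoelectric users adopt to stabilize the
    arm on the target.  Gains are in units of excitation per rad, per rad/s
    and per rad*s; the integral term is clamped to ``i_max`` (anti-windup).

    The controller is stateful (integral memory); build a fresh one per
    trial.
    """
    target = cfg.task.theta_target * DEG
    mem = {"i": 0.0, "t": 0.0}

    def controller(state: ArmState, t: float) -> ControlSample:
        e = target - state.theta
        dt = t - mem["t"]
        mem["t"] = t
        mem["i"] = min(max(mem["i"] + ki * e * dt, -i_max), i_max)
        co = co_level * math.exp(-((e / (co_width_deg * DEG)) ** 2))
        drive = kp * e - kd * state.omega + mem["i"]
        u_f = min(max(co + drive, 0.0), 1.0)
        u_e = min(max(co - drive, 0.0), 1.0)
        return ControlSample(u_f=u_f, u_e=u_e)

    return controller


def _rollout_schedule(cfg, schedule, level: float) -> float:
    """Settled angle (rad) after following a bang-bang schedule to t_limit."""
    dt = cfg.sim.dt
    samples = bang_bang_stream(schedule, level, dt, cfg.task.t_limit)
    geoms = (cfg.flexor_path, cfg.extensor_path)
    muscles = (cfg.flexor, cfg.extensor)
    s = initial_state(cfg)
    for k in range(len(samples) - 1):
        s = rk4_step(s, samples[k], dt, cfg.actuation, geoms, muscles, cfg.arm)
    return s.theta


def _build_pulses(cfg, level: float, theta_switch: float, omega_stop: float):
    """Flexor-on until ``theta_switch``, extensor-on until nearly stopped."""
    dt = cfg.sim.dt
    n_steps = round(cfg.task.t_limit / dt)
    geoms = (cfg.flexor_path, cfg.extensor_path)
    muscles = (cfg.flexor, cfg.extensor)
    s = initial_state(cfg)
    phase = "flex"
    t_brake_on = t_brake_off = None
    for k in range(n_steps):
        if phase == "flex" and s.theta >= theta_switch:
            phase, t_brake_on = "brake", k * dt
        elif phase == "brake" and s.omega <= omega_stop:
            phase, t_brake_off = "coast", k * dt
        if phase == "flex":
            u = ControlSample(u_f=level)
        elif phase == "brake":
            u = ControlSample(u_e=level)
        else:
            u = ControlSample()
        s = rk4_step(s, u, dt, cfg.actuation, geoms, muscles, cfg.arm)
    if t_brake_on is None or t_brake_on == 0.0:
        return None
    if t_brake_off is None:
        t_brake_off = n_steps * dt
    schedule = [(0.0, t_brake_on, "flexor")]
    if t_brake_off > t_brake_on:
        schedule.append((t_brake_on, t_brake_off, "extensor"))
    return schedule


def tune_bang_bang_schedule(
    cfg,
    level_max: float = 1.0,
    omega_stop: float = 0.05,
    tol_deg: float = 0.1,
    max_iter: int = 60,
):
    """Tune a flex-then-brake bang-bang trial that lands on the target.

    Returns ``(schedule, level)``: pulse intervals ``[(t_on, t_off, side)]``
    and the fixed excitation level at which replaying them settles the arm
    within ``tol_deg`` of the target.  Intended for torque/force generator
    modes, where the arm is at rest wherever the pulses leave it and joint
    damping then drives the velocity below the success threshold.
    """
    target = cfg.task.theta_target * DEG
    start = cfg.task.theta_start * DEG
    schedule = _build_pulses(cfg, level_max, target, omega_stop)
    if schedule is None:
        raise ConfigurationError("bang-bang tuning failed: arm never reached the switch angle")
    th_full = _rollout_schedule(cfg, schedule, level_max)
    if th_full - start < (target - start) * (1 - 1e-9):
        raise ConfigurationError("bang-bang tuning failed: full-level rollout falls short")
    # settled displacement is ~proportional to level; polish by bisection
    lo, hi = 0.0, level_max
    level = level_max * (target - start) / (th_full - start)
    for _ in range(max_iter):
        th = _rollout_schedule(cfg, schedule, level)
        if abs(th - target) < tol_deg * DEG:
            return schedule, level
        if th > target:
            hi = level
        else:
            lo = level
        level = 0.5 * (lo + hi)
    raise ConfigurationError("bang-bang tuning did not converge to the target window")
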