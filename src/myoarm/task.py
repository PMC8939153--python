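"""Goal-directed trial engine: success predicate, timeout, reset, logging.

The task mirrors a fast goal-directed elbow flexion: from a 90° start the
arm must reach a target 45° further into flexion and *stop* there — a trial
succeeds at the first integration step whose post-step state is within ±2°
of the target with |angular velocity| below 0.001°/s, and times out at 5 s.
After either outcome the arm (and, in muscle mode, both muscle states) is
reset to a fresh start equilibrium, so multiple-trial sessions are
independent and deterministic controllers reproduce identical records.

The velocity criterion is strict; it is attainable because joint damping
drives the velocity toward zero exponentially once the controller stops
driving the arm (expect long settle tails relative to the transport phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .control import ControlSample
from .dynamics import ArmState, damping_torque, ligament_torque, rk4_step
from .errors import InputValidationError
from .geometry import moment_arm, muscle_tendon_length
from .muscle import init_muscle_state, muscle_force

__all__ = [
    "TaskParams",
    "TrialRecord",
    "success_check",
    "initial_state",
    "run_trial",
    "run_session",
    "summarize_session",
]

DEG = np.pi / 180.0

Controller = Callable[[ArmState, float], ControlSample]


@dataclass(frozen=True)
class TaskParams:
    """Task constants. Angles in degrees, matching the user-facing surface."""

    theta_start: float = 90.0     # start angle (deg)
    delta_target: float = 45.0    # target offset (deg, + = flexion)
    tol_theta: float = 2.0        # success half-width (deg)
    tol_omega: float = 0.001      # success velocity threshold (deg/s)
    t_limit: float = 5.0          # movement time limit (s)

    def __post_init__(self) -> None:
        if not (self.tol_theta > 0 and self.tol_omega > 0 and self.t_limit > 0):
            raise InputValidationError("tol_theta, tol_omega and t_limit must be positive")

    @property
    def theta_target(self) -> float:
        return self.theta_start + self.delta_target


_SERIES = (
    "time", "theta", "omega", "u_f", "u_e", "a_f", "a_e", "force_f", "force_e",
    "l_ce_f", "l_ce_e", "l_se_f", "l_se_e", "r_f", "r_e", "t_lig", "t_damp",
)


@dataclass
class TrialRecord:
    """Per-step time series of one trial plus its outcome.

    Angles are stored in radians (SI, like every other series); the CSV
    writer converts to degrees.  ``movement_time`` is present iff the trial
    succeeded.
    """

    series: dict = field(default_factory=dict)
    outcome: str = "timeout"                 # 'success' | 'timeout'
    movement_time: Optional[float] = None

    def __len__(self) -> int:
        return len(self.series["time"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: np.asarray(v) for k, v in self.series.items()})


def success_check(theta: float, omega: float, tp: TaskParams) -> bool:
    """Success predicate on one sample; ``theta`` in deg, ``omega`` in deg/s."""
    return (
        abs(theta - tp.theta_target) <= tp.tol_theta and abs(omega) < tp.tol_omega
    )


def initial_state(cfg) -> ArmState:
    """Fresh start-of-trial state at the task's start angle.

    In muscle mode both muscles are placed at their isometric equilibrium
    with activation at the floor, so a passive arm holds still at the start.
    """
    theta0 = cfg.task.theta_start * DEG
    if cfg.actuation.mode != "muscle":
        return ArmState(theta=theta0, omega=0.0)
    fx = init_muscle_state(theta0, cfg.flexor.a_min, cfg.flexor_path, cfg.flexor)
    ex = init_muscle_state(theta0, cfg.extensor.a_min, cfg.extensor_path, cfg.extensor)
    return ArmState(theta=theta0, omega=0.0, flexor=fx, extensor=ex)


def _log_step(series: dict, t: float, s: ArmState, u: ControlSample, cfg) -> None:
    mode = cfg.actuation.mode
    series["time"].append(t)
    series["theta"].append(s.theta)
    series["omega"].append(s.omega)
    series["u_f"].append(u.u_f)
    series["u_e"].append(u.u_e)
    series["t_lig"].append(ligament_torque(s.theta, cfg.arm))
    series["t_damp"].append(damping_torque(s.omega, cfg.arm))
    if mode == "torque":
        r_f = r_e = np.nan
    else:
        r_f = moment_arm(s.theta, cfg.flexor_path)
        r_e = moment_arm(s.theta, cfg.extensor_path)
    series["r_f"].append(r_f)
    series["r_e"].append(r_e)
    if mode == "muscle":
        l_mt_f = muscle_tendon_length(s.theta, cfg.flexor_path)
        l_mt_e = muscle_tendon_length(s.theta, cfg.extensor_path)
        series["a_f"].append(s.flexor.a)
        series["a_e"].append(s.extensor.a)
        series["l_ce_f"].append(s.flexor.l_ce)
        series["l_ce_e"].append(s.extensor.l_ce)
        series["l_se_f"].append(l_mt_f - s.flexor.l_ce)
        series["l_se_e"].append(l_mt_e - s.extensor.l_ce)
        series["force_f"].append(muscle_force(s.flexor, l_mt_f, cfg.flexor))
        series["force_e"].append(muscle_force(s.extensor, l_mt_e, cfg.extensor))
    else:
        for k in ("a_f", "a_e", "l_ce_f", "l_ce_e", "l_se_f", "l_se_e"):
            series[k].append(np.nan)
        if mode == "force":
            series["force_f"].append(u.u_f * cfg.actuation.f_gen_max)
            series["force_e"].append(u.u_e * cfg.actuation.f_gen_max)
        else:
            series["force_f"].append(np.nan)
            series["force_e"].append(np.nan)


def run_trial(controller: Controller, cfg) -> TrialRecord:
    """Run one goal-directed trial under ``controller`` and log every step.

    The controller maps (state, time) to a :class:`ControlSample`; its output
    is zero-order held over each RK4 step.  Success is evaluated once per
    step on the post-step state; ties between success and timeout at the
    same step resolve to success.
    """
    dt = cfg.sim.dt
    tp = cfg.task
    n_steps = round(tp.t_limit / dt)
    series: dict = {k: [] for k in _SERIES}
    s = initial_state(cfg)
    geoms = (cfg.flexor_path, cfg.extensor_path)
    muscles = (cfg.flexor, cfg.extensor)

    record = TrialRecord(series=series)
    t = 0.0
    u = _checked_control(controller, s, t, 0)
    _log_step(series, t, s, u, cfg)
    for k in range(1, n_steps + 1):
        s = rk4_step(s, u, dt, cfg.actuation, geoms, muscles, cfg.arm)
        t = k * dt
        u_next = _checked_control(controller, s, t, k)
        _log_step(series, t, s, u_next, cfg)
        if success_check(s.theta / DEG, s.omega / DEG, tp):
            record.outcome = "success"
            record.movement_time = t
            return record
        u = u_next
    record.outcome = "timeout"
    return record


def _checked_control(controller: Controller, s: ArmState, t: float, step: int) -> ControlSample:
    try:
        return controller(s, t)
    except InputValidationError as exc:
        raise InputValidationError(f"controller output invalid at step {step}: {exc}") from exc


def run_session(
    n_trials: int,
    controller_factory: Callable[[int, int], Controller],
    cfg,
    seed: int = 0,
) -> list[TrialRecord]:
    """Run ``n_trials`` sequential trials with a full reset in between.

    ``controller_factory(trial_index, trial_seed)`` builds each trial's
    controller; per-trial seeds are derived deterministically from ``seed``.
    """
    if n_trials < 1:
        raise InputValidationError("n_trials must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_trials)
    records = []
    for k in range(n_trials):
        controller = controller_factory(k, int(child_seeds[k] % (2**31)))
        records.append(run_trial(controller, cfg))
    return records


def summarize_session(
    records: Sequence[TrialRecord], tp: Optional[TaskParams] = None
) -> pd.DataFrame:
    """Per-trial summary: outcome, movement time, peak speed, terminal error.

    Peak velocity (deg/s) is max |omega| over the trial; terminal error (deg)
    is the final sample's distance from the target of ``tp`` (defaults to the
    standard task constants).
    """
    if not records:
        raise InputValidationError("cannot summarize an empty session")
    tp = tp or TaskParams()
    rows = []
    for i, rec in enumerate(records):
        theta = np.asarray(rec.series["theta"]) / DEG
        omega = np.asarray(rec.series["omega"]) / DEG
        rows.append(
            {
                "trial": i + 1,
                "outcome": rec.outcome,
                "movement_time": rec.movement_time if rec.outcome == "success" else np.nan,
                "peak_velocity": float(np.max(np.abs(omega))),
                "terminal_error": float(abs(theta[-1] - tp.theta_target)),
            }
        )
    return pd.DataFrame(rows)
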