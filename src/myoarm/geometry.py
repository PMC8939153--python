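"""Straight-line actuator geometry and the three actuation modes.

Both actuators run in a straight line from an origin on the upper arm to an
insertion on the forearm.  The joint angle ``theta`` is the flexion angle:
0 = full extension, counterclockwise (flexion) positive, so the task's 90°
start and +45° flexion target are theta = 90° -> 135°.

The flexor spans the anterior side of the hinge; its muscle--tendon length
follows the law of cosines on the triangle (origin, elbow, insertion) and
shortens with flexion.  The extensor inserts on the posterior extension of
the forearm (olecranon-like), which mirrors the triangle: its length grows
with flexion.  Moment arms follow the tendon-excursion principle: the moment
arm equals the magnitude of d(l_mt)/d(theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputValidationError
from .muscle import muscle_force

__all__ = [
    "PathGeometry",
    "ActuationConfig",
    "muscle_tendon_length",
    "moment_arm",
    "control_to_joint_torque",
]

MODES = ("torque", "force", "muscle")


@dataclass(frozen=True)
class PathGeometry:
    """Straight-line path of one actuator about the elbow hinge."""

    d_origin: float   # elbow-to-origin distance along the upper arm (m)
    d_insert: float   # elbow-to-insertion distance along the forearm axis (m)
    side: str = "flexor"  # 'flexor' | 'extensor'

    def __post_init__(self) -> None:
        if self.side not in ("flexor", "extensor"):
            raise InputValidationError(f"side must be flexor|extensor, got {self.side!r}")
        if not (self.d_origin > 0 and self.d_insert > 0):
            raise InputValidationError("d_origin and d_insert must be positive")
        if not self.d_origin > self.d_insert:
            raise InputValidationError(
                "d_origin must exceed d_insert (origins proximal on the upper arm, "
                "insertions near the elbow)"
            )


@dataclass(frozen=True)
class ActuationConfig:
    """Actuation mode and generator scales."""

    mode: str = "muscle"      # 'torque' | 'force' | 'muscle'
    t_max: float = 15.0       # max generator torque per side (N*m, torque mode)
    f_gen_max: float = 1000.0  # max generator force per actuator (N, force mode)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InputValidationError(f"actuation mode must be one of {MODES}, got {self.mode!r}")
        if not self.t_max > 0:
            raise InputValidationError("t_max must be positive")
        if not self.f_gen_max > 0:
            raise InputValidationError("f_gen_max must be positive")


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= math.pi):
        raise InputValidationError("theta must lie strictly inside (0, pi) radians")
    return theta


def muscle_tendon_length(theta, g: PathGeometry):
    """Origin-to-insertion distance (m) at flexion angle ``theta`` (rad).

    Law of cosines on the elbow triangle; the flexor shortens and the
    extensor lengthens as flexion increases.
    """
    theta = _check_theta(theta)
    sign = 1.0 if g.side == "flexor" else -1.0
    out = np.sqrt(
        g.d_origin**2 + g.d_insert**2 + 2.0 * sign * g.d_origin * g.d_insert * np.cos(theta)
    )
    return float(out) if out.ndim == 0 else out


def moment_arm(theta, g: PathGeometry):
    """Moment arm (m, >= 0) about the hinge at flexion angle ``theta`` (rad).

    Equal on both sides to ``d_o * d_i * sin(theta) / l_mt``, which is exactly
    |d(l_mt)/d(theta)| (tendon excursion).
    """
    theta = _check_theta(theta)
    out = g.d_origin * g.d_insert * np.sin(theta) / muscle_tendon_length(theta, g)
    return float(out) if out.ndim == 0 else out


def control_to_joint_torque(
    u,
    theta: float,
    states,
    cfg: ActuationConfig,
    geoms,
    params,
) -> float:
    """Net active joint torque (N*m, flexion positive) from a control sample.

    ``u`` has fields ``u_f``/``u_e``; ``states``, ``geoms`` and ``params`` are
    (flexor, extensor) pairs.  In torque mode controls map directly to
    torques; in force mode to actuator forces times moment arms; in muscle
    mode the transmitted (tendon) forces are multiplied by the moment arms.
    ``states`` may be None except in muscle mode.
    """
    if cfg.mode == "torque":
        return (u.u_f - u.u_e) * cfg.t_max
    geom_f, geom_e = geoms
    r_f = moment_arm(theta, geom_f)
    r_e = moment_arm(theta, geom_e)
    if cfg.mode == "force":
        return u.u_f * cfg.f_gen_max * r_f - u.u_e * cfg.f_gen_max * r_e
    if states is None or states[0] is None or states[1] is None:
        raise ConfigurationError("muscle mode requires flexor and extensor muscle states")
    s_f, s_e = states
    p_f, p_e = params
    f_f = muscle_force(s_f, muscle_tendon_length(theta, geom_f), p_f)
    f_e = muscle_force(s_e, muscle_tendon_length(theta, geom_e), p_e)
    return f_f * r_f - f_e * r_e
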