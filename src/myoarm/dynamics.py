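"""Planar rigid-body elbow dynamics and the fixed-step RK4 integrator.

The upper arm is fixed; the forearm (plus hand) is one rigid link rotating
about a frictionless hinge.  The plane is treated as horizontal, so no
gravity torque appears; the only passive torques are a double-sided
exponential ligament that keeps the joint inside its physiological range of
motion, and linear viscous damping (present in the modeled system expressly
to make stopping on a target feasible).

The full dynamic state couples the rigid-body pair (theta, omega) with each
muscle's (activation, CE length) in muscle mode.  The classical fourth-order
Runge-Kutta scheme advances the whole coupled state with the control sample
held constant across the step (zero-order hold, matching a discrete
interaction loop sampled at the solver rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .control import ControlSample
from .errors import InputValidationError, NumericalError
from .geometry import ActuationConfig, PathGeometry, control_to_joint_torque, muscle_tendon_length
from .muscle import MuscleParams, MuscleState, activation_derivative, ce_velocity_from_equilibrium

__all__ = [
    "ArmParams",
    "ArmState",
    "SimConfig",
    "ligament_torque",
    "damping_torque",
    "state_derivative",
    "rk4_step",
]

DEG = np.pi / 180.0


@dataclass(frozen=True)
class ArmParams:
    """Rigid-body and passive-torque constants of the forearm link."""

    inertia: float = 0.075       # forearm+hand moment of inertia about the elbow (kg*m^2)
    damping_b: float = 0.8       # viscous damping coefficient (N*m*s/rad)
    rom_min: float = 10.0 * DEG  # range-of-motion lower limit (rad)
    rom_max: float = 160.0 * DEG  # range-of-motion upper limit (rad)
    lig_k: float = 4.0           # ligament torque scale (N*m)
    lig_c: float = 30.0          # ligament exponential rate (1/rad)
    upper_len: float = 0.30      # upper-arm segment length (m, bookkeeping)
    fore_len: float = 0.30       # forearm segment length (m, bookkeeping)

    def __post_init__(self) -> None:
        checks = [
            ("inertia", self.inertia > 0),
            ("damping_b", self.damping_b >= 0),
            ("rom_min", 0 < self.rom_min < np.pi),
            ("rom_max", self.rom_min < self.rom_max < np.pi),
            ("lig_k", self.lig_k > 0),
            ("lig_c", self.lig_c > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise InputValidationError(
                    f"ArmParams.{name} = {getattr(self, name)!r} violates its invariant"
                )


@dataclass
class ArmState:
    """Joint state plus per-muscle internal states (None outside muscle mode)."""

    theta: float                      # flexion angle (rad)
    omega: float                      # angular velocity (rad/s)
    flexor: Optional[MuscleState] = None
    extensor: Optional[MuscleState] = None


@dataclass(frozen=True)
class SimConfig:
    """Integration step and time cap for free (non-task) simulations."""

    dt: float = 1.0 / 150.0
    t_limit: float = 5.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InputValidationError("sim.dt must be positive")
        if not self.t_limit > 0:
            raise InputValidationError("sim.t_limit must be positive")


def ligament_torque(theta, p: ArmParams):
    """Double-sided exponential restoring torque near the ROM limits (N*m).

    Positive (flexing) below rom_min, negative above rom_max, negligible
    (<1% of lig_k with defaults) in mid-range.
    """
    theta = np.asarray(theta, dtype=float)
    out = p.lig_k * (
        np.exp(p.lig_c * (p.rom_min - theta)) - np.exp(p.lig_c * (theta - p.rom_max))
    )
    return float(out) if out.ndim == 0 else out


def damping_torque(omega, p: ArmParams):
    """Linear viscous torque -b*omega (N*m)."""
    out = -p.damping_b * np.asarray(omega, dtype=float)
    return float(out) if out.ndim == 0 else out


# --- state vector packing -------------------------------------------------
# torque/force modes: y = [theta, omega]
# muscle mode:        y = [theta, omega, a_f, l_ce_f, a_e, l_ce_e]

_COMPONENT_NAMES = ("theta", "omega", "flexor.a", "flexor.l_ce", "extensor.a", "extensor.l_ce")


def pack_state(s: ArmState) -> np.ndarray:
    if s.flexor is None:
        return np.array([s.theta, s.omega], dtype=float)
    return np.array(
        [s.theta, s.omega, s.flexor.a, s.flexor.l_ce, s.extensor.a, s.extensor.l_ce],
        dtype=float,
    )


def unpack_state(y: np.ndarray) -> ArmState:
    if y.size == 2:
        return ArmState(theta=float(y[0]), omega=float(y[1]))
    return ArmState(
        theta=float(y[0]),
        omega=float(y[1]),
        flexor=MuscleState(a=float(y[2]), l_ce=float(y[3])),
        extensor=MuscleState(a=float(y[4]), l_ce=float(y[5])),
    )


def state_derivative(
    s: ArmState,
    u: ControlSample,
    actuation: ActuationConfig,
    geoms: tuple[PathGeometry, PathGeometry],
    muscles: tuple[MuscleParams, MuscleParams],
    arm: ArmParams,
) -> np.ndarray:
    """Time derivative of the packed state vector.

    Newton-Euler on the hinge: ``I * domega = T_active + T_lig + T_damp``
    with the active torque from the current actuation mode; in muscle mode
    activation follows its first-order dynamics and the CE length rate comes
    from the series-equilibrium velocity solve.
    """
    states = (s.flexor, s.extensor) if actuation.mode == "muscle" else None
    t_active = control_to_joint_torque(u, s.theta, states, actuation, geoms, muscles)
    t_total = t_active + ligament_torque(s.theta, arm) + damping_torque(s.omega, arm)
    d_theta = s.omega
    d_omega = t_total / arm.inertia
    if actuation.mode != "muscle":
        return np.array([d_theta, d_omega])
    out = np.empty(6)
    out[0], out[1] = d_theta, d_omega
    for i, (ms, geom, p, u_side) in enumerate(
        ((s.flexor, geoms[0], muscles[0], u.u_f), (s.extensor, geoms[1], muscles[1], u.u_e))
    ):
        da = activation_derivative(u_side, min(max(ms.a, p.a_min), 1.0), p)
        l_mt = muscle_tendon_length(s.theta, geom)
        v_ce = ce_velocity_from_equilibrium(ms, l_mt, p)  # l_ce_opt/s, shortening +
        out[2 + 2 * i] = da
        out[3 + 2 * i] = -v_ce * p.l_ce_opt
    return out


def rk4_step(
    s: ArmState,
    u: ControlSample,
    dt: float,
    actuation: ActuationConfig,
    geoms: tuple[PathGeometry, PathGeometry],
    muscles: tuple[MuscleParams, MuscleParams],
    arm: ArmParams,
) -> ArmState:
    """One classical RK4 step of the coupled state, controls held constant.

    Activations are clamped into [a_min, 1] after the update.  A non-finite
    result raises :class:`NumericalError` naming the offending component.
    """
    if not dt > 0:
        raise InputValidationError("dt must be positive")

    def f(y: np.ndarray) -> np.ndarray:
        return state_derivative(unpack_state(y), u, actuation, geoms, muscles, arm)

    y0 = pack_state(s)
    k1 = f(y0)
    k2 = f(y0 + 0.5 * dt * k1)
    k3 = f(y0 + 0.5 * dt * k2)
    k4 = f(y0 + dt * k3)
    y1 = y0 + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if y1.size == 6:
        y1[2] = min(max(y1[2], muscles[0].a_min), 1.0)
        y1[4] = min(max(y1[4], muscles[1].a_min), 1.0)
        # CE lengths stay physical even through violent transients
        y1[3] = max(y1[3], 1e-4)
        y1[5] = max(y1[5], 1e-4)
    if not np.all(np.isfinite(y1)):
        bad = _COMPONENT_NAMES[int(np.flatnonzero(~np.isfinite(y1))[0])]
        raise NumericalError(f"non-finite state component {bad!r} after RK4 step")
    return unpack_state(y1)
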