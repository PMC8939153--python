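"""Hill-type two-element muscle model.

A muscle is a contractile element (CE) in series with an elastic element
(SEE, the tendon).  The CE produces force ``f_max * a * fl(l_ce) * fv(v_ce)``
where ``a`` is activation, ``fl`` a Gaussian force--length scaling and ``fv``
the Hill force--velocity scaling; the SEE is an exponential spring that is
compliant at low force and stiffens at higher force.  Because the two elements
are in series they carry the same force, which lets the CE velocity be
obtained in closed form by inverting ``fv`` at the force the tendon currently
demands.  The force transmitted to the skeleton is always the SEE force.

Excitation ``u`` (the neural / control input, in [0, 1]) drives activation
``a`` through first-order dynamics with separate rise and fall time
constants.  Activation never falls below the floor ``a_min``, which keeps the
CE-velocity solve non-singular.

Units: SI (N, m, s).  CE velocity is expressed in optimal CE lengths per
second, shortening positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, InputValidationError

__all__ = [
    "MuscleParams",
    "MuscleState",
    "activation_derivative",
    "force_length",
    "force_velocity",
    "force_velocity_inverse",
    "see_force",
    "ce_velocity_from_equilibrium",
    "muscle_force",
    "init_muscle_state",
]

#: Floor applied to the force--length factor inside the equilibrium solve so
#: the required fv never divides by ~0 at extreme CE lengths.
FL_FLOOR = 1e-2

#: Margin below fv_ecc_max when clamping the required force--velocity factor.
#: Bounds the maximum eccentric (lengthening) CE speed returned by the solve,
#: which bounds the per-step CE excursion of the explicit integrator.
FV_ECC_MARGIN = 0.1


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one Hill-type muscle--tendon actuator."""

    f_max: float = 1000.0       # maximum isometric force (N)
    l_ce_opt: float = 0.10      # optimal CE length (m)
    w: float = 0.45             # force-length width (dimensionless)
    v_max: float = 10.0         # max shortening velocity (l_ce_opt/s)
    a_f: float = 0.25           # force-velocity curvature
    fv_ecc_max: float = 1.5     # eccentric force ceiling (>1)
    l_slack: float = 0.20       # SEE slack length (m)
    c1: float = 0.02            # SEE shape: force scale fraction of f_max
    c2: float = 30.0            # SEE shape: exponential strain rate
    tau_act: float = 0.015      # activation time constant (s)
    tau_deact: float = 0.050    # deactivation time constant (s)
    a_min: float = 0.05         # activation floor

    def __post_init__(self) -> None:
        checks = [
            ("f_max", self.f_max > 0),
            ("l_ce_opt", self.l_ce_opt > 0),
            ("w", self.w > 0),
            ("v_max", self.v_max > 0),
            ("a_f", self.a_f > 0),
            ("fv_ecc_max", self.fv_ecc_max > 1),
            ("l_slack", self.l_slack > 0),
            ("c1", self.c1 > 0),
            ("c2", self.c2 > 0),
            ("tau_act", 0 < self.tau_act <= self.tau_deact),
            ("a_min", 0 < self.a_min < 0.1),
        ]
        for name, ok in checks:
            if not ok:
                raise InputValidationError(
                    f"MuscleParams.{name} = {getattr(self, name)!r} violates its invariant"
                )

    def with_slack(self, l_slack: float) -> "MuscleParams":
        return replace(self, l_slack=l_slack)


@dataclass
class MuscleState:
    """Dynamic state of one muscle: activation and CE length."""

    a: float      # activation in [a_min, 1]
    l_ce: float   # contractile-element length (m)

    def validate(self, p: MuscleParams) -> None:
        if not (p.a_min - 1e-12 <= self.a <= 1 + 1e-12):
            raise InputValidationError(f"activation {self.a} outside [{p.a_min}, 1]")
        if not self.l_ce > 0:
            raise InputValidationError(f"l_ce {self.l_ce} must be positive")


def activation_derivative(u: float, a: float, p: MuscleParams) -> float:
    """Rate of change of activation under excitation ``u``.

    First-order dynamics toward the effective excitation
    ``u' = max(u, a_min)``, with the faster time constant when activation is
    rising and the slower one when it is falling.
    """
    if not 0 <= u <= 1:
        raise InputValidationError(f"excitation u = {u} outside [0, 1]")
    if not (p.a_min - 1e-12 <= a <= 1 + 1e-12):
        raise InputValidationError(f"activation a = {a} outside [{p.a_min}, 1]")
    u_eff = max(u, p.a_min)
    tau = p.tau_act if u_eff > a else p.tau_deact
    return (u_eff - a) / tau


def force_length(l_ce, p: MuscleParams):
    """Gaussian active force--length scaling; 1 at the optimal CE length."""
    l_ce = np.asarray(l_ce, dtype=float)
    if np.any(l_ce <= 0):
        raise InputValidationError("l_ce must be positive")
    out = np.exp(-(((l_ce / p.l_ce_opt) - 1.0) / p.w) ** 2)
    return float(out) if out.ndim == 0 else out


def force_velocity(v_ce, p: MuscleParams):
    """Hill force--velocity scaling.

    ``v_ce`` is in optimal CE lengths per second, shortening positive.  The
    concentric branch is the Hill hyperbola, zero at ``v_max`` and beyond; the
    eccentric branch rises smoothly (continuous value and slope at zero
    velocity) toward the asymptote ``fv_ecc_max``.
    """
    v = np.asarray(v_ce, dtype=float)
    fe, af, vmax = p.fv_ecc_max, p.a_f, p.v_max
    # Eccentric slope matched to the concentric slope -(1+a_f)/(a_f*v_max).
    g = (1.0 + af) / (af * vmax * (fe - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (1.0 - v / vmax) / (1.0 + v / (vmax * af))
        ecc = fe - (fe - 1.0) / (1.0 - g * v)
    out = np.where(v >= 0, np.where(v >= vmax, 0.0, conc), ecc)
    return float(out) if out.ndim == 0 else out


def force_velocity_inverse(fv, p: MuscleParams):
    """Closed-form inverse of :func:`force_velocity` on [0, fv_ecc_max)."""
    fv = np.asarray(fv, dtype=float)
    if np.any(fv < 0) or np.any(fv >= p.fv_ecc_max):
        raise InputValidationError("fv must lie in [0, fv_ecc_max)")
    fe, af, vmax = p.fv_ecc_max, p.a_f, p.v_max
    g = (1.0 + af) / (af * vmax * (fe - 1.0))
    conc = vmax * af * (1.0 - fv) / (af + fv)
    with np.errstate(divide="ignore"):
        ecc = (1.0 - (fe - 1.0) / (fe - fv)) / g
    out = np.where(fv <= 1.0, conc, ecc)
    return float(out) if out.ndim == 0 else out


def see_force(l_se, p: MuscleParams):
    """Series-elastic (tendon) force at SEE length ``l_se``.

    Zero at or below the slack length; exponential in strain above it, so the
    tendon is compliant at low force and stiffens as force rises.
    """
    l_se = np.asarray(l_se, dtype=float)
    if np.any(l_se <= 0):
        raise InputValidationError("l_se must be positive")
    strain = (l_se - p.l_slack) / p.l_slack
    out = np.where(strain > 0, p.f_max * p.c1 * np.expm1(p.c2 * np.clip(strain, 0, None)), 0.0)
    return float(out) if out.ndim == 0 else out


def ce_velocity_from_equilibrium(s: MuscleState, l_mt: float, p: MuscleParams) -> float:
    """CE velocity (l_ce_opt/s, shortening positive) from series equilibrium.

    The SEE force is what the tendon demands at the current stretch; dividing
    by the CE's activation- and length-scaled strength gives the required
    force--velocity factor, which is clamped into the invertible range and
    inverted in closed form.  Clamping makes the operation total: an
    overloaded tendon yields fast (bounded) lengthening, a slack tendon yields
    shortening at ``v_max``.
    """
    if not l_mt > 0:
        raise InputValidationError("l_mt must be positive")
    f_se = see_force(l_mt - s.l_ce, p) if l_mt - s.l_ce > 0 else 0.0
    cap = p.f_max * max(s.a, p.a_min) * max(force_length(s.l_ce, p), FL_FLOOR)
    fv_req = f_se / cap
    fv_req = min(max(fv_req, 0.0), p.fv_ecc_max - FV_ECC_MARGIN)
    return force_velocity_inverse(fv_req, p)


def muscle_force(s: MuscleState, l_mt: float, p: MuscleParams) -> float:
    """Force transmitted to the skeleton (= SEE force) at MT length ``l_mt``."""
    l_se = l_mt - s.l_ce
    if l_se <= 0:
        return 0.0
    return see_force(l_se, p)


def init_muscle_state(theta: float, a0: float, geom, p: MuscleParams) -> MuscleState:
    """Muscle state in isometric equilibrium at joint angle ``theta`` (rad).

    Solves for the CE length at which the SEE force equals the CE force
    ``f_max * a0 * fl(l_ce)`` (isometric, fv = 1), by bracketing on
    (0, l_mt).  Raises :class:`ConfigurationError` when the bracket has no
    sign change, which indicates a geometry/parameter mismatch.
    """
    from .geometry import muscle_tendon_length  # local import, avoids cycle

    a0 = max(a0, p.a_min)
    l_mt = muscle_tendon_length(theta, geom)

    def residual(l_ce: float) -> float:
        return see_force(l_mt - l_ce, p) - p.f_max * a0 * force_length(l_ce, p)

    lo, hi = 1e-6 * p.l_ce_opt, l_mt - 1e-12
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        return MuscleState(a=a0, l_ce=lo)
    if r_lo * r_hi > 0:
        raise ConfigurationError(
            "isometric equilibrium has no solution in (0, l_mt): "
            f"residuals {r_lo:.3g} / {r_hi:.3g}; check geometry and l_slack"
        )
    l_ce = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    if abs(residual(l_ce)) > 1e-8 * p.f_max:
        raise ConfigurationError("isometric equilibrium solve did not converge")
    return MuscleState(a=a0, l_ce=float(l_ce))
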