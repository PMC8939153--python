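"""Hill-muscle primitives: activation dynamics, fl/fv/SEE curves, equilibrium."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myoarm.errors import ConfigurationError, InputValidationError
from myoarm.muscle import (
    MuscleParams,
    MuscleState,
    activation_derivative,
    ce_velocity_from_equilibrium,
    force_length,
    force_velocity,
    force_velocity_inverse,
    init_muscle_state,
    muscle_force,
    see_force,
)

P = MuscleParams()


@pytest.mark.parametrize(
    "field,value",
    [
        ("f_max", -1.0),
        ("l_ce_opt", 0.0),
        ("w", 0.0),
        ("v_max", -2.0),
        ("fv_ecc_max", 1.0),
        ("l_slack", 0.0),
        ("c1", 0.0),
        ("c2", -1.0),
        ("tau_act", 0.2),  # exceeds tau_deact
        ("a_min", 0.5),
    ],
)
def test_params_invariants_rejected(field, value):
    with pytest.raises(InputValidationError, match=field):
        replace(P, **{field: value})


class TestActivation:
    def test_fixed_point(self):
        assert activation_derivative(0.5, 0.5, P) == 0.0

    def test_rise_rate_definition(self):
        p = replace(P, tau_act=0.015)
        assert activation_derivative(1.0, p.a_min, p) == pytest.approx(
            (1 - p.a_min) / 0.015
        )

    def test_step_response_reaches_95pct_within_5_tau(self):
        # RK4 on the scalar linear ODE; closed form predicts 1-exp(-5)>0.99
        a, dt = P.a_min, 1.0 / 150.0
        t = 0.0
        while t < 5 * P.tau_act:
            k1 = activation_derivative(1.0, a, P)
            k2 = activation_derivative(1.0, min(a + dt / 2 * k1, 1.0), P)
            k3 = activation_derivative(1.0, min(a + dt / 2 * k2, 1.0), P)
            k4 = activation_derivative(1.0, min(a + dt * k3, 1.0), P)
            a = min(a + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 1.0)
            t += dt
        assert a >= 0.95

    @pytest.mark.parametrize("u,a", [(-0.1, 0.5), (1.1, 0.5), (0.5, 0.001), (0.5, 1.2)])
    def test_out_of_range_rejected(self, u, a):
        with pytest.raises(InputValidationError):
            activation_derivative(u, a, P)

    def test_activation_stays_bounded_under_random_excitation(self):
        rng = np.random.default_rng(7)
        dt = 1.0 / 150.0
        a = P.a_min
        for u in rng.uniform(0, 1, size=600):
            k1 = activation_derivative(u, a, P)
            a2 = min(max(a + dt * k1, P.a_min), 1.0)
            a = a2
        assert P.a_min <= a <= 1.0


class TestForceLength:
    def test_peak_at_optimum(self):
        assert force_length(P.l_ce_opt, P) == 1.0

    def test_one_width_from_optimum(self):
        assert force_length(P.l_ce_opt * (1 + P.w), P) == pytest.approx(math.exp(-1))

    @given(st.floats(min_value=1e-3, max_value=0.9))
    def test_symmetry(self, x):
        lo = force_length(P.l_ce_opt * (1 - x), P)
        hi = force_length(P.l_ce_opt * (1 + x), P)
        assert lo == pytest.approx(hi, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InputValidationError):
            force_length(0.0, P)


class TestForceVelocity:
    def test_isometric_point(self):
        assert force_velocity(0.0, P) == 1.0

    def test_vmax_and_beyond_zero(self):
        assert force_velocity(P.v_max, P) == 0.0
        assert force_velocity(2 * P.v_max, P) == 0.0

    def test_strictly_decreasing_on_grid(self):
        v = np.linspace(-P.v_max, P.v_max, 1000)
        fv = force_velocity(v, P)
        assert np.all(np.diff(fv) < 0)

    def test_value_and_slope_continuous_at_zero(self):
        h = 1e-8
        assert force_velocity(h, P) == pytest.approx(force_velocity(-h, P), abs=1e-6)
        slope_c = (force_velocity(2 * h, P) - force_velocity(h, P)) / h
        slope_e = (force_velocity(-h, P) - force_velocity(-2 * h, P)) / h
        assert slope_c == pytest.approx(slope_e, rel=1e-4)

    def test_eccentric_asymptote(self):
        assert force_velocity(-1e6, P) < P.fv_ecc_max
        assert force_velocity(-1e6, P) == pytest.approx(P.fv_ecc_max, rel=1e-4)

    def test_roundtrip_inversion_on_grid(self):
        fv = np.linspace(0.0, P.fv_ecc_max - 1e-9, 10_000)
        back = force_velocity(force_velocity_inverse(fv, P), P)
        assert np.max(np.abs(back - fv)) < 1e-9


class TestSeeForce:
    def test_slack_and_buckled_carry_nothing(self):
        assert see_force(P.l_slack, P) == 0.0
        assert see_force(0.9 * P.l_slack, P) == 0.0

    def test_continuous_at_slack(self):
        assert see_force(P.l_slack * (1 + 1e-12), P) == pytest.approx(0.0, abs=1e-6)

    def test_stiffens_with_strain(self):
        # central-difference stiffness at 4% strain exceeds that at 1%
        def stiffness(eps):
            l = P.l_slack * (1 + eps)
            h = 1e-7
            return (see_force(l + h, P) - see_force(l - h, P)) / (2 * h)

        assert stiffness(0.04) > stiffness(0.01)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InputValidationError):
            see_force(-0.01, P)


class TestEquilibriumVelocity:
    def test_isometric_fixed_point(self, cfg):
        st0 = init_muscle_state(np.pi / 2, 0.06, cfg.flexor_path, cfg.flexor)
        v = ce_velocity_from_equilibrium(
            st0, _l_mt(cfg, np.pi / 2), cfg.flexor
        )
        assert abs(v) < 1e-9

    def test_slack_see_shortens_at_vmax(self):
        s = MuscleState(a=0.5, l_ce=P.l_slack)  # l_se = 0 if l_mt = l_slack... use small l_mt
        v = ce_velocity_from_equilibrium(s, P.l_slack * 1.001, P)
        assert v == pytest.approx(P.v_max)

    def test_roundtrip_on_random_states(self, cfg):
        from myoarm.muscle import FL_FLOOR, FV_ECC_MARGIN

        p = cfg.flexor
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = rng.uniform(p.a_min, 1)
            l_ce = rng.uniform(0.3, 1.6) * p.l_ce_opt
            l_mt = rng.uniform(0.95, 1.05) * (p.l_slack + l_ce)
            s = MuscleState(a=a, l_ce=l_ce)
            f_se = see_force(max(l_mt - l_ce, 1e-9), p)
            cap = p.f_max * a * max(force_length(l_ce, p), FL_FLOOR)
            fv_req = min(max(f_se / cap, 0.0), p.fv_ecc_max - FV_ECC_MARGIN)
            v = ce_velocity_from_equilibrium(s, l_mt, p)
            assert force_velocity(v, p) == pytest.approx(fv_req, abs=1e-9)


def _l_mt(cfg, theta):
    from myoarm.geometry import muscle_tendon_length

    return muscle_tendon_length(theta, cfg.flexor_path)


class TestMuscleForceAndInit:
    def test_slack_configuration_transmits_nothing(self):
        s = MuscleState(a=0.8, l_ce=P.l_ce_opt)
        assert muscle_force(s, P.l_ce_opt + 0.95 * P.l_slack, P) == 0.0
        assert muscle_force(s, P.l_ce_opt, P) == 0.0

    def test_monotone_in_mt_length(self, cfg):
        p = cfg.flexor
        s = MuscleState(a=0.5, l_ce=p.l_ce_opt)
        lengths = np.linspace(p.l_ce_opt + 0.8 * p.l_slack, p.l_ce_opt + 1.2 * p.l_slack, 200)
        forces = [muscle_force(s, l, p) for l in lengths]
        assert np.all(np.diff(forces) >= 0)

    def test_init_residual_below_tolerance(self, cfg):
        for p, g in ((cfg.flexor, cfg.flexor_path), (cfg.extensor, cfg.extensor_path)):
            s = init_muscle_state(np.pi / 2, p.a_min, g, p)
            from myoarm.geometry import muscle_tendon_length

            l_mt = muscle_tendon_length(np.pi / 2, g)
            res = abs(see_force(l_mt - s.l_ce, p) - p.f_max * p.a_min * force_length(s.l_ce, p))
            assert res < 1e-8 * p.f_max
            assert 0 < s.l_ce < l_mt

    def test_isometric_settling_balances_forces(self, cfg):
        # hold l_mt and u fixed; the muscle substate converges to force balance
        p = cfg.flexor
        from myoarm.geometry import muscle_tendon_length

        l_mt = muscle_tendon_length(100 * np.pi / 180, cfg.flexor_path)
        a, l_ce, u, dt = 0.4, 0.08, 0.4, 1 / 150

        def deriv(y):
            s = MuscleState(a=min(max(y[0], p.a_min), 1.0), l_ce=y[1])
            return np.array(
                [
                    activation_derivative(u, s.a, p),
                    -ce_velocity_from_equilibrium(s, l_mt, p) * p.l_ce_opt,
                ]
            )

        y = np.array([a, l_ce])
        delta = np.inf
        for _ in range(3000):
            k1 = deriv(y)
            k2 = deriv(y + dt / 2 * k1)
            k3 = deriv(y + dt / 2 * k2)
            k4 = deriv(y + dt * k3)
            y_new = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            delta = np.linalg.norm(y_new - y)
            y = y_new
        assert delta < 1e-10
        f_se = see_force(l_mt - y[1], p)
        f_ce = p.f_max * y[0] * force_length(y[1], p) * force_velocity(0.0, p)
        assert abs(f_se - f_ce) < 1e-6 * p.f_max

    def test_unsolvable_geometry_reports_configuration_error(self, cfg):
        # slack longer than the whole path: SEE can never carry the CE force
        p = replace(cfg.flexor, l_slack=1.0)
        with pytest.raises(ConfigurationError):
            init_muscle_state(np.pi / 2, 0.5, cfg.flexor_path, p)
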