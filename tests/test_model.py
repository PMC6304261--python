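"""Model core: parameter conversions, equations of motion, RK4, GRF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msdgrf import (
    ModelState,
    NaturalParameters,
    ScaledParameters,
    SimulationConfig,
    SimulationDivergedError,
    derivatives,
    grf,
    simulate,
    takeoff_time,
    to_natural,
    to_scaled,
    upper_acc_in_g,
)
from conftest import draw_params

G = -9.81


class TestParameterScaling:
    def test_to_scaled_hand_example(self, demo_natural):
        sc = to_scaled(demo_natural)
        assert sc.lam == pytest.approx(3.0, rel=1e-12)
        assert sc.omega1_sq == pytest.approx(600.0, rel=1e-12)
        assert sc.omega2_sq == pytest.approx(3600.0, rel=1e-12)
        assert sc.zeta == pytest.approx(0.36, rel=1e-12)
        assert sc.M == pytest.approx(76.0)

    def test_zero_damping_gives_zero_zeta(self):
        nat = NaturalParameters.from_masses(57.0, 19.0, 34200.0, 68400.0, 0.0)
        assert to_scaled(nat).zeta == 0.0

    def test_equal_masses_symmetry(self):
        nat = NaturalParameters.from_masses(38.0, 38.0, 30000.0, 60000.0, 100.0)
        sc = to_scaled(nat)
        assert sc.lam == pytest.approx(1.0)
        assert sc.omega2_sq == pytest.approx(2.0 * 60000.0 / nat.M)

    def test_to_natural_hand_example(self):
        sc = ScaledParameters(
            p1=0, p2=0, v1=0, v2=0,
            omega1_sq=600.0, omega2_sq=3600.0, lam=3.0, zeta=0.36, M=76.0,
        )
        nat = to_natural(sc)
        assert nat.m1 == pytest.approx(57.0, rel=1e-12)
        assert nat.m2 == pytest.approx(19.0, rel=1e-12)
        assert nat.k1 == pytest.approx(34200.0, rel=1e-12)
        assert nat.k2 == pytest.approx(68400.0, rel=1e-12)
        assert nat.c == pytest.approx(820.8, rel=1e-12)

    def test_zero_zeta_gives_zero_damping(self):
        sc = ScaledParameters(0, 0, 0, 0, 600.0, 3600.0, 3.0, 0.0, 76.0)
        assert to_natural(sc).c == 0.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_roundtrip_identity(self, seed):
        sc = draw_params(np.random.default_rng(seed))
        back = to_scaled(to_natural(sc), p1=sc.p1, p2=sc.p2, v1=sc.v1, v2=sc.v2)
        for name in ("p1", "p2", "v1", "v2", "omega1_sq", "omega2_sq", "lam", "zeta", "M"):
            a, b = getattr(sc, name), getattr(back, name)
            assert b == pytest.approx(a, rel=1e-12, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NaturalParameters.from_masses(-1.0, 19.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            ScaledParameters(0, 0, 0, 0, 600.0, -1.0, 3.0, 0.36, 76.0)
        with pytest.raises(ValueError):
            ScaledParameters(0, 0, 0, 0, 600.0, 3600.0, -3.0, 0.36, 76.0)


class TestDerivatives:
    def test_equal_positions_free_fall_upper(self, demo_params):
        s = ModelState(t=0.0, p1=0.02, p2=0.02, v1=-1.0, v2=0.5)
        _, _, a1, _ = derivatives(s, demo_params, g=G)
        assert a1 == pytest.approx(G)

    def test_zero_state_both_accelerate_at_g(self, demo_params):
        s = ModelState(t=0.0, p1=0.0, p2=0.0, v1=0.0, v2=0.0)
        _, _, a1, a2 = derivatives(s, demo_params, g=G)
        assert a1 == pytest.approx(G)
        assert a2 == pytest.approx(G)

    def test_newtons_second_law_identity(self):
        # m1 (a1 - g) + m2 (a2 - g) must equal the lower-element force
        # -(k2 p2 + c v2) for any state: the only external vertical forces
        # are gravity and the ground contact.
        rng = np.random.default_rng(1234)
        for _ in range(100):
            sc = draw_params(rng)
            nat = to_natural(sc)
            s = ModelState(
                t=0.0,
                p1=rng.uniform(-0.1, 0.1), p2=rng.uniform(-0.1, 0.1),
                v1=rng.uniform(-3, 3), v2=rng.uniform(-3, 3),
            )
            _, _, a1, a2 = derivatives(s, sc, g=G)
            lhs = nat.m1 * (a1 - G) + nat.m2 * (a2 - G)
            rhs = -(nat.k2 * s.p2 + nat.c * s.v2)
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestSimulate:
    def test_free_fall_closed_form(self):
        # omega1_sq = 0 decouples the upper mass: exact parabola, which
        # fixed-step RK4 reproduces to machine precision.
        sc = ScaledParameters(
            p1=0.01, p2=0.0, v1=-0.8, v2=-0.02,
            omega1_sq=0.0, omega2_sq=3600.0, lam=3.0, zeta=0.36, M=76.0,
        )
        cfg = SimulationConfig(dt=1e-4, duration=0.3)
        traj = simulate(sc, cfg)
        exact = sc.p1 + sc.v1 * traj.t + 0.5 * G * traj.t**2
        assert np.max(np.abs(traj.p1 - exact)) < 1e-12

    def test_damped_oscillator_closed_form(self):
        # with omega1_sq = 0 the lower mass is an underdamped oscillator
        # about its gravity-loaded equilibrium
        w2, zeta = 3600.0, 0.36
        sc = ScaledParameters(
            p1=0.0, p2=0.01, v1=0.0, v2=-0.5,
            omega1_sq=0.0, omega2_sq=w2, lam=3.0, zeta=zeta, M=76.0,
        )
        cfg = SimulationConfig(dt=1e-4, duration=0.3)
        traj = simulate(sc, cfg)
        wn = np.sqrt(w2)
        wd = wn * np.sqrt(1 - zeta**2)
        eq = G / w2
        u0 = sc.p2 - eq
        exact = eq + np.exp(-zeta * wn * traj.t) * (
            u0 * np.cos(wd * traj.t)
            + (sc.v2 + zeta * wn * u0) / wd * np.sin(wd * traj.t)
        )
        assert np.max(np.abs(traj.p2 - exact)) < 1e-6

    def test_rk4_fourth_order_convergence(self, demo_params):
        def endpoint(dt):
            traj = simulate(demo_params, SimulationConfig(dt=dt, duration=0.3))
            return np.array([traj.p1[-1], traj.p2[-1], traj.v1[-1], traj.v2[-1]])

        ref = endpoint(1e-6)
        err_coarse = np.linalg.norm(endpoint(2e-4) - ref)
        err_fine = np.linalg.norm(endpoint(1e-4) - ref)
        ratio = err_coarse / err_fine
        assert 12.0 <= ratio <= 20.0

    def test_energy_conserved_without_damping_or_gravity(self):
        sc = ScaledParameters(
            p1=0.02, p2=-0.01, v1=-0.5, v2=0.3,
            omega1_sq=600.0, omega2_sq=3600.0, lam=3.0, zeta=0.0, M=76.0,
        )
        cfg = SimulationConfig(dt=1e-4, duration=0.5, g=0.0)
        traj = simulate(sc, cfg)
        nat = to_natural(sc)
        energy = (
            0.5 * nat.m1 * traj.v1**2
            + 0.5 * nat.m2 * traj.v2**2
            + 0.5 * nat.k1 * (traj.p1 - traj.p2) ** 2
            + 0.5 * nat.k2 * traj.p2**2
        )
        assert np.max(np.abs(energy - energy[0])) / energy[0] < 1e-6

    def test_divergence_raises_with_last_valid_time(self):
        # omega2 dt >> 1 puts fixed-step RK4 far outside its stability region
        sc = ScaledParameters(
            p1=0.0, p2=0.01, v1=0.0, v2=0.0,
            omega1_sq=600.0, omega2_sq=1e9, lam=3.0, zeta=0.0, M=76.0,
        )
        with pytest.raises(SimulationDivergedError) as exc:
            simulate(sc, SimulationConfig(dt=1e-3, duration=1.0))
        assert 0.0 <= exc.value.t_last < 1.0

    def test_state_count(self, demo_params):
        traj = simulate(demo_params, SimulationConfig(dt=1e-3, duration=0.25))
        assert traj.n == 251


class TestGrfAndAcceleration:
    def test_unloaded_spring_damper_reads_zero(self):
        sc = ScaledParameters(0.01, 0.0, -1.0, 0.0, 600.0, 3600.0, 3.0, 0.36, 76.0)
        cfg = SimulationConfig(duration=0.01)
        traj = simulate(sc, cfg)
        assert grf(traj).values[0] == pytest.approx(0.0, abs=1e-12)

    def test_damper_only_hand_value(self):
        # p2=0, v2=-2: GRF(0) = c |v2| = 820.8 * 2 = 1641.6 N
        sc = ScaledParameters(0.0, 0.0, 0.0, -2.0, 600.0, 3600.0, 3.0, 0.36, 76.0)
        traj = simulate(sc, SimulationConfig(duration=0.01))
        assert grf(traj).values[0] == pytest.approx(1641.6, rel=1e-12)

    def test_newton_identity_along_trajectory(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            sc = draw_params(rng)
            traj = simulate(sc, SimulationConfig(duration=0.2))
            nat = to_natural(sc)
            spring = sc.omega1_sq * (traj.p1 - traj.p2)
            a1 = -spring + G
            a2 = (
                -sc.omega2_sq * traj.p2 + sc.lam * spring
                - 2 * sc.zeta * np.sqrt(sc.omega2_sq) * traj.v2 + G
            )
            newton = nat.m1 * (a1 - G) + nat.m2 * (a2 - G)
            f = grf(traj).values
            assert np.max(np.abs(f - newton)) <= 1e-9 * max(np.max(np.abs(f)), 1.0)

    def test_proper_acceleration_free_fall_and_static(self):
        sc = ScaledParameters(0.02, 0.02, 0.0, 0.0, 600.0, 3600.0, 3.0, 0.36, 76.0)
        traj = simulate(sc, SimulationConfig(duration=0.01))
        # p1 == p2 at t=0: upper spring unloaded, accelerometer reads 0 g
        assert upper_acc_in_g(traj).values[0] == pytest.approx(0.0, abs=1e-12)
        # static support: p1 - p2 = g/omega1_sq makes a1 = 0, i.e. 1 g
        sc2 = ScaledParameters(G / 600.0, 0.0, 0.0, 0.0, 600.0, 3600.0, 3.0, 0.36, 76.0)
        traj2 = simulate(sc2, SimulationConfig(duration=0.01))
        assert upper_acc_in_g(traj2).values[0] == pytest.approx(1.0, rel=1e-12)

    def test_proper_acceleration_matches_velocity_derivative(self, demo_params):
        traj = simulate(demo_params, SimulationConfig(dt=1e-4, duration=0.2))
        acc = upper_acc_in_g(traj).values
        dv1 = np.gradient(traj.v1, traj.config.dt)
        assert np.max(np.abs(acc[1:-1] - (dv1[1:-1] - G) / 9.81)) < 1e-3

    def test_takeoff_detected_after_peak(self, demo_params):
        traj = simulate(demo_params, SimulationConfig(duration=0.5))
        t_off = takeoff_time(traj)
        f = grf(traj).values
        assert t_off is not None
        assert traj.t[np.argmax(f)] < t_off < 0.5
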