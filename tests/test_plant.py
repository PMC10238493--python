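"""Physics of the planar two-link standing model: segment derivation,
kinematics, dynamics invariants, energy bookkeeping and CoP."""

import dataclasses
import math

import numpy as np
import pytest
import sympy as sp

from posturecoord import plant
from posturecoord.plant import (PlantState, GeometryError,
                                derive_segment_parameters,
                                forward_kinematics, step_dynamics, compute_cop,
                                mass_matrix, coriolis_matrix, total_energy)


class TestSegmentDerivation:
    def test_default_morphology_reproduces_com_height(self):
        p = derive_segment_parameters(40.15, 1.57, 0.814)
        m = p.leg_mass + p.trunk_mass
        com = (p.leg_mass * p.leg_com_distance
               + p.trunk_mass * (p.leg_length + p.trunk_com_distance)) / m
        assert com == pytest.approx(0.814, abs=1e-6)
        assert m == pytest.approx(40.15, abs=1e-9)
        assert p.leg_length + p.head_distance == pytest.approx(1.57)

    def test_mass_scaling_is_linear(self):
        p1 = derive_segment_parameters(40.15, 1.57, 0.814)
        p2 = derive_segment_parameters(80.30, 1.57, 0.814)
        assert p2.leg_mass == pytest.approx(2 * p1.leg_mass)
        assert p2.trunk_mass == pytest.approx(2 * p1.trunk_mass)
        assert p2.leg_length == p1.leg_length
        assert p2.trunk_com_distance == pytest.approx(p1.trunk_com_distance)

    def test_infeasible_geometry_raises(self):
        with pytest.raises(GeometryError):
            derive_segment_parameters(40.15, 1.57, 1.56)   # CoM at head height
        with pytest.raises(GeometryError):
            derive_segment_parameters(40.15, 1.57, 0.30)   # CoM below the legs

    def test_table_defaults(self, params):
        assert params.torque_limit == 100.0
        assert params.ankle_angle_range == pytest.approx(
            (math.radians(-50), math.radians(50)))
        assert params.hip_angle_range == pytest.approx(
            (math.radians(-120), math.radians(45)))
        assert params.ankle_stiffness == 25.0
        assert params.hip_stiffness == 125.0


class TestKinematics:
    def test_upright_head_position(self, params):
        mech = forward_kinematics(PlantState(), params)
        assert mech.head_x == pytest.approx(0.0, abs=1e-12)
        assert mech.head_z == pytest.approx(params.total_height)
        assert mech.com_z == pytest.approx(0.814, abs=1e-9)
        assert not mech.fallen

    def test_quarter_turn(self, params):
        mech = forward_kinematics(PlantState(theta_ankle=math.pi / 2), params)
        assert mech.head_z == pytest.approx(0.0, abs=1e-12)
        assert mech.head_x == pytest.approx(params.total_height)

    def test_against_trigonometric_oracle(self, params):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ta, th = rng.uniform(-0.3, 0.3, 2)
            mech = forward_kinematics(PlantState(theta_ankle=ta, theta_hip=th), params)
            # independent recomputation from raw geometry
            hx = params.leg_length * math.sin(ta) + params.head_distance * math.sin(ta + th)
            hz = params.leg_length * math.cos(ta) + params.head_distance * math.cos(ta + th)
            assert mech.head_x == pytest.approx(hx, abs=1e-12)
            assert mech.head_z == pytest.approx(hz, abs=1e-12)


class TestDynamics:
    def test_equilibrium_without_gravity(self, params):
        p0 = dataclasses.replace(params, gravity=0.0)
        st = PlantState()
        for _ in range(100):
            st, _ = step_dynamics(st, (0.0, 0.0), p0, 1e-3)
        assert st.as_array() == pytest.approx(np.zeros(4), abs=1e-14)

    def test_energy_conservation_undamped(self, params):
        # strong springs keep the free oscillation inside the joint limits
        p0 = dataclasses.replace(params, ankle_damping=0.0, hip_damping=0.0,
                                 ankle_stiffness=800.0, hip_stiffness=800.0)
        st = PlantState(theta_ankle=0.05, theta_hip=-0.03)
        e0 = total_energy(st, p0)
        for _ in range(10_000):
            st, mech = step_dynamics(st, (0.0, 0.0), p0, 1e-3)
            assert not mech.limits_hit
        assert abs(total_energy(st, p0) - e0) / abs(e0) < 1e-6

    def test_damping_dissipates(self, params):
        p0 = dataclasses.replace(params, ankle_stiffness=800.0, hip_stiffness=800.0)
        st = PlantState(theta_ankle=0.05, theta_hip=-0.03)
        energies = [total_energy(st, p0)]
        for _ in range(2000):
            st, _ = step_dynamics(st, (0.0, 0.0), p0, 1e-3)
            energies.append(total_energy(st, p0))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12)

    def test_torque_saturation(self, params):
        st = PlantState()
        _, mech = step_dynamics(st, (250.0, -250.0), params, 1e-3)
        assert mech.ankle_torque_applied == 100.0
        assert mech.hip_torque_applied == -100.0

    def test_mass_matrix_symmetric_positive_definite(self, params):
        for th in np.linspace(-2.0, 0.7, 17):
            M = mass_matrix(th, params)
            assert M[0, 1] == M[1, 0]
            assert np.all(np.linalg.eigvalsh(M) > 0)

    def test_skew_symmetry_identity(self, params):
        # d/dt M(q) - 2 C(q, q') must be skew-symmetric
        rng = np.random.default_rng(3)
        _, _, h, _, _ = plant._coeffs(params)
        for _ in range(20):
            th, wa, wh = rng.uniform(-1, 1, 3)
            C = coriolis_matrix(th, wa, wh, params)
            s = np.sin(th)
            Mdot = np.array([[-2 * h * s * wh, -h * s * wh],
                             [-h * s * wh, 0.0]])
            S = Mdot - 2 * C
            assert np.allclose(S, -S.T, atol=1e-12)

    def test_hip_locked_pendulum_frequency(self, params):
        # flip gravity so upright is a stable hanging configuration; lock the
        # hip with a near-rigid spring; compare the small-oscillation
        # frequency with the closed-form rigid-pendulum value
        p0 = dataclasses.replace(params, gravity=-9.81,
                                 ankle_stiffness=1e-6, ankle_damping=0.0,
                                 hip_stiffness=1e6, hip_damping=300.0)
        J1, J2, h, g1, g2 = plant._coeffs(p0)
        omega_expected = math.sqrt(abs(g1 + g2) / (J1 + J2 + 2 * h))
        st = PlantState(theta_ankle=math.radians(1.0))
        times, angles = [], []
        for _ in range(10_000):
            st, _ = step_dynamics(st, (0.0, 0.0), p0, 1e-3)
            times.append(st.time)
            angles.append(st.theta_ankle)
        angles = np.asarray(angles)
        crossings = np.flatnonzero(np.diff(np.signbit(angles)))
        period = 2 * np.mean(np.diff(np.asarray(times)[crossings]))
        omega_measured = 2 * math.pi / period
        assert omega_measured == pytest.approx(omega_expected, rel=0.01)

    def test_dt_validation(self, params):
        with pytest.raises(ValueError):
            step_dynamics(PlantState(), (0.0, 0.0), params, 0.06)
        with pytest.raises(ValueError):
            step_dynamics(PlantState(), (np.nan, 0.0), params, 1e-3)


class TestCenterOfPressure:
    def test_static_limit_equals_com_projection(self, params):
        st = PlantState(theta_ankle=0.03, theta_hip=-0.05)
        mech = forward_kinematics(st, params)
        assert compute_cop(st, (0.0, 0.0), params) == pytest.approx(mech.com_x, abs=1e-12)

    def test_small_lean_first_order(self, params):
        th = 1e-3
        cop = compute_cop(PlantState(theta_ankle=th), (0.0, 0.0), params)
        assert cop == pytest.approx(params.standing_com_height * th, rel=1e-3)

    def test_dynamic_case_matches_symbolic_oracle(self, params):
        """Full Newton-Euler balance derived independently with sympy."""
        t1, t2, w1, w2, a1, a2 = sp.symbols("t1 t2 w1 w2 a1 a2")
        p = params
        m1, m2 = p.leg_mass, p.upper_mass
        r1, r2, L1 = p.leg_com_distance, p.trunk_com_distance, p.leg_length
        I1, I2 = p.leg_inertia, p.trunk_inertia
        g = p.gravity
        q1, q2 = t1, t1 + t2
        x1s, z1s = r1 * sp.sin(q1), r1 * sp.cos(q1)
        x2s = L1 * sp.sin(q1) + r2 * sp.sin(q2)
        z2s = L1 * sp.cos(q1) + r2 * sp.cos(q2)

        def ddt(expr):
            # chain rule through (t1, t2, w1, w2) with prescribed rates
            return (sp.diff(expr, t1) * w1 + sp.diff(expr, t2) * w2
                    + sp.diff(expr, w1) * sp.Symbol("al1")
                    + sp.diff(expr, w2) * sp.Symbol("al2"))

        al1, al2 = sp.Symbol("al1"), sp.Symbol("al2")
        ax1, az1 = ddt(ddt(x1s)), ddt(ddt(z1s))
        ax2, az2 = ddt(ddt(x2s)), ddt(ddt(z2s))
        Fz = m1 * (az1 + g) + m2 * (az2 + g)
        dH = (m1 * (z1s * ax1 - x1s * az1) + I1 * al1
              + m2 * (z2s * ax2 - x2s * az2) + I2 * (al1 + al2))
        Mg = g * (m1 * x1s + m2 * x2s)
        cop_expr = (Mg - dH) / Fz
        f = sp.lambdify((t1, t2, w1, w2, al1, al2), cop_expr, "numpy")

        rng = np.random.default_rng(11)
        for _ in range(10):
            ta, th_, wa, wh, qdd1, qdd2 = rng.uniform(-0.5, 0.5, 6)
            st = PlantState(theta_ankle=ta, theta_hip=th_,
                            omega_ankle=wa, omega_hip=wh)
            got = compute_cop(st, (qdd1, qdd2), params)
            assert got == pytest.approx(float(f(ta, th_, wa, wh, qdd1, qdd2)), abs=1e-9)

    def test_airborne_rejected(self, params):
        # enormous forward angular acceleration unloads the foot
        with pytest.raises(ValueError):
            compute_cop(PlantState(theta_ankle=0.3), (500.0, 0.0), params)
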