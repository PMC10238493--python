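"""Planar two-link (ankle + hip) inverted-pendulum standing model.

The standing human is reduced to a sagittal-plane double inverted pendulum:
link 1 is both legs lumped together (ankle pinned to the ground), link 2 is
the head-arms-trunk (HAT) segment articulated at the hip.  Both joints carry
passive rotational stiffness and damping about a neutral upright posture and
accept bounded active torques.  The module provides segment-parameter
derivation from aggregate anthropometry, forward kinematics, a fixed-step
RK4 integrator for the manipulator equations

    M(q) q" + C(q, q') q' + G(q) = tau_active + tau_passive,

center-of-pressure (CoP) computation from a whole-body Newton-Euler balance,
and fall detection against a trunk-height threshold.

Conventions
-----------
Angles are measured from the upright vertical; positive rotation tilts the
segment toward +x.  ``theta_hip`` is the relative hip angle, so the trunk's
absolute inclination is ``theta_ankle + theta_hip``.  All quantities are SI
(rad, m, kg, N·m); configuration files store angle ranges in degrees and are
converted at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "PlantParams",
    "PlantState",
    "MechanicsOutput",
    "GeometryError",
    "IntegrationError",
    "derive_segment_parameters",
    "forward_kinematics",
    "step_dynamics",
    "compute_cop",
    "mass_matrix",
    "coriolis_matrix",
    "gravity_vector",
    "passive_torques",
    "total_energy",
    "trunk_reference_height",
]

# Anthropometric mass/length fractions for the two-segment reduction.  The
# leg segment is treated as a uniform rod (CoM at mid-length); the HAT CoM
# offset is then solved from the prescribed whole-body CoM height.
LEG_MASS_FRACTION = 0.32
TRUNK_MASS_FRACTION = 0.68
LEG_LENGTH_FRACTION = 0.53

GRAVITY_DEFAULT = 9.81


class GeometryError(ValueError):
    """Raised when aggregate anthropometry cannot be realized by the model."""


class IntegrationError(RuntimeError):
    """Raised when the dynamics integrator produces a non-finite state."""


@dataclass(frozen=True)
class PlantParams:
    """Physical constants of the planar standing model (SI units)."""

    total_mass: float
    total_height: float
    standing_com_height: float
    leg_mass: float
    trunk_mass: float
    leg_length: float
    leg_com_distance: float        # ankle -> leg CoM
    trunk_com_distance: float      # hip -> HAT CoM
    head_distance: float           # hip -> head
    added_mass: float = 0.0        # extra load attached at the HAT CoM
    ankle_stiffness: float = 25.0
    hip_stiffness: float = 125.0
    ankle_damping: float = 2.0
    hip_damping: float = 2.0
    torque_limit: float = 100.0
    ankle_angle_range: Tuple[float, float] = (math.radians(-50.0), math.radians(50.0))
    hip_angle_range: Tuple[float, float] = (math.radians(-120.0), math.radians(45.0))
    neutral_angles: Tuple[float, float] = (0.0, 0.0)
    gravity: float = GRAVITY_DEFAULT
    fall_height_threshold: float = 1.0

    def __post_init__(self) -> None:
        if min(self.total_mass, self.total_height, self.leg_mass, self.trunk_mass,
               self.leg_length, self.leg_com_distance, self.trunk_com_distance,
               self.head_distance, self.ankle_stiffness, self.hip_stiffness) <= 0:
            raise ValueError("masses, lengths and stiffnesses must be strictly positive")
        if self.ankle_damping < 0 or self.hip_damping < 0 or self.torque_limit <= 0:
            raise ValueError("damping must be non-negative, torque_limit positive")
        if abs(self.leg_mass + self.trunk_mass - self.total_mass) > 1e-9:
            raise ValueError("leg_mass + trunk_mass must equal total_mass (added_mass is extra)")
        if self.added_mass < 0:
            raise ValueError("added_mass must be non-negative")
        for (lo, hi), neutral in zip((self.ankle_angle_range, self.hip_angle_range),
                                     self.neutral_angles):
            if not (lo <= neutral <= hi):
                raise ValueError("angle range must contain the neutral angle")

    # -- derived inertial coefficients ------------------------------------
    @property
    def leg_inertia(self) -> float:
        """Leg-segment moment of inertia about its CoM (slender rod)."""
        return self.leg_mass * self.leg_length ** 2 / 12.0

    @property
    def trunk_inertia(self) -> float:
        """HAT moment of inertia about its CoM (slender rod hip->head)."""
        return self.trunk_mass * self.head_distance ** 2 / 12.0

    @property
    def upper_mass(self) -> float:
        """HAT mass plus any added load (the load sits at the HAT CoM)."""
        return self.trunk_mass + self.added_mass

    def with_added_mass(self, added_mass: float) -> "PlantParams":
        return replace(self, added_mass=float(added_mass))

    def with_stiffness(self, ankle: float | None = None, hip: float | None = None) -> "PlantParams":
        kw = {}
        if ankle is not None:
            kw["ankle_stiffness"] = float(ankle)
        if hip is not None:
            kw["hip_stiffness"] = float(hip)
        return replace(self, **kw)


@dataclass
class PlantState:
    """Instantaneous mechanical state (angles relative to upright)."""

    theta_ankle: float = 0.0
    theta_hip: float = 0.0
    omega_ankle: float = 0.0
    omega_hip: float = 0.0
    time: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_ankle, self.theta_hip,
                         self.omega_ankle, self.omega_hip], dtype=float)


@dataclass
class MechanicsOutput:
    """Per-step mechanical observables derived from the state."""

    head_x: float
    head_z: float
    com_x: float
    com_z: float
    cop_x: float
    ankle_torque_applied: float
    hip_torque_applied: float
    fallen: bool
    trunk_ref_height: float = 0.0
    limits_hit: bool = False


def derive_segment_parameters(total_mass: float, total_height: float,
                              standing_com_height: float, **overrides) -> PlantParams:
    """Build :class:`PlantParams` from aggregate anthropometry.

    Segment masses follow fixed fractions (legs 32 %, HAT 68 %), the leg
    length is 53 % of stature with its CoM at mid-length, and the HAT CoM
    offset is solved so the upright whole-body CoM height matches
    ``standing_com_height`` exactly.  The head sits at ``total_height``.
    Remaining fields (stiffness, damping, limits) take their defaults unless
    passed as keyword overrides.
    """
    if min(total_mass, total_height, standing_com_height) <= 0:
        raise GeometryError("anthropometric inputs must be positive")
    if standing_com_height >= total_height:
        raise GeometryError("standing CoM height must be below the head")

    leg_mass = LEG_MASS_FRACTION * total_mass
    trunk_mass = TRUNK_MASS_FRACTION * total_mass
    leg_length = LEG_LENGTH_FRACTION * total_height
    head_distance = total_height - leg_length
    leg_com = 0.5 * leg_length
    # whole-body CoM: (m1*c1 + m2*(L1 + c2)) / M = standing_com_height
    trunk_com = (total_mass * standing_com_height
                 - leg_mass * leg_com - trunk_mass * leg_length) / trunk_mass
    if not (0.0 < trunk_com < head_distance):
        raise GeometryError(
            f"whole-body CoM height {standing_com_height} m is not bracketable: "
            f"solved HAT CoM offset {trunk_com:.4f} m outside (0, {head_distance:.4f})")
    return PlantParams(total_mass=total_mass, total_height=total_height,
                       standing_com_height=standing_com_height,
                       leg_mass=leg_mass, trunk_mass=trunk_mass,
                       leg_length=leg_length, leg_com_distance=leg_com,
                       trunk_com_distance=trunk_com, head_distance=head_distance,
                       **overrides)


def default_params(**overrides) -> PlantParams:
    """Table-1-style default morphology (40.15 kg, 1.57 m, CoM 0.814 m)."""
    return derive_segment_parameters(40.15, 1.57, 0.814, **overrides)


# ---------------------------------------------------------------------------
# dynamics coefficients (all functions broadcast over array-valued angles)
# ---------------------------------------------------------------------------

def _coeffs(p: PlantParams):
    m1, m2 = p.leg_mass, p.upper_mass
    c1, c2, L1 = p.leg_com_distance, p.trunk_com_distance, p.leg_length
    I1, I2 = p.leg_inertia, p.trunk_inertia
    J1 = I1 + m1 * c1 ** 2 + m2 * L1 ** 2
    J2 = I2 + m2 * c2 ** 2
    h = m2 * L1 * c2
    g1 = (m1 * c1 + m2 * L1) * p.gravity   # torque coefficient, sin(a1)
    g2 = m2 * c2 * p.gravity               # torque coefficient, sin(a2)
    return J1, J2, h, g1, g2


def mass_matrix(theta_hip, params: PlantParams) -> np.ndarray:
    """Configuration-dependent inertia matrix M(q), shape (..., 2, 2)."""
    J1, J2, h, _, _ = _coeffs(params)
    c2 = np.cos(theta_hip)
    m11 = J1 + J2 + 2.0 * h * c2
    m12 = J2 + h * c2
    m22 = np.broadcast_to(J2, np.shape(m11))
    return np.stack([np.stack([m11, m12], axis=-1),
                     np.stack([m12, m22], axis=-1)], axis=-2)


def coriolis_matrix(theta_hip, omega_ankle, omega_hip, params: PlantParams) -> np.ndarray:
    """Coriolis/centrifugal matrix C(q, q'), shape (..., 2, 2)."""
    _, _, h, _, _ = _coeffs(params)
    s2 = np.sin(theta_hip)
    c11 = -h * s2 * omega_hip
    c12 = -h * s2 * (omega_ankle + omega_hip)
    c21 = h * s2 * omega_ankle
    c22 = np.zeros_like(c11)
    return np.stack([np.stack([c11, c12], axis=-1),
                     np.stack([c21, c22], axis=-1)], axis=-2)


def gravity_vector(theta_ankle, theta_hip, params: PlantParams) -> np.ndarray:
    """Gravity torque vector G(q) (destabilizing about upright), (..., 2)."""
    _, _, _, g1, g2 = _coeffs(params)
    a2 = theta_ankle + theta_hip
    G1 = -(g1 * np.sin(theta_ankle) + g2 * np.sin(a2))
    G2 = -g2 * np.sin(a2)
    return np.stack([G1, G2], axis=-1)


def passive_torques(theta_ankle, theta_hip, omega_ankle, omega_hip,
                    params: PlantParams) -> np.ndarray:
    """Passive spring-damper joint torques -K (q - q_neutral) - D q'."""
    na, nh = params.neutral_angles
    ta = -params.ankle_stiffness * (theta_ankle - na) - params.ankle_damping * omega_ankle
    th = -params.hip_stiffness * (theta_hip - nh) - params.hip_damping * omega_hip
    return np.stack([np.broadcast_to(ta, np.shape(ta)),
                     np.broadcast_to(th, np.shape(th))], axis=-1)


def _accelerations(q, qd, tau_applied, params: PlantParams) -> np.ndarray:
    """Joint accelerations for state arrays q, qd of shape (..., 2).

    Uses the closed-form 2x2 solve rather than np.linalg.solve: this sits
    in the innermost loop of vectorized training rollouts.
    """
    ta, th = q[..., 0], q[..., 1]
    wa, wh = qd[..., 0], qd[..., 1]
    J1, J2, h, g1, g2 = _coeffs(params)
    c2, s2 = np.cos(th), np.sin(th)
    m11 = J1 + J2 + 2.0 * h * c2
    m12 = J2 + h * c2
    m22 = J2
    # C(q, q') q' terms
    cc1 = -h * s2 * (2.0 * wa * wh + wh ** 2)
    cc2 = h * s2 * wa ** 2
    a2 = ta + th
    G1 = -(g1 * np.sin(ta) + g2 * np.sin(a2))
    G2 = -g2 * np.sin(a2)
    na, nh = params.neutral_angles
    tp1 = -params.ankle_stiffness * (ta - na) - params.ankle_damping * wa
    tp2 = -params.hip_stiffness * (th - nh) - params.hip_damping * wh
    r1 = tau_applied[..., 0] + tp1 - cc1 - G1
    r2 = tau_applied[..., 1] + tp2 - cc2 - G2
    det = m11 * m22 - m12 * m12
    return np.stack([(m22 * r1 - m12 * r2) / det,
                     (m11 * r2 - m12 * r1) / det], axis=-1)


# ---------------------------------------------------------------------------
# kinematics, CoP, energy
# ---------------------------------------------------------------------------

def _segment_positions(theta_ankle, theta_hip, params: PlantParams):
    a1 = np.asarray(theta_ankle, dtype=float)
    a2 = a1 + np.asarray(theta_hip, dtype=float)
    p = params
    x1, z1 = p.leg_com_distance * np.sin(a1), p.leg_com_distance * np.cos(a1)
    x2 = p.leg_length * np.sin(a1) + p.trunk_com_distance * np.sin(a2)
    z2 = p.leg_length * np.cos(a1) + p.trunk_com_distance * np.cos(a2)
    return a1, a2, x1, z1, x2, z2


def trunk_reference_height(theta_ankle, theta_hip, params: PlantParams):
    """Height of the trunk segment's geometric midpoint (fall reference).

    The hip->head midpoint is used rather than the mass-weighted HAT CoM:
    the planar reduction pulls the HAT CoM down to ~1.00 m upright (to honor
    the aggregate whole-body CoM), which would make a 1 m fall threshold
    fire at a ~3 degree lean.  The segment midpoint (1.20 m upright) is the
    closest planar analogue of the 3D torso-body CoM the fall rule refers to.
    """
    a1 = np.asarray(theta_ankle, dtype=float)
    a2 = a1 + np.asarray(theta_hip, dtype=float)
    return params.leg_length * np.cos(a1) + 0.5 * params.head_distance * np.cos(a2)


def forward_kinematics(state: PlantState, params: PlantParams) -> MechanicsOutput:
    """Positions-only mechanics: head/CoM locations, static CoP, fall flag."""
    a1, a2, x1, z1, x2, z2 = _segment_positions(state.theta_ankle, state.theta_hip, params)
    p = params
    head_x = p.leg_length * np.sin(a1) + p.head_distance * np.sin(a2)
    head_z = p.leg_length * np.cos(a1) + p.head_distance * np.cos(a2)
    mtot = p.leg_mass + p.upper_mass
    com_x = (p.leg_mass * x1 + p.upper_mass * x2) / mtot
    com_z = (p.leg_mass * z1 + p.upper_mass * z2) / mtot
    trunk_z = trunk_reference_height(state.theta_ankle, state.theta_hip, p)
    return MechanicsOutput(head_x=float(head_x), head_z=float(head_z),
                           com_x=float(com_x), com_z=float(com_z),
                           cop_x=float(com_x),  # static limit
                           ankle_torque_applied=0.0, hip_torque_applied=0.0,
                           fallen=bool(trunk_z < p.fall_height_threshold),
                           trunk_ref_height=float(trunk_z))


def head_position(theta_ankle, theta_hip, params: PlantParams):
    """Vectorized head (x, z); used by the task and fixture layers."""
    a1 = np.asarray(theta_ankle, dtype=float)
    a2 = a1 + np.asarray(theta_hip, dtype=float)
    return (params.leg_length * np.sin(a1) + params.head_distance * np.sin(a2),
            params.leg_length * np.cos(a1) + params.head_distance * np.cos(a2))


def head_velocity_x(theta_ankle, theta_hip, omega_ankle, omega_hip, params: PlantParams):
    a1 = np.asarray(theta_ankle, dtype=float)
    a2 = a1 + np.asarray(theta_hip, dtype=float)
    w1 = np.asarray(omega_ankle, dtype=float)
    w2 = w1 + np.asarray(omega_hip, dtype=float)
    return params.leg_length * np.cos(a1) * w1 + params.head_distance * np.cos(a2) * w2


def compute_cop(state: PlantState, accelerations, params: PlantParams) -> float:
    """Center of pressure (m, relative to the ankle) from a force balance.

    Whole-body Newton-Euler about the ankle pin: the ground-reaction wrench
    (vertical force Fz at the CoP) must close the moment balance
    ``M_grf + M_gravity = dH/dt``.  In the static limit this reduces to the
    horizontal CoM projection.
    """
    qdd = np.asarray(accelerations, dtype=float)
    return float(_cop_from_arrays(state.as_array()[None, :2], state.as_array()[None, 2:],
                                  qdd[None, :], params)[0])


def _cop_from_arrays(q, qd, qdd, params: PlantParams, strict: bool = True) -> np.ndarray:
    p = params
    a1 = q[..., 0]
    a2 = q[..., 0] + q[..., 1]
    w1 = qd[..., 0]
    w2 = qd[..., 0] + qd[..., 1]
    al1 = qdd[..., 0]
    al2 = qdd[..., 0] + qdd[..., 1]
    s1, c1 = np.sin(a1), np.cos(a1)
    s2, c2 = np.sin(a2), np.cos(a2)
    m1, m2 = p.leg_mass, p.upper_mass
    r1, r2, L1 = p.leg_com_distance, p.trunk_com_distance, p.leg_length
    # segment CoM positions and accelerations
    x1, z1 = r1 * s1, r1 * c1
    x2, z2 = L1 * s1 + r2 * s2, L1 * c1 + r2 * c2
    ax1 = r1 * (c1 * al1 - s1 * w1 ** 2)
    az1 = -r1 * (s1 * al1 + c1 * w1 ** 2)
    ax2 = L1 * (c1 * al1 - s1 * w1 ** 2) + r2 * (c2 * al2 - s2 * w2 ** 2)
    az2 = -L1 * (s1 * al1 + c1 * w1 ** 2) - r2 * (s2 * al2 + c2 * w2 ** 2)
    g = p.gravity
    Fz = m1 * (az1 + g) + m2 * (az2 + g)
    if strict and np.any(Fz <= 0):
        raise ValueError("vertical ground-reaction force is non-positive (airborne state)")
    # rate of angular momentum about the ankle (y-component, M_y = z*Fx - x*Fz)
    dH = (m1 * (z1 * ax1 - x1 * az1) + p.leg_inertia * al1
          + m2 * (z2 * ax2 - x2 * az2) + p.trunk_inertia * al2)
    Mg = g * (m1 * x1 + m2 * x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cop = np.where(Fz > 0, (Mg - dH) / np.where(Fz > 0, Fz, 1.0), np.nan)
    return cop


def total_energy(state: PlantState, params: PlantParams) -> float:
    """Kinetic + gravitational + elastic energy (J); conserved when
    undamped, unactuated and inside joint limits."""
    q = np.array([state.theta_ankle, state.theta_hip])
    qd = np.array([state.omega_ankle, state.omega_hip])
    M = mass_matrix(state.theta_hip, params)
    ke = 0.5 * float(qd @ M @ qd)
    _, _, x1, z1, x2, z2 = _segment_positions(state.theta_ankle, state.theta_hip, params)
    pe = params.gravity * (params.leg_mass * float(z1) + params.upper_mass * float(z2))
    na, nh = params.neutral_angles
    el = (0.5 * params.ankle_stiffness * (state.theta_ankle - na) ** 2
          + 0.5 * params.hip_stiffness * (state.theta_hip - nh) ** 2)
    return ke + pe + el


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def saturate_torques(torques, params: PlantParams) -> np.ndarray:
    """Elementwise clamp of commanded torques to +/- torque_limit."""
    return np.clip(np.asarray(torques, dtype=float),
                   -params.torque_limit, params.torque_limit)


def _rk4(q, qd, tau, params: PlantParams, dt: float):
    def deriv(q_, qd_):
        return qd_, _accelerations(q_, qd_, tau, params)

    k1q, k1v = deriv(q, qd)
    k2q, k2v = deriv(q + 0.5 * dt * k1q, qd + 0.5 * dt * k1v)
    k3q, k3v = deriv(q + 0.5 * dt * k2q, qd + 0.5 * dt * k2v)
    k4q, k4v = deriv(q + dt * k3q, qd + dt * k3v)
    qn = q + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
    qdn = qd + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return qn, qdn


def _apply_joint_limits(q, qd, params: PlantParams):
    """Soft clamp: angle pinned at the bound with velocity zeroed there."""
    hit = np.zeros(q.shape[:-1], dtype=bool)
    for j, (lo, hi) in enumerate((params.ankle_angle_range, params.hip_angle_range)):
        below, above = q[..., j] < lo, q[..., j] > hi
        q[..., j] = np.clip(q[..., j], lo, hi)
        qd[..., j] = np.where(below | above, 0.0, qd[..., j])
        hit |= below | above
    return q, qd, hit


def step_dynamics(state: PlantState, active_torques, params: PlantParams,
                  dt: float) -> Tuple[PlantState, MechanicsOutput]:
    """Advance the plant one physics step of size ``dt`` (RK4).

    Commanded torques are saturated to ``+/- torque_limit`` before use;
    joint limits are enforced by clamping with velocity zeroing.
    """
    if not (0.0 < dt <= 0.05):
        raise ValueError("dt must be in (0, 0.05] s")
    tau = saturate_torques(active_torques, params)
    if not np.all(np.isfinite(tau)):
        raise ValueError("active torques must be finite")
    q = np.array([state.theta_ankle, state.theta_hip], dtype=float)
    qd = np.array([state.omega_ankle, state.omega_hip], dtype=float)
    qn, qdn = _rk4(q, qd, tau, params, dt)
    if not (np.all(np.isfinite(qn)) and np.all(np.isfinite(qdn))):
        raise IntegrationError(
            f"non-finite state after step at t={state.time:.6f} s (dt={dt})")
    qn, qdn, hit = _apply_joint_limits(qn, qdn, params)
    new = PlantState(theta_ankle=float(qn[0]), theta_hip=float(qn[1]),
                     omega_ankle=float(qdn[0]), omega_hip=float(qdn[1]),
                     time=state.time + dt)
    qdd = _accelerations(qn, qdn, tau, params)
    mech = forward_kinematics(new, params)
    # non-strict: a toppling plant can momentarily unload the foot, which is
    # logged as NaN CoP rather than aborting the episode
    mech.cop_x = float(_cop_from_arrays(qn[None, :], qdn[None, :], qdd[None, :],
                                        params, strict=False)[0])
    mech.ankle_torque_applied = float(tau[0])
    mech.hip_torque_applied = float(tau[1])
    mech.limits_hit = bool(hit)
    return new, mech
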