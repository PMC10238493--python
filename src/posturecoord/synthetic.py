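"""Synthetic joint-angle fixtures with prescribed coordination structure.

These generators emulate hip/ankle angle traces (frequency, amplitudes,
peak lag, additive Gaussian noise) so the metrics and experiment plumbing
can be exercised without any training run.  The logs use the same column
dialect as real episode logs; head position is computed through the plant's
forward kinematics so fixtures stay geometrically consistent.  Torque
channels are passive-stiffness proxies (-k * theta), clearly non-dynamic:
they exist so energy-metric code paths have aligned torque/velocity series,
not to satisfy the equations of motion.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import plant as _plant
from .plant import PlantParams
from .task import LOG_COLUMNS, TrajectoryLog

__all__ = ["FixtureSpec", "gen_coordination_pair", "gen_mode_switch_series"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic hip/ankle coordination trace."""

    frequency: float = 0.4          # Hz (chirp start frequency if chirp_rate > 0)
    chirp_rate: float = 0.0         # Hz/s
    ankle_amplitude: float = 0.05   # rad
    hip_amplitude: float = 0.08     # rad
    lag: float = 0.0                # s, hip peak minus ankle peak
    noise_sigma: float = 0.0        # fraction of each amplitude
    duration: float = 25.0          # s
    sample_rate: float = 60.0       # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chirp_rate == 0.0 and self.duration * self.frequency < 5:
            raise ValueError("phase fixtures need at least 5 cycles")
        if not (0.0 <= self.noise_sigma < 0.2):
            raise ValueError("noise_sigma must lie in [0, 0.2)")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("duration and sample_rate must be positive")


def _assemble_log(t: np.ndarray, ankle: np.ndarray, hip: np.ndarray,
                  spec: FixtureSpec, params: PlantParams) -> TrajectoryLog:
    dt = 1.0 / spec.sample_rate
    om_a = np.gradient(ankle, dt)
    om_h = np.gradient(hip, dt)
    tau_a = -params.ankle_stiffness * ankle       # stiffness proxy, non-dynamic
    tau_h = -params.hip_stiffness * hip
    head_x, _ = _plant.head_position(ankle, hip, params)
    head_vx = _plant.head_velocity_x(ankle, hip, om_a, om_h, params)
    com_x = ((params.leg_mass * params.leg_com_distance * np.sin(ankle)
              + params.upper_mass * (params.leg_length * np.sin(ankle)
                                     + params.trunk_com_distance * np.sin(ankle + hip)))
             / (params.leg_mass + params.upper_mass))
    df = pd.DataFrame({
        "time": t, "theta_ankle": ankle, "theta_hip": hip,
        "omega_ankle": om_a, "omega_hip": om_h,
        "torque_ankle": tau_a, "torque_hip": tau_h,
        "head_x": head_x, "head_vx": head_vx,
        "target_x": head_x,          # fixtures track their own head perfectly
        "cop_x": com_x,              # static limit
        "r_stay": 1.0, "r_target": 1.0, "r_energy": 0.0, "r_torque": 0.0,
        "r_total": 0.0, "fallen": False,
    }, columns=list(LOG_COLUMNS))
    return TrajectoryLog(data=df, meta={"fixture": asdict(spec), "synthetic": True})


def gen_coordination_pair(spec: FixtureSpec,
                          params: Optional[PlantParams] = None) -> TrajectoryLog:
    """Sinusoidal ankle/hip pair with a prescribed peak lag.

    ankle = a sin(2 pi f t) + noise, hip = b sin(2 pi f (t - lag)) + noise,
    so the hip peaks trail the ankle peaks by exactly ``lag`` seconds in the
    noise-free limit.  Identical seeds yield identical logs.
    """
    if params is None:
        params = _plant.default_params()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, 1.0 / spec.sample_rate)
    w = 2.0 * np.pi * spec.frequency
    ankle = spec.ankle_amplitude * np.sin(w * t)
    hip = spec.hip_amplitude * np.sin(w * (t - spec.lag))
    if spec.noise_sigma > 0:
        ankle = ankle + rng.normal(0, spec.noise_sigma * spec.ankle_amplitude, t.shape)
        hip = hip + rng.normal(0, spec.noise_sigma * spec.hip_amplitude, t.shape)
    return _assemble_log(t, ankle, hip, spec, params)


def gen_mode_switch_series(f_start: float, rate: float, flip_frequency: float,
                           spec: FixtureSpec,
                           params: Optional[PlantParams] = None) -> TrajectoryLog:
    """Chirp fixture whose hip-ankle lag flips from in-phase to anti-phase.

    The instantaneous frequency grows linearly, f(t) = f_start + rate * t;
    while it is below ``flip_frequency`` the hip tracks the ankle in phase,
    afterwards it is offset by half the instantaneous period (anti-phase).
    Emulates a transition episode for testing transition detection.
    """
    if rate < 0:
        raise ValueError("chirp rate must be non-negative")
    if params is None:
        params = _plant.default_params()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, 1.0 / spec.sample_rate)
    phase = 2.0 * np.pi * (f_start * t + 0.5 * rate * t ** 2)
    f_inst = f_start + rate * t
    ankle = spec.ankle_amplitude * np.sin(phase)
    hip_phase = np.where(f_inst < flip_frequency, phase, phase + np.pi)
    hip = spec.hip_amplitude * np.sin(hip_phase)
    if spec.noise_sigma > 0:
        ankle = ankle + rng.normal(0, spec.noise_sigma * spec.ankle_amplitude, t.shape)
        hip = hip + rng.normal(0, spec.noise_sigma * spec.hip_amplitude, t.shape)
    fixture = FixtureSpec(frequency=f_start, chirp_rate=rate,
                          ankle_amplitude=spec.ankle_amplitude,
                          hip_amplitude=spec.hip_amplitude, lag=spec.lag,
                          noise_sigma=spec.noise_sigma, duration=spec.duration,
                          sample_rate=spec.sample_rate, seed=spec.seed)
    log = _assemble_log(t, ankle, hip, fixture, params)
    log.meta["flip_frequency"] = float(flip_frequency)
    return log
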