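"""Coordination-analysis layer: correlation, relative phase, amplitudes,
energy cost, CoP statistics and mode-transition detection.

In-phase vs anti-phase hip-ankle coordination is read from the sign of the
Pearson correlation between the two joint-angle series; the relative phase
is computed per target cycle from the peak-time offset as |t0 - t1| * f * pi
(the printed convention; the conventional 2*pi*f*|dt| lag is reported
alongside).  A sliding-window correlation against a time-varying target
frequency locates the in-phase -> anti-phase transition frequency as the
first zero crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
from scipy import stats

from .task import TaskSpec, TrajectoryLog

__all__ = [
    "CoordinationSummary",
    "DegenerateSeriesError",
    "pearson_correlation",
    "cycle_peaks",
    "relative_phase",
    "energy_cost",
    "summarize_episode",
    "windowed_correlation",
    "transition_frequency",
    "NoTransition",
    "MODE_CORRELATION_THRESHOLD",
]

#: |r| dead-band below which the coordination mode is labeled ambiguous
MODE_CORRELATION_THRESHOLD = 0.1


class DegenerateSeriesError(ValueError):
    """Raised for constant or too-short input series."""


@dataclass
class CoordinationSummary:
    """Evaluation indices for one episode (Tables-3/4-style row)."""

    hip_ankle_correlation: float
    relative_phase: float               # rad, |t0-t1|*f*pi convention
    relative_phase_conventional: float  # rad, 2*pi*f*|t0-t1|
    mode_label: str                     # in_phase | anti_phase | ambiguous
    peak_to_peak_ankle: float
    peak_to_peak_hip: float
    torque_amplitude_ankle: float
    torque_amplitude_hip: float
    target_head_correlation_r: float
    head_amplitude: float
    mean_head_velocity: float
    energy_cost: float
    cop_quartiles: Tuple[float, float, float, float, float]

    def as_row(self) -> dict:
        d = asdict(self)
        q = d.pop("cop_quartiles")
        for name, val in zip(("cop_min", "cop_q1", "cop_median", "cop_q3", "cop_max"), q):
            d[name] = val
        return d


def pearson_correlation(x, y) -> float:
    """Pearson r; raises DegenerateSeriesError instead of returning NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise DegenerateSeriesError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSeriesError("constant series has undefined correlation")
    return float(stats.pearsonr(x, y).statistic)


def cycle_peaks(series, times, f: float, flat_tol: float = 1e-9):
    """One refined argmax time per target cycle [k/f, (k+1)/f).

    The series is first low-pass smoothed (Hann kernel, ~0.2 cycles wide)
    so measurement noise near the flat crest does not displace the argmax;
    the peak time is then refined by a least-squares parabola fitted over
    ~0.25 cycles around the crest.  Cycles whose within-cycle range is
    below ``flat_tol`` times the overall series range are skipped; returns
    (peak_times, n_skipped).
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if f <= 0:
        raise ValueError("frequency must be positive")
    period = 1.0 / f
    span = t[-1] - t[0]
    if span < 2 * period:
        raise ValueError("series must span at least two target periods")
    dt_s = float(np.median(np.diff(t)))
    width = int(round(0.2 * period / dt_s))
    if width >= 3:
        kern = np.hanning(width + 2)[1:-1]
        kern /= kern.sum()
        ys = np.convolve(y, kern, mode="same")
    else:
        ys = y
    overall = np.ptp(y)
    half_fit = max(1, int(round(0.125 * period / dt_s)))
    peaks = []
    skipped = 0
    k0 = int(np.floor(t[0] / period))
    k1 = int(np.ceil(t[-1] / period))
    for k in range(k0, k1):
        mask = (t >= k * period) & (t < (k + 1) * period)
        idx = np.flatnonzero(mask)
        if len(idx) < 3:
            continue
        if np.ptp(y[idx]) < flat_tol * max(overall, 1e-300):
            skipped += 1
            continue
        j = idx[np.argmax(ys[idx])]
        lo, hi = max(j - half_fit, 0), min(j + half_fit + 1, len(ys))
        if hi - lo >= 5:
            tt = t[lo:hi] - t[j]
            c2, c1, _ = np.polyfit(tt, ys[lo:hi], 2)
            if c2 < 0:
                delta = -c1 / (2.0 * c2)
                peaks.append(t[j] + float(np.clip(delta, -0.25 * period,
                                                  0.25 * period)))
                continue
        peaks.append(t[j])
    return np.asarray(peaks), skipped


def relative_phase(t0, t1, f: float) -> float:
    """Relative phase |t0 - t1| * f * pi (rad) from per-cycle peak times."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return float(abs(np.asarray(t0) - np.asarray(t1)) * f * np.pi)


def conventional_phase_lag(t0, t1, f: float) -> float:
    """Phase lag 2*pi*f*|t0 - t1| (rad), the textbook convention."""
    return 2.0 * relative_phase(t0, t1, f)


def energy_cost(torques, omegas, dt: float) -> float:
    """Cumulative mechanical work magnitude sum_t sum_j |tau_j w_j| dt (J)."""
    tau = np.asarray(torques, dtype=float)
    om = np.asarray(omegas, dtype=float)
    if tau.shape != om.shape:
        raise ValueError("torque and velocity series must be aligned")
    return float(np.sum(np.abs(tau * om)) * dt)


def _paired_cycle_lag(t_ankle: np.ndarray, t_hip: np.ndarray, period: float):
    """Match per-cycle peak times by cycle index and return |dt| per cycle."""
    ka = np.floor(t_ankle / period).astype(int)
    kh = np.floor(t_hip / period).astype(int)
    lags = []
    hip_by_cycle = dict(zip(kh, t_hip))
    for k, ta in zip(ka, t_ankle):
        th = hip_by_cycle.get(k)
        if th is not None:
            lags.append(abs(ta - th))
    return np.asarray(lags)


def _per_cycle_half_range(y: np.ndarray, t: np.ndarray, period: float) -> float:
    """Mean per-cycle oscillation amplitude (half range equivalent).

    Estimated from the fundamental Fourier component of each cycle rather
    than the raw max-min: the raw range has an extreme-value noise bias
    (a 5% additive noise inflates it by ~7%), while the fundamental
    amplitude equals the half range exactly for sinusoidal cycles and is
    noise-robust.
    """
    k0, k1 = int(np.floor(t[0] / period)), int(np.ceil(t[-1] / period))
    w = 2.0 * np.pi / period
    vals = []
    for k in range(k0, k1):
        mask = (t >= k * period) & (t < (k + 1) * period)
        if mask.sum() >= 8:
            seg = y[mask] - np.mean(y[mask])
            ph = np.exp(-1j * w * t[mask])
            vals.append(2.0 * np.abs(np.mean(seg * ph)))
    return float(np.mean(vals)) if vals else float("nan")


def summarize_episode(log: TrajectoryLog, spec: TaskSpec,
                      discard_periods: int = 2) -> CoordinationSummary:
    """Aggregate one evaluation episode into a CoordinationSummary.

    The first ``discard_periods`` target periods are dropped as transient.
    Requires at least five target periods of fall-free data.
    """
    df = log.data
    f = spec.frequency_f
    if f <= 0:
        raise ValueError("summarize_episode requires a fixed positive frequency")
    period = 1.0 / f
    if df["fallen"].any():
        t_fall = float(df.loc[df["fallen"], "time"].iloc[0])
        raise ValueError(
            f"fall at t={t_fall:.2f} s inside the analysis window; "
            "shorten the window or evaluate a converged policy")
    t = df["time"].to_numpy()
    if t[-1] - t[0] < 5 * period:
        raise ValueError("log must cover at least five target periods")
    keep = t >= t[0] + discard_periods * period
    d = df.loc[keep]
    t = d["time"].to_numpy()
    ankle = d["theta_ankle"].to_numpy()
    hip = d["theta_hip"].to_numpy()
    dt = float(np.median(np.diff(t)))

    r = pearson_correlation(ankle, hip)
    if r > MODE_CORRELATION_THRESHOLD:
        mode = "in_phase"
    elif r < -MODE_CORRELATION_THRESHOLD:
        mode = "anti_phase"
    else:
        mode = "ambiguous"

    pk_a, _ = cycle_peaks(ankle, t, f)
    pk_h, _ = cycle_peaks(hip, t, f)
    lags = _paired_cycle_lag(pk_a, pk_h, period)
    mean_lag = float(np.mean(lags)) if len(lags) else float("nan")
    rel = relative_phase(mean_lag, 0.0, f) if np.isfinite(mean_lag) else float("nan")

    tau_a = d["torque_ankle"].to_numpy()
    tau_h = d["torque_hip"].to_numpy()
    om = d[["omega_ankle", "omega_hip"]].to_numpy()
    head = d["head_x"].to_numpy()
    cop = d["cop_x"].to_numpy()
    return CoordinationSummary(
        hip_ankle_correlation=r,
        relative_phase=rel,
        relative_phase_conventional=2.0 * rel if np.isfinite(rel) else rel,
        mode_label=mode,
        peak_to_peak_ankle=2.0 * _per_cycle_half_range(ankle, t, period),
        peak_to_peak_hip=2.0 * _per_cycle_half_range(hip, t, period),
        torque_amplitude_ankle=_per_cycle_half_range(tau_a, t, period),
        torque_amplitude_hip=_per_cycle_half_range(tau_h, t, period),
        target_head_correlation_r=pearson_correlation(d["target_x"].to_numpy(), head),
        head_amplitude=_per_cycle_half_range(head, t, period),
        mean_head_velocity=float(np.mean(np.abs(d["head_vx"].to_numpy()))),
        energy_cost=energy_cost(np.stack([tau_a, tau_h], axis=-1), om, dt),
        cop_quartiles=tuple(float(v) for v in
                            np.percentile(cop, [0, 25, 50, 75, 100])),
    )


def windowed_correlation(ankle, hip, times, window: int, stride: int = 1):
    """Sliding-window Pearson r with window-center timestamps.

    Constant windows yield NaN-flagged entries (reported, not silently
    dropped).  Returns (centers, correlations).
    """
    a = np.asarray(ankle, dtype=float)
    h = np.asarray(hip, dtype=float)
    t = np.asarray(times, dtype=float)
    if window < 10:
        raise ValueError("window must be at least 10 samples")
    if len(a) < window:
        raise ValueError("series shorter than the window")
    centers, rs = [], []
    for start in range(0, len(a) - window + 1, stride):
        sl = slice(start, start + window)
        centers.append(0.5 * (t[sl][0] + t[sl][-1]))
        try:
            rs.append(pearson_correlation(a[sl], h[sl]))
        except DegenerateSeriesError:
            rs.append(float("nan"))
    return np.asarray(centers), np.asarray(rs)


class NoTransition:
    """Sentinel result: the windowed correlation never changes sign."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NoTransition()"

    def __eq__(self, other) -> bool:
        return isinstance(other, NoTransition)

    def __hash__(self) -> int:
        return hash("NoTransition")


def transition_frequency(correlations, frequencies):
    """Frequency of the first + -> - zero crossing of the correlation series.

    Linearly interpolates between the bracketing windows; returns
    :class:`NoTransition` when no sign change occurs.
    """
    r = np.asarray(correlations, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if r.shape != f.shape:
        raise ValueError("correlation and frequency series must be aligned")
    valid = np.isfinite(r)
    r, f = r[valid], f[valid]
    for i in range(len(r) - 1):
        if r[i] > 0 and r[i + 1] <= 0:
            w = r[i] / (r[i] - r[i + 1])
            return float(f[i] + w * (f[i + 1] - f[i]))
    return NoTransition()
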