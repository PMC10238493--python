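"""Configuration-driven sweeps reproducing the four study conditions.

Each sweep varies one factor — target frequency, energy-penalty weight
gamma, hip stiffness, or added upper-body mass — trains (or reuses) a
policy per condition, evaluates a long fall-free episode and summarizes it
into one tidy row per (condition, seed).  The added-mass sweep is a
transfer test: it evaluates a single multi-frequency policy without any
retraining.  A chirp evaluation sweeps the target frequency continuously
within one episode and locates the in-phase -> anti-phase transition
frequency from the windowed hip-ankle correlation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import plant as _plant
from . import ppo as _ppo
from . import metrics as _metrics
from .plant import PlantParams
from .task import (TaskSpec, RewardWeights, TrackingEnv, TrajectoryLog,
                   run_episode, CONTROL_DT)

__all__ = ["SweepSpec", "PRESETS", "run_sweep", "run_chirp_eval",
           "train_condition", "train_multifrequency", "make_report"]

#: the fixed study conditions, verbatim
PRESETS = {
    "frequency": [round(0.15 * k, 2) for k in range(1, 11)],        # 0.15 .. 1.50
    "gamma": [0, 5, 10, 15, 20, 25, 30, 35, 40],
    "hip_stiffness": [25, 50, 75, 100, 125, 150, 175, 200],
    "added_mass": [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0],
    "grid_stiffness": [25, 50, 75, 100, 125, 150, 175, 200],
    "grid_frequency": [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5],
}

#: per-variable fixed task settings from the study design
SWEEP_TASK_DEFAULTS = {
    "frequency": dict(gamma=20.0),
    "gamma": dict(frequency=0.4),
    "hip_stiffness": dict(frequency=0.5, gamma=20.0),
    "added_mass": dict(frequency=0.4, gamma=20.0),
    "grid": dict(gamma=20.0),
}

EVAL_DURATION = 100.0      # s, evaluation-episode length at full scale


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: the varied factor, its values, seeds and scale profile."""

    variable: str                      # frequency | gamma | hip_stiffness | added_mass | grid
    values: Sequence = ()
    seeds: Sequence[int] = (0, 1, 2)
    profile: str = "desk"              # desk | paper
    eval_duration: float = EVAL_DURATION
    ppo_overrides: dict = field(default_factory=dict)
    checkpoint: Optional[str] = None   # multi-frequency checkpoint (added_mass)

    def __post_init__(self) -> None:
        if self.variable not in ("frequency", "gamma", "hip_stiffness",
                                 "added_mass", "grid"):
            raise ValueError(f"unknown sweep variable {self.variable!r}")
        if len(self.values) == 0:
            raise ValueError("sweep values list must not be empty")

    @classmethod
    def preset(cls, variable: str, **kw) -> "SweepSpec":
        if variable == "grid":
            values = [(s, f) for s in PRESETS["grid_stiffness"]
                      for f in PRESETS["grid_frequency"]]
        else:
            values = PRESETS[variable]
        return cls(variable=variable, values=values, **kw)


def exploration_std(frequency: float) -> float:
    """Initial policy noise scale for a condition at ``frequency`` Hz.

    The torque modulation a tracking policy needs grows with the target's
    acceleration demand, so the initial exploration noise scales linearly
    with target frequency (clipped to [0.15, 0.3] of the torque limit).
    """
    return float(np.clip(0.2 + 0.05 * (frequency - 0.2), 0.15, 0.3))


def _ppo_config(profile: str, seed: int, frequency: Optional[float] = None,
                **overrides) -> _ppo.PolicyConfig:
    if profile == "paper":
        return _ppo.paper_profile(seed=seed, **overrides)
    if profile == "desk":
        if frequency is not None and "action_std_init" not in overrides:
            overrides["action_std_init"] = exploration_std(frequency)
        return _ppo.desk_profile(seed=seed, **overrides)
    raise ValueError(f"unknown profile {profile!r}")


def train_condition(params: PlantParams, spec: TaskSpec, weights: RewardWeights,
                    config: _ppo.PolicyConfig,
                    frequency_choices: Optional[Sequence[float]] = None,
                    checkpoint_path=None, selection_duration: float = 15.0):
    """Train one policy for one condition; returns (agent, history).

    Snapshot selection during training scores candidate policies with a
    short deterministic evaluation episode (falls are heavily penalized by
    the episode truncating), so the returned policy is the best balancer-
    tracker seen, not whatever the final update produced.
    """
    def factory():
        return TrackingEnv(params, spec, weights, n_envs=config.n_envs,
                           seed=config.seed, frequency_choices=frequency_choices)

    eval_freqs = list(frequency_choices) if frequency_choices is not None \
        else [spec.frequency_f]
    sel_freqs = ([min(eval_freqs), max(eval_freqs)] if len(eval_freqs) > 1
                 else eval_freqs)

    def eval_score(agent: _ppo.PPOAgent) -> float:
        """Deterministic vectorized evaluation: a few phase-aligned episodes
        per frequency; any fall disqualifies the snapshot."""
        total = 0.0
        for f in sel_freqs:
            sp = replace(spec, frequency_f=f, episode_duration=selection_duration)
            env = TrackingEnv(params, sp, weights, n_envs=4, seed=config.seed + 7,
                              random_target_phase=False, init_angle_std=0.01,
                              init_omega_std=0.0)
            obs = env.reset()
            n_steps = int(round(selection_duration / CONTROL_DT))
            for _ in range(n_steps):
                act = np.clip(agent.mean_action(obs), -1.0, 1.0)
                obs, reward, terminated, _, _ = env.step(act)
                total += float(reward.sum())
                if np.any(terminated):
                    total -= 1e6
        return total

    return _ppo.train(factory, config, checkpoint_path=checkpoint_path,
                      eval_fn=eval_score)


def train_multifrequency(params: PlantParams, weights: RewardWeights,
                         config: _ppo.PolicyConfig,
                         frequencies: Optional[Sequence[float]] = None,
                         amplitude: float = 0.1, episode_duration: float = 20.0,
                         checkpoint_path=None):
    """Train one policy with per-episode frequency sampled from the fixed
    frequency set (the transfer-learning curriculum)."""
    if frequencies is None:
        frequencies = PRESETS["frequency"]
    spec = TaskSpec(amplitude_A=amplitude, frequency_f=float(frequencies[0]),
                    episode_duration=episode_duration)
    return train_condition(params, spec, weights, config,
                           frequency_choices=frequencies,
                           checkpoint_path=checkpoint_path)


def _condition_hash(variable: str, value, seed: int, profile: str,
                    overrides: dict) -> str:
    key = json.dumps([variable, value, seed, profile,
                      sorted(overrides.items())], default=str)
    return hashlib.sha256(key.encode()).hexdigest()[:12]


def evaluate_policy(agent: _ppo.PPOAgent, params: PlantParams, spec: TaskSpec,
                    weights: RewardWeights, seed: int,
                    duration: float) -> TrajectoryLog:
    eval_spec = replace(spec, episode_duration=duration)
    policy = agent.torque_policy(params.torque_limit, deterministic=True)
    return run_episode(policy, eval_spec, params, weights, seed=seed,
                       init_angle_std=0.005)


def run_sweep(sweep: SweepSpec, out_dir=None, base_params: Optional[PlantParams] = None,
              amplitude: float = 0.1, episode_duration: float = 20.0,
              progress: bool = False) -> pd.DataFrame:
    """Run a full sweep; one row per (condition value, seed).

    Rows already present in ``out_dir/results.csv`` (matched by condition
    hash) are skipped, making interrupted sweeps resumable.  Training
    failures mark the row ``status='failed'`` and the sweep continues.
    """
    if base_params is None:
        base_params = _plant.default_params()
    out_path = None
    done_hashes = set()
    existing = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "results.csv"
        if out_path.exists():
            existing = pd.read_csv(out_path)
            done_hashes = set(existing["condition_hash"])

    multi_agent = None
    if sweep.variable == "added_mass":
        if sweep.checkpoint is None:
            raise ValueError("added_mass sweep requires a pre-trained "
                             "multi-frequency checkpoint (transfer, no retraining)")
        multi_agent = _ppo.PPOAgent.load(sweep.checkpoint)

    rows = []
    for value in sweep.values:
        for seed in sweep.seeds:
            chash = _condition_hash(sweep.variable, value, seed, sweep.profile,
                                    sweep.ppo_overrides)
            if chash in done_hashes:
                continue
            row = {"variable": sweep.variable, "seed": seed,
                   "condition_hash": chash, "status": "ok"}
            params = base_params
            freq = SWEEP_TASK_DEFAULTS.get(sweep.variable, {}).get("frequency", 0.4)
            gamma = SWEEP_TASK_DEFAULTS.get(sweep.variable, {}).get("gamma", 20.0)
            if sweep.variable == "frequency":
                freq = float(value)
                row["frequency"] = freq
            elif sweep.variable == "gamma":
                gamma = float(value)
                row["gamma"] = gamma
            elif sweep.variable == "hip_stiffness":
                params = base_params.with_stiffness(hip=float(value))
                row["hip_stiffness"] = float(value)
            elif sweep.variable == "added_mass":
                params = base_params.with_added_mass(float(value))
                row["added_mass"] = float(value)
            elif sweep.variable == "grid":
                stiff, freq = value
                params = base_params.with_stiffness(hip=float(stiff))
                row["hip_stiffness"] = float(stiff)
                row["frequency"] = float(freq)
            spec = TaskSpec(amplitude_A=amplitude, frequency_f=freq,
                            episode_duration=episode_duration)
            weights = RewardWeights(gamma=gamma)
            try:
                if multi_agent is not None:
                    agent, history = multi_agent, None
                else:
                    cfg = _ppo_config(sweep.profile, seed, frequency=freq,
                                      **sweep.ppo_overrides)
                    agent, history = train_condition(params, spec, weights, cfg)
                    row["final_mean_reward"] = float(history["mean_reward"].iloc[-1])
                    row["train_steps"] = int(history["steps"].iloc[-1])
                log = evaluate_policy(agent, params, spec, weights, seed=seed,
                                      duration=sweep.eval_duration)
                summary = _metrics.summarize_episode(log, spec)
                row.update(summary.as_row())
            except Exception as exc:  # noqa: BLE001 - recorded, sweep continues
                row["status"] = "failed"
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            if progress:
                print(f"[{sweep.variable}] value={value} seed={seed} "
                      f"status={row['status']}", flush=True)

    df = pd.DataFrame(rows)
    if existing is not None and len(existing):
        df = pd.concat([existing, df], ignore_index=True)
    if out_path is not None:
        df.to_csv(out_path, index=False)
        (out_dir / "manifest.json").write_text(json.dumps(
            {"sweep": {**asdict(sweep), "values": list(map(str, sweep.values)),
                       "seeds": list(sweep.seeds)}}, indent=2, default=str))
    return df


def run_chirp_eval(agent_or_policy, start_f: float = 0.15, rate: float = 0.036,
                   duration: float = 25.0, window: int = 300,
                   params: Optional[PlantParams] = None,
                   amplitude: float = 0.1, gamma: float = 20.0, seed: int = 0,
                   stride: int = 30, init_angle_std: float = 0.005):
    """One chirp episode: windowed correlation series + transition frequency.

    ``agent_or_policy`` is a PPOAgent (ideally trained on the multi-frequency
    curriculum) or a bare obs->torque callable.  Falls truncate the log; the
    partial correlation series is still returned.
    """
    if params is None:
        params = _plant.default_params()
    spec = TaskSpec(amplitude_A=amplitude, frequency_f=start_f, chirp_rate=rate,
                    episode_duration=duration)
    if isinstance(agent_or_policy, _ppo.PPOAgent):
        policy = agent_or_policy.torque_policy(params.torque_limit, deterministic=True)
    else:
        policy = agent_or_policy
    log = run_episode(policy, spec, params, RewardWeights(gamma=gamma),
                      seed=seed, init_angle_std=init_angle_std)
    d = log.data.loc[~log.data["fallen"]]
    centers, corr = _metrics.windowed_correlation(
        d["theta_ankle"].to_numpy(), d["theta_hip"].to_numpy(),
        d["time"].to_numpy(), window=window, stride=stride)
    freqs = start_f + rate * centers
    result = _metrics.transition_frequency(corr, freqs)
    return {"log": log, "window_centers": centers, "correlations": corr,
            "frequencies": freqs, "transition_frequency": result,
            "fell": log.fell}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def make_report(results: pd.DataFrame, out_dir, kind: Optional[str] = None) -> dict:
    """Render sweep-result tables and figures.

    Writes a tidy CSV always; with >= 2 ok rows also renders the matching
    figure (correlation/relative-phase curves, CoP box summaries, or the
    stiffness x frequency correlation heat map).  Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "variable" not in results.columns:
        raise KeyError("results table lacks the 'variable' column")
    kind = kind or str(results["variable"].iloc[0])
    written = {}
    table_path = out_dir / f"table_{kind}.csv"
    results.to_csv(table_path, index=False)
    written["table"] = table_path

    ok = results[results.get("status", "ok") == "ok"] if "status" in results else results
    if len(ok) < 2:
        written["note"] = "figures skipped: fewer than two successful rows"
        return written

    if kind == "grid":
        need = {"hip_stiffness", "frequency", "hip_ankle_correlation"}
        missing = need - set(ok.columns)
        if missing:
            raise KeyError(f"grid report missing columns: {sorted(missing)}")
        mat = ok.pivot_table(index="hip_stiffness", columns="frequency",
                             values="hip_ankle_correlation")
        fig, ax = plt.subplots(figsize=(7, 4))
        im = ax.imshow(mat.to_numpy(), aspect="auto", origin="lower",
                       cmap="RdBu", vmin=-1, vmax=1,
                       extent=[mat.columns.min(), mat.columns.max(),
                               mat.index.min(), mat.index.max()])
        ax.set_xlabel("target frequency [Hz]")
        ax.set_ylabel("hip stiffness [Nm/rad]")
        fig.colorbar(im, label="hip-ankle correlation")
        fig_path = out_dir / "grid_correlation_heatmap.png"
        fig.savefig(fig_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written["heatmap"] = fig_path
        return written

    xcol = {"frequency": "frequency", "gamma": "gamma",
            "hip_stiffness": "hip_stiffness", "added_mass": "added_mass"}[kind]
    if xcol not in ok.columns:
        raise KeyError(f"report for {kind!r} missing column {xcol!r}")
    agg = ok.groupby(xcol)[["hip_ankle_correlation", "relative_phase"]].mean()
    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.plot(agg.index, agg["hip_ankle_correlation"], "o-", color="tab:blue")
    ax1.axhline(0.0, color="grey", lw=0.5)
    ax1.set_xlabel(xcol)
    ax1.set_ylabel("hip-ankle correlation", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(agg.index, agg["relative_phase"], "s--", color="tab:green")
    ax2.set_ylabel("relative phase [rad]", color="tab:green")
    fig_path = out_dir / f"{kind}_correlation_phase.png"
    fig.savefig(fig_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written["curves"] = fig_path

    cop_cols = ["cop_min", "cop_q1", "cop_median", "cop_q3", "cop_max"]
    if all(c in ok.columns for c in cop_cols):
        cop = ok.groupby(xcol)[cop_cols].mean()
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.fill_between(cop.index, cop["cop_q1"], cop["cop_q3"], alpha=0.4,
                        label="IQR")
        ax.plot(cop.index, cop["cop_median"], "k-", label="median")
        ax.plot(cop.index, cop["cop_min"], "k:", lw=0.7)
        ax.plot(cop.index, cop["cop_max"], "k:", lw=0.7, label="min/max")
        ax.set_xlabel(xcol)
        ax.set_ylabel("CoP x [m from ankle]")
        ax.legend()
        fig_path = out_dir / f"{kind}_cop_box.png"
        fig.savefig(fig_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written["cop"] = fig_path
    return written
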