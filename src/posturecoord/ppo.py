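"""Proximal policy optimization (actor-critic) in pure NumPy.

Two small MLPs (a Gaussian actor with state-independent learned log-std and
a scalar critic) are trained with the clipped-surrogate objective

    L_clip = E_t[ min( w_t A_t, clip(w_t, 1-eps, 1+eps) A_t ) ],
    w_t = pi_theta(a_t|s_t) / pi_theta_old(a_t|s_t),

a squared-error value loss, generalized advantage estimation, and an
adaptive Adam learning rate driven by a KL threshold (halve when the
per-update KL exceeds twice the threshold, grow by 1.5x when it falls below
half of it).  Gradients are hand-derived; the networks are small enough
that a CPU BLAS handles the desk-scale profile in minutes.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PolicyConfig",
    "RolloutBatch",
    "MLP",
    "Adam",
    "PPOAgent",
    "probability_ratio",
    "clipped_surrogate",
    "value_loss",
    "compute_advantages",
    "adapt_learning_rate",
    "train",
]

LOG2PI = float(np.log(2.0 * np.pi))
RATIO_EXPONENT_CLAMP = 30.0     # guards exp overflow in the likelihood ratio

#: fixed per-field scaling applied to observations before the networks
#: (angles rad, angular velocities rad/s, positions m, velocities m/s)
OBS_SCALE = np.array([3.0, 3.0, 0.7, 0.7, 6.0, 1.5, 10.0, 1.2])


@dataclass(frozen=True)
class PolicyConfig:
    """PPO hyper-parameters; defaults mirror the paper-scale profile."""

    hidden_layers: Tuple[int, ...] = (256, 256)
    clip_epsilon: float = 0.2
    kl_threshold: float = 0.002
    n_envs: int = 8192
    horizon: int = 32
    minibatch_size: int = 8192
    ppo_epochs: int = 5
    total_steps: int = 5_000_000
    discount: float = 0.99
    gae_lambda: float = 0.95
    learning_rate: float = 3e-4
    action_std_init: float = 0.4
    entropy_coef: float = 0.0
    normalize_advantages: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_epsilon < 1.0):
            raise ValueError("clip_epsilon must lie in (0, 1)")
        if not (0.0 < self.discount <= 1.0):
            raise ValueError("discount must lie in (0, 1]")
        if not (0.0 <= self.gae_lambda <= 1.0):
            raise ValueError("gae_lambda must lie in [0, 1]")


def desk_profile(**overrides) -> PolicyConfig:
    """CPU-scale profile: fewer environments and steps, narrower networks."""
    base = dict(hidden_layers=(96, 96), n_envs=256, minibatch_size=2048,
                total_steps=3_000_000, action_std_init=0.2)
    base.update(overrides)
    return PolicyConfig(**base)


def paper_profile(**overrides) -> PolicyConfig:
    return PolicyConfig(**overrides)


@dataclass
class RolloutBatch:
    """Flattened experience from one collection phase."""

    observations: np.ndarray     # (B, obs_dim), already scaled
    actions: np.ndarray          # (B, act_dim)
    log_probs_old: np.ndarray    # (B,)
    rewards: np.ndarray          # (B,)
    values: np.ndarray           # (B,)
    advantages: np.ndarray       # (B,)  normalized if configured
    value_targets: np.ndarray    # (B,)  advantages + values, pre-normalization
    terminated: np.ndarray       # (B,) bool episode-boundary flags


# ---------------------------------------------------------------------------
# primitive objectives (unit surface)
# ---------------------------------------------------------------------------

def probability_ratio(logp_new, logp_old) -> np.ndarray:
    """Likelihood ratio pi_new / pi_old from log-densities (overflow-clamped)."""
    diff = np.asarray(logp_new, dtype=float) - np.asarray(logp_old, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("log-probabilities must be finite")
    return np.exp(np.clip(diff, -RATIO_EXPONENT_CLAMP, RATIO_EXPONENT_CLAMP))


def clipped_surrogate(ratio, advantage, clip_epsilon: float) -> np.ndarray:
    """Per-sample clipped objective min(w A, clip(w, 1-eps, 1+eps) A)."""
    if not (0.0 < clip_epsilon < 1.0):
        raise ValueError("clip_epsilon must lie in (0, 1)")
    r = np.asarray(ratio, dtype=float)
    a = np.asarray(advantage, dtype=float)
    return np.minimum(r * a, np.clip(r, 1.0 - clip_epsilon, 1.0 + clip_epsilon) * a)


def value_loss(v_estimate, v_target) -> float:
    """Mean squared error between value estimates and targets."""
    v = np.asarray(v_estimate, dtype=float)
    t = np.asarray(v_target, dtype=float)
    return float(np.mean((v - t) ** 2))


def compute_advantages(rewards, values, next_values, terminated, done,
                       discount: float, gae_lambda: float):
    """Generalized advantage estimation over (T,) or (T, N) sequences.

    ``next_values[t]`` is the bootstrap value of the state following step t
    (pre-reset for truncated tails); ``terminated`` zeroes the bootstrap,
    ``done`` (terminated or truncated) resets the recursion at episode
    boundaries.  Returns (advantages, value_targets).
    """
    r = np.atleast_1d(np.asarray(rewards, dtype=float))
    v = np.atleast_1d(np.asarray(values, dtype=float))
    nv = np.atleast_1d(np.asarray(next_values, dtype=float))
    term = np.atleast_1d(np.asarray(terminated, dtype=bool))
    dn = np.atleast_1d(np.asarray(done, dtype=bool))
    if not (r.shape == v.shape == nv.shape == term.shape == dn.shape):
        raise ValueError("misaligned sequence lengths in advantage computation")
    adv = np.zeros_like(r)
    carry = np.zeros(r.shape[1:], dtype=float)
    for t in range(r.shape[0] - 1, -1, -1):
        delta = r[t] + discount * nv[t] * (~term[t]) - v[t]
        carry = delta + discount * gae_lambda * (~dn[t]) * carry
        adv[t] = carry
    return adv, adv + v


def adapt_learning_rate(lr: float, kl: float, kl_threshold: float,
                        bounds: Tuple[float, float] = (1e-6, 1e-2)) -> float:
    """KL-driven learning-rate rule: halve above 2x threshold, grow 1.5x
    below half of it, clamped to ``bounds``."""
    if kl > 2.0 * kl_threshold:
        lr = lr / 2.0
    elif kl < 0.5 * kl_threshold:
        lr = lr * 1.5
    return float(np.clip(lr, *bounds))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _orthogonal(rng: np.random.Generator, shape, gain: float) -> np.ndarray:
    a = rng.normal(size=shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    if shape[0] < shape[1]:
        q = q.T
    return gain * q[:shape[0], :shape[1]]


class MLP:
    """Tanh MLP with a linear head and hand-written backprop.

    Weights are float32: the networks are the training hot spot and single
    precision is ample for policy/value function approximation.
    """

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator,
                 out_gain: float = 0.01):
        self.sizes = list(sizes)
        self.W = []
        self.b = []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            gain = out_gain if i == len(sizes) - 2 else np.sqrt(2.0)
            self.W.append(_orthogonal(rng, (n_in, n_out), gain).astype(np.float32))
            self.b.append(np.zeros(n_out, dtype=np.float32))
        self._cache = None

    @property
    def params(self) -> List[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        acts = [np.asarray(x, dtype=np.float32)]
        h = acts[0]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.tanh(h)
            acts.append(h)
        if cache:
            self._cache = acts
        return h

    def backward(self, d_out: np.ndarray) -> List[np.ndarray]:
        """Gradients w.r.t. params for the last cached forward pass."""
        acts = self._cache
        if acts is None:
            raise RuntimeError("forward(cache=True) must precede backward()")
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = np.asarray(d_out, dtype=np.float32)
        for i in range(len(self.W) - 1, -1, -1):
            a_in = acts[i]
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - acts[i] ** 2)
        return gW + gb


class Adam:
    """Standard Adam on a flat list of parameter arrays."""

    def __init__(self, params: List[np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# agent
# ---------------------------------------------------------------------------

class PPOAgent:
    """Gaussian actor + critic with save/load and torque-policy export."""

    def __init__(self, obs_dim: int, act_dim: int, config: PolicyConfig,
                 obs_scale: Optional[np.ndarray] = None):
        self.config = config
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        self.obs_scale = (OBS_SCALE[:obs_dim] if obs_scale is None
                          else np.asarray(obs_scale, dtype=float))
        rng = np.random.default_rng(config.seed)
        sizes = [obs_dim, *config.hidden_layers]
        self.actor = MLP(sizes + [act_dim], rng, out_gain=0.01)
        self.critic = MLP(sizes + [1], rng, out_gain=1.0)
        self.log_std = np.full(act_dim, np.log(config.action_std_init))
        # running affine normalization of value targets: the critic head
        # predicts in normalized units so returns of O(10^2-10^3) do not
        # have to be reached through the small-init linear head
        self.v_mean = 0.0
        self.v_std = 1.0

    # -- distributions ----------------------------------------------------
    def _scale(self, obs: np.ndarray) -> np.ndarray:
        return np.asarray(obs, dtype=float) * self.obs_scale

    def mean_action(self, obs: np.ndarray) -> np.ndarray:
        return self.actor.forward(np.atleast_2d(self._scale(obs)))

    def value(self, obs: np.ndarray) -> np.ndarray:
        raw = self.critic.forward(np.atleast_2d(self._scale(obs)))[:, 0]
        return raw * self.v_std + self.v_mean

    def update_value_norm(self, targets: np.ndarray, momentum: float = 0.99) -> None:
        m, s = float(np.mean(targets)), float(np.std(targets) + 1e-6)
        self.v_mean = momentum * self.v_mean + (1.0 - momentum) * m
        self.v_std = momentum * self.v_std + (1.0 - momentum) * s

    def log_prob(self, mean: np.ndarray, actions: np.ndarray) -> np.ndarray:
        std = np.exp(self.log_std)
        z = (actions - mean) / std
        return -0.5 * np.sum(z ** 2 + LOG2PI, axis=-1) - np.sum(self.log_std)

    def sample(self, obs: np.ndarray, rng: np.random.Generator):
        mean = self.mean_action(obs)
        std = np.exp(self.log_std)
        actions = mean + std * rng.normal(size=mean.shape)
        return actions, self.log_prob(mean, actions)

    def torque_policy(self, params_torque_limit: float,
                      deterministic: bool = True,
                      rng: Optional[np.random.Generator] = None) -> Callable:
        """Export an obs -> torque (N·m) callable for episode evaluation."""
        def policy(obs: np.ndarray) -> np.ndarray:
            if deterministic:
                a = self.mean_action(obs)[0]
            else:
                a = self.sample(obs, rng)[0][0]
            return np.clip(a, -1.0, 1.0) * params_torque_limit
        return policy

    # -- snapshots --------------------------------------------------------
    def get_state(self) -> dict:
        """Deep copy of all learnable state (for best-checkpoint tracking)."""
        return {"actor_W": [W.copy() for W in self.actor.W],
                "actor_b": [b.copy() for b in self.actor.b],
                "critic_W": [W.copy() for W in self.critic.W],
                "critic_b": [b.copy() for b in self.critic.b],
                "log_std": self.log_std.copy(),
                "v_mean": self.v_mean, "v_std": self.v_std}

    def set_state(self, state: dict) -> None:
        for i in range(len(self.actor.W)):
            self.actor.W[i][...] = state["actor_W"][i]
            self.actor.b[i][...] = state["actor_b"][i]
            self.critic.W[i][...] = state["critic_W"][i]
            self.critic.b[i][...] = state["critic_b"][i]
        self.log_std[...] = state["log_std"]
        self.v_mean = state["v_mean"]
        self.v_std = state["v_std"]

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write weights (.npz) plus a JSON metadata sidecar."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        arrays = {}
        for tag, net in (("actor", self.actor), ("critic", self.critic)):
            for i, (W, b) in enumerate(zip(net.W, net.b)):
                arrays[f"{tag}_W{i}"] = W
                arrays[f"{tag}_b{i}"] = b
        arrays["log_std"] = self.log_std
        arrays["obs_scale"] = self.obs_scale
        arrays["value_norm"] = np.array([self.v_mean, self.v_std])
        np.savez(path, **arrays)
        meta = {"format_version": 1, "obs_dim": self.obs_dim,
                "act_dim": self.act_dim, "config": asdict(self.config)}
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2, default=list))

    @classmethod
    def load(cls, path) -> "PPOAgent":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        cfg = meta["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        config = PolicyConfig(**cfg)
        agent = cls(meta["obs_dim"], meta["act_dim"], config)
        data = np.load(path)
        for tag, net in (("actor", agent.actor), ("critic", agent.critic)):
            for i in range(len(net.W)):
                net.W[i] = data[f"{tag}_W{i}"]
                net.b[i] = data[f"{tag}_b{i}"]
        agent.log_std = data["log_std"]
        agent.obs_scale = data["obs_scale"]
        if "value_norm" in data:
            agent.v_mean, agent.v_std = (float(x) for x in data["value_norm"])
        return agent


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _collect(env, agent: PPOAgent, obs: np.ndarray, horizon: int,
             rng: np.random.Generator):
    """Roll ``horizon`` control steps across all parallel environments."""
    T, N = horizon, env.n_envs
    O, A = env.obs_dim, env.act_dim
    obs_buf = np.empty((T, N, O))
    act_buf = np.empty((T, N, A))
    logp_buf = np.empty((T, N))
    rew_buf = np.empty((T, N))
    val_buf = np.empty((T, N))
    term_buf = np.empty((T, N), dtype=bool)
    done_buf = np.empty((T, N), dtype=bool)
    final_val = np.zeros((T, N))
    ep_returns: List[float] = []

    for t in range(T):
        obs_buf[t] = obs
        val_buf[t] = agent.value(obs)
        actions, logp = agent.sample(obs, rng)
        act_buf[t] = actions
        logp_buf[t] = logp
        pre_obs = obs
        obs, reward, terminated, truncated, info = env.step(np.clip(actions, -1.0, 1.0))
        rew_buf[t] = reward
        term_buf[t] = terminated
        done = terminated | truncated
        done_buf[t] = done
        if np.any(truncated):
            # bootstrap truncated tails with the value of the pre-reset state
            final_val[t, truncated] = agent.value(info["final_obs"][truncated])
        if "episode_returns" in info:
            ep_returns.extend(info["episode_returns"])
    last_val = agent.value(obs)
    next_val = np.empty((T, N))
    next_val[:-1] = val_buf[1:]
    next_val[-1] = last_val
    next_val = np.where(done_buf, final_val, next_val)
    return (obs_buf, act_buf, logp_buf, rew_buf, val_buf, term_buf, done_buf,
            next_val, obs, ep_returns)


def _update(agent: PPOAgent, batch: RolloutBatch, opt_actor: Adam,
            opt_critic: Adam, config: PolicyConfig,
            rng: np.random.Generator):
    """Run ppo_epochs of minibatched updates; returns diagnostics."""
    B = batch.observations.shape[0]
    mb = min(config.minibatch_size, B)
    kl = 0.0
    clip_frac = 0.0
    n_mb = 0
    first_epoch_ratio_err = 0.0
    for epoch in range(config.ppo_epochs):
        order = rng.permutation(B)
        for start in range(0, B, mb):
            idx = order[start:start + mb]
            obs = batch.observations[idx]
            act = batch.actions[idx]
            adv = batch.advantages[idx]
            logp_old = batch.log_probs_old[idx]
            vt = batch.value_targets[idx]
            n = len(idx)

            # actor forward/backward
            mean = agent.actor.forward(obs, cache=True)
            logp = agent.log_prob(mean, act)
            ratio = probability_ratio(logp, logp_old)
            if epoch == 0 and start == 0:
                # before any update in this round, new policy == old policy
                first_epoch_ratio_err = float(np.max(np.abs(ratio - 1.0)))
            clipped = np.clip(ratio, 1.0 - config.clip_epsilon, 1.0 + config.clip_epsilon)
            use_unclipped = ratio * adv <= clipped * adv
            # d(-mean surr)/d logp = -(1/n) * adv * ratio on the unclipped branch
            dlogp = np.where(use_unclipped, -(adv * ratio) / n, 0.0)
            std = np.exp(agent.log_std)
            z = (act - mean) / std
            d_mean = dlogp[:, None] * (z / std)
            g_actor = agent.actor.backward(d_mean)
            g_logstd = np.sum(dlogp[:, None] * (z ** 2 - 1.0), axis=0)
            if config.entropy_coef > 0.0:
                g_logstd -= config.entropy_coef * np.ones_like(g_logstd)
            opt_actor.step(g_actor + [g_logstd])

            # critic (fit in normalized-value units)
            vt_n = (vt - agent.v_mean) / agent.v_std
            v_n = agent.critic.forward(obs, cache=True)[:, 0]
            d_v = (2.0 * (v_n - vt_n) / n)[:, None]
            g_critic = agent.critic.backward(d_v)
            opt_critic.step(g_critic)
            v = v_n * agent.v_std + agent.v_mean

            kl += float(np.mean(logp_old - logp))
            clip_frac += float(np.mean(np.abs(ratio - 1.0) > config.clip_epsilon))
            n_mb += 1
    return {"kl": kl / n_mb, "clip_fraction": clip_frac / n_mb,
            "value_loss": value_loss(v, vt),
            "first_epoch_ratio_err": first_epoch_ratio_err}


def train(env_factory: Callable[[], object], config: PolicyConfig,
          checkpoint_path=None, diagnostics_path=None,
          eval_fn: Optional[Callable[["PPOAgent"], float]] = None,
          eval_every: int = 20, progress: bool = False):
    """Train PPO on environments from ``env_factory``.

    Returns ``(agent, history)`` where history is a per-update DataFrame of
    diagnostics (mean reward, KL, clip fraction, learning rate).  A fixed
    ``config.seed`` makes the run bit-reproducible on one worker.

    Because PPO on this unstable plant oscillates between good and degraded
    policies, the returned agent is the best snapshot over the run: scored
    by ``eval_fn`` (a deterministic evaluation, higher is better) every
    ``eval_every`` updates when given, otherwise by a smoothed training
    reward penalized by the fall rate.
    """
    env = env_factory()
    rng = np.random.default_rng(config.seed + 1)
    agent = PPOAgent(env.obs_dim, env.act_dim, config)
    # separate optimizer for log_std rides with the actor parameter list
    opt_actor = Adam(agent.actor.params + [agent.log_std], config.learning_rate)
    opt_critic = Adam(agent.critic.params, config.learning_rate)
    lr = config.learning_rate

    obs = env.reset()
    steps_done = 0
    records = []
    update = 0
    # best-snapshot selection: PPO on this task oscillates, so the returned
    # policy is the one with the best smoothed score, not the last update
    score_ema = None
    best_score = -np.inf
    best_state = None
    while steps_done < config.total_steps:
        (obs_b, act_b, logp_b, rew_b, val_b, term_b, done_b, next_v, obs,
         _) = _collect(env, agent, obs, config.horizon, rng)
        adv, vtarget = compute_advantages(rew_b, val_b, next_v, term_b, done_b,
                                          config.discount, config.gae_lambda)
        flat = lambda x: x.reshape(-1, *x.shape[2:])
        adv_f = flat(adv)
        if config.normalize_advantages:
            adv_f = (adv_f - adv_f.mean()) / (adv_f.std() + 1e-8)
        agent.update_value_norm(flat(vtarget))
        batch = RolloutBatch(
            observations=flat(obs_b) * agent.obs_scale,
            actions=flat(act_b), log_probs_old=flat(logp_b),
            rewards=flat(rew_b), values=flat(val_b), advantages=adv_f,
            value_targets=flat(vtarget), terminated=flat(term_b))
        diag = _update(agent, batch, opt_actor, opt_critic, config, rng)
        if not np.isfinite(diag["value_loss"]):
            raise FloatingPointError(
                f"NaN loss at update {update} (steps={steps_done}); "
                f"diagnostics: {diag}")
        lr = adapt_learning_rate(lr, diag["kl"], config.kl_threshold)
        opt_actor.lr = lr
        opt_critic.lr = lr
        steps_done += config.horizon * env.n_envs
        if eval_fn is not None:
            if update >= 10 and update % eval_every == 0:
                score = float(eval_fn(agent))
                if score > best_score:
                    best_score = score
                    best_state = agent.get_state()
            score_ema = None
        else:
            score = float(rew_b.mean()) - 10.0 * float(term_b.mean())
            score_ema = score if score_ema is None else 0.7 * score_ema + 0.3 * score
            if update >= 10 and score_ema > best_score:
                best_score = score_ema
                best_state = agent.get_state()
        records.append({"update": update, "steps": steps_done,
                        "mean_reward": float(rew_b.mean()),
                        "fall_rate": float(term_b.mean()),
                        "score_ema": score_ema,
                        "learning_rate": lr, **diag})
        if progress and update % 10 == 0:
            r = records[-1]
            print(f"update {update:4d} steps {steps_done:8d} "
                  f"mean_r {r['mean_reward']:+.3f} kl {r['kl']:.4f} lr {lr:.2e}",
                  flush=True)
        update += 1

    if eval_fn is not None:
        # the final policy competes with the stored snapshots
        if float(eval_fn(agent)) > best_score:
            best_state = None
    if best_state is not None:
        agent.set_state(best_state)
    history = pd.DataFrame(records)
    if checkpoint_path is not None:
        agent.save(checkpoint_path)
    if diagnostics_path is not None:
        history.to_csv(diagnostics_path, index=False)
    return agent, history
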