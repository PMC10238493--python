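"""Shared fixtures: default morphology and a deterministic 1-D toy task
for exercising the PPO learner without the full standing plant."""

from __future__ import annotations

import numpy as np
import pytest

from posturecoord import default_params


@pytest.fixture(scope="session")
def params():
    """Default standing-model morphology (40.15 kg / 1.57 m / CoM 0.814 m)."""
    return default_params()


class LinearTrackEnv:
    """Deterministic LQR-like scalar plant: x' = a x + b u, reward -x^2 - c u^2.

    Initial states are drawn once per episode from the seeded generator;
    the dynamics themselves are noise-free.  Mirrors the vectorized-env
    interface the PPO trainer expects.
    """

    def __init__(self, n_envs: int = 8, seed: int = 0, horizon: int = 32):
        self.n_envs = n_envs
        self.obs_dim = 1
        self.act_dim = 1
        self.rng = np.random.default_rng(seed)
        self.max_steps = horizon
        self.a, self.b, self.c = 0.95, 0.3, 0.01
        self.x = np.zeros(n_envs)
        self.steps = np.zeros(n_envs, dtype=int)

    def reset(self):
        self.x = self.rng.uniform(-2.0, 2.0, self.n_envs)
        self.steps[:] = 0
        return self.x[:, None].copy()

    def step(self, actions):
        u = np.clip(np.asarray(actions)[:, 0], -1.0, 1.0)
        self.x = self.a * self.x + self.b * u
        self.steps += 1
        reward = -(self.x ** 2) - self.c * u ** 2
        terminated = np.zeros(self.n_envs, dtype=bool)
        truncated = self.steps >= self.max_steps
        info = {"final_obs": self.x[:, None].copy()}
        idx = np.flatnonzero(truncated)
        if len(idx):
            self.x[idx] = self.rng.uniform(-2.0, 2.0, len(idx))
            self.steps[idx] = 0
        return self.x[:, None].copy(), reward, terminated, truncated, info


@pytest.fixture
def toy_env_factory():
    def make(seed: int = 0):
        return lambda: LinearTrackEnv(n_envs=8, seed=seed)
    return make
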