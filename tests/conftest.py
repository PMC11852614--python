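import numpy as np
import pytest

from choicesim.model import PolicyParams
from choicesim.simulator import SimConfig, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trajectory(s, a, n_actions=2, memory_length=20, nw=1):
    """Build a Trajectory from given stimulus/action series (dummy rewards/losses)."""
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=np.int64)
    T = len(s)
    cfg = SimConfig(
        policy=PolicyParams(tuple([1.5, 0.0] * nw), n_actions=n_actions),
        memory_length=memory_length,
        n_steps=T,
    )
    zeros = np.zeros(T)
    return Trajectory(
        config=cfg,
        t=np.arange(T),
        s=s,
        a=a,
        r=zeros.copy(),
        w=np.tile(np.asarray(cfg.policy.weights), (T, 1)),
        loss_a=zeros.copy(),
        loss_r=zeros.copy(),
        loss_lambda=zeros.copy(),
    )


def rule_trajectory(rule, T=300, seed=0, noise=0.0, n_actions=2, memory_length=20):
    """Trajectory whose actions follow ``rule(s)`` with optional label noise."""
    g = np.random.default_rng(seed)
    s = g.normal(0.0, 1.0, T)
    a = np.asarray([rule(x) for x in s], dtype=np.int64)
    if noise > 0:
        flip = g.random(T) < noise
        a[flip] = g.integers(1, n_actions + 1, flip.sum())
    return make_trajectory(s, a, n_actions=n_actions, memory_length=memory_length)
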