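"""Expected losses: choice-consistency surprisal, reward loss, and their mixture.

The consistency loss is the summed surprisal (negative log-probability) of the
remembered actions under a candidate policy; the reward loss is the negative
expected mean reward of the policy over the remembered stimuli.  A scalar
``lambda_`` in [0, 1] trades them off: ``l = lambda*l_r + (1-lambda)*l_a``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .model import EnvParams, PolicyParams

__all__ = [
    "History",
    "LossBreakdown",
    "consistency_loss",
    "reward_loss",
    "reward_loss_prior",
    "compromise_loss",
    "LOSS_SENTINEL",
    "PROB_FLOOR",
]

# Floor on per-action probabilities before taking logs, so that a candidate
# policy that assigns (numerically) zero probability to a remembered action
# yields a huge-but-finite loss the simplex search can retreat from.
PROB_FLOOR = 1e-300
LOSS_SENTINEL = 1e300


@dataclass(frozen=True)
class LossBreakdown:
    """The two component losses and their lambda-mixture."""

    l_a: float
    l_r: float
    l_lambda: float
    lambda_: float


class History:
    """Bounded FIFO of the last ``capacity`` (stimulus, action, reward) triples."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self._entries: deque[tuple[float, int, float]] = deque(maxlen=self.capacity)

    def append(self, s: float, a: int, r: float) -> None:
        self._entries.append((float(s), int(a), float(r)))

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def full(self) -> bool:
        return len(self._entries) == self.capacity

    @property
    def entries(self) -> list[tuple[float, int, float]]:
        return list(self._entries)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self._entries:
            raise ValueError("history is empty")
        s, a, r = zip(*self._entries)
        return (
            np.asarray(s, dtype=float),
            np.asarray(a, dtype=np.int64),
            np.asarray(r, dtype=float),
        )


def _log_pmf_matrix(wvec, sigma_a, n_actions, s):
    """Log action pmf for each remembered stimulus; shape (len(s), Na)."""
    w = np.asarray(wvec, dtype=float)
    means = w[0::2][None, :] + w[1::2][None, :] * s[:, None]  # (T, Nw)
    a = np.arange(1, n_actions + 1, dtype=float)
    z = -((a[None, :, None] - means[:, None, :]) ** 2) / (2.0 * sigma_a**2)
    zmax = z.max(axis=2)
    with np.errstate(invalid="ignore"):  # -inf - -inf when the density overflows
        logmix = zmax + np.log(np.exp(z - zmax[:, :, None]).sum(axis=2))  # (T, Na)
        norm = zmax.max(axis=1)
        logz = norm + np.log(np.exp(logmix - norm[:, None]).sum(axis=1))
    return logmix - logz[:, None]


def _consistency_from_arrays(wvec, sigma_a, n_actions, s, a) -> float:
    logp = _log_pmf_matrix(wvec, sigma_a, n_actions, s)
    picked = logp[np.arange(len(a)), a - 1]
    picked = np.maximum(picked, np.log(PROB_FLOOR))
    if not np.all(np.isfinite(picked)):
        return LOSS_SENTINEL
    out = float(-picked.sum())
    return out if np.isfinite(out) else LOSS_SENTINEL


def _reward_from_arrays(wvec, sigma_a, n_actions, s, weights, env: EnvParams) -> float:
    """Negative weighted expected reward of the policy at stimuli ``s``."""
    logp = _log_pmf_matrix(wvec, sigma_a, n_actions, s)
    p = np.exp(logp)  # (T, Na)
    a = np.arange(1, n_actions + 1, dtype=float)
    if env.reward_form == "bilinear":
        mu = env.alpha * (a[None, :] - env.beta) * s[:, None]
    else:
        mu = env.alpha * a[None, :] + env.beta * s[:, None]
    expected = (p * mu).sum(axis=1)
    if not np.all(np.isfinite(expected)):
        return LOSS_SENTINEL
    return float(-(weights * expected).sum())


_QUAD_NODES = 41


def stimulus_quadrature(sigma_s: float, n_nodes: int = _QUAD_NODES):
    """Gauss-Hermite nodes and weights for expectations under Normal(0, sigma_s^2)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return np.sqrt(2.0) * sigma_s * x, w / np.sqrt(np.pi)


def consistency_loss(params: PolicyParams, history: History) -> float:
    """Summed surprisal of the recorded actions under ``params``.

    ``-sum_j ln p(a_j | s_j, w)`` over the memory window (natural log, sum
    not mean).  A policy that numerically excludes a recorded action returns
    the large finite sentinel rather than raising.
    """
    s, a, _ = history.arrays()
    return _consistency_from_arrays(
        np.asarray(params.weights), params.sigma_a, params.n_actions, s, a
    )


def reward_loss(
    params: PolicyParams,
    history: History,
    env: EnvParams,
    form: str = "prior",
) -> float:
    """Negative Bayes expected reward of the policy.

    Uses the analytic reward mean (the reward model is Normal, so the Bayes
    expected reward given (a, s) is its mean).  ``form`` selects the
    stimulus measure: ``"prior"`` (default) integrates over the stimulus
    distribution Normal(0, sigma_s^2) by Gauss-Hermite quadrature — the
    expectation a Bayes agent that knows the stimulus model would compute —
    while ``"mean"``/``"sum"`` average/sum over the remembered stimuli.
    """
    if form == "prior":
        return reward_loss_prior(params, env)
    if form not in ("mean", "sum"):
        raise ValueError("form must be 'prior', 'mean' or 'sum'")
    s, _, _ = history.arrays()
    weights = np.full(s.size, 1.0 / s.size) if form == "mean" else np.ones(s.size)
    return _reward_from_arrays(
        np.asarray(params.weights), params.sigma_a, params.n_actions, s, weights, env
    )


def reward_loss_prior(params: PolicyParams, env: EnvParams, n_nodes: int = _QUAD_NODES) -> float:
    """Negative expected reward of the policy under the stimulus prior.

    -E_s[sum_a p(a|s,w) mu(a,s)] with s ~ Normal(0, sigma_s^2).  Constant
    (stimulus-blind) policies score exactly zero here, since the reward mean
    is odd in s, so only genuinely discriminating policies are rewarded.
    """
    nodes, weights = stimulus_quadrature(env.sigma_s, n_nodes)
    return _reward_from_arrays(
        np.asarray(params.weights), params.sigma_a, params.n_actions, nodes, weights, env
    )


def sampled_reward_loss(params: PolicyParams, history: History, form: str = "mean") -> float:
    """Reward loss using the recorded (sampled) rewards instead of the analytic mean.

    Weighs each remembered reward by the candidate policy's probability of
    the action that earned it.
    """
    s, a, r = history.arrays()
    logp = _log_pmf_matrix(
        np.asarray(params.weights), params.sigma_a, params.n_actions, s
    )
    p = np.exp(logp[np.arange(len(a)), a - 1])
    weighted = p * r
    return float(-weighted.mean() if form == "mean" else -weighted.sum())


def compromise_loss(
    params: PolicyParams,
    history: History,
    env: EnvParams,
    lambda_: float,
    reward_form: str = "prior",
) -> LossBreakdown:
    """Lambda-mixture of reward and consistency losses.

    ``l_lambda = lambda*l_r + (1-lambda)*l_a`` with ``0 <= lambda <= 1``.
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda_ must lie in [0, 1]")
    l_a = consistency_loss(params, history)
    l_r = reward_loss(params, history, env, form=reward_form)
    return LossBreakdown(
        l_a=l_a,
        l_r=l_r,
        l_lambda=lambda_ * l_r + (1.0 - lambda_) * l_a,
        lambda_=lambda_,
    )
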