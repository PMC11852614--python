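"""Generative model: stimulus distribution, mixture action policy, reward model.

The agent faces a one-dimensional Gaussian stimulus and a discrete action set
``{1, ..., Na}``.  The policy is a mixture of ``Nw`` Gaussians whose means
depend linearly on the stimulus; the mixture density is evaluated at the
integer action locations and renormalized to give a proper probability mass
function over actions.  Rewards are Gaussian around a mean that couples action
and stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolicyParams",
    "EnvParams",
    "PolicyCollapseError",
    "component_means",
    "action_pmf",
    "sample_stimulus",
    "sample_action",
    "reward_mean",
    "sample_reward",
]


class PolicyCollapseError(FloatingPointError):
    """Raised when the mixture density underflows at every action location.

    In that regime the conditional action distribution is 0/0 and no choice
    can be sampled; callers that optimize over weights catch this and treat
    the candidate as maximally costly instead.
    """


@dataclass(frozen=True)
class PolicyParams:
    """Parametric stimulus-to-action policy.

    Parameters
    ----------
    weights
        Flat vector ``[w_1^0, w_1^1, ..., w_Nw^0, w_Nw^1]``: intercept and
        slope of each mixture component's mean.
    n_actions
        Number of discrete actions ``Na >= 2``; actions live at the integer
        locations ``1..Na``.
    sigma_a
        Standard deviation of every mixture component (action units).
    """

    weights: tuple[float, ...]
    n_actions: int = 2
    sigma_a: float = 1.0

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if len(w) == 0 or len(w) % 2 != 0:
            raise ValueError("weights must have an even, positive length (intercept, slope per component)")
        if self.n_actions < 2:
            raise ValueError("n_actions must be >= 2")
        if not self.sigma_a > 0:
            raise ValueError("sigma_a must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights) // 2

    @property
    def intercepts(self) -> np.ndarray:
        return np.asarray(self.weights[0::2], dtype=float)

    @property
    def slopes(self) -> np.ndarray:
        return np.asarray(self.weights[1::2], dtype=float)

    def with_weights(self, weights) -> "PolicyParams":
        return PolicyParams(tuple(float(x) for x in weights), self.n_actions, self.sigma_a)


@dataclass(frozen=True)
class EnvParams:
    """Stimulus and reward environment.

    ``sigma_s`` is the stimulus SD (stimuli are zero-mean Normal);
    ``alpha``/``beta`` couple (action, stimulus) to the mean reward and
    ``sigma_r`` is the reward SD.  With the default ``reward_form``
    ``"bilinear"`` the mean reward is ``alpha * (a - beta) * s``, so with
    ``alpha=2, beta=3/2`` action 1 is rewarded for negative stimuli and
    action 2 for positive ones.  ``"additive"`` selects the plain
    ``alpha*a + beta*s`` form instead.
    """

    sigma_s: float = 1.0
    alpha: float = 2.0
    beta: float = 1.5
    sigma_r: float = 1.0
    reward_form: str = "bilinear"

    def __post_init__(self) -> None:
        if not self.sigma_s > 0:
            raise ValueError("sigma_s must be positive")
        if not self.sigma_r > 0:
            raise ValueError("sigma_r must be positive")
        if self.reward_form not in ("bilinear", "additive"):
            raise ValueError("reward_form must be 'bilinear' or 'additive'")


def component_means(params: PolicyParams, s: float) -> np.ndarray:
    """Means of the mixture components at stimulus ``s``: ``w_i^0 + w_i^1 * s``."""
    return params.intercepts + params.slopes * s


def _log_mixture_at_actions(intercepts, slopes, sigma_a, n_actions, s):
    """Log of the (unnormalized) mixture density at each action location.

    Computed through logsumexp over components so that large weights do not
    underflow before normalization.
    """
    means = intercepts + slopes * s  # (Nw,)
    a = np.arange(1, n_actions + 1, dtype=float)
    z = -((a[:, None] - means[None, :]) ** 2) / (2.0 * sigma_a**2)  # (Na, Nw)
    zmax = z.max(axis=1)
    with np.errstate(invalid="ignore"):  # -inf - -inf when the density overflows
        return zmax + np.log(np.exp(z - zmax[:, None]).sum(axis=1))


def action_pmf(params: PolicyParams, s: float) -> np.ndarray:
    """Probability of each action ``1..Na`` given stimulus ``s``.

    The continuous mixture density is evaluated at the integer action
    locations and renormalized over them.

    Raises
    ------
    PolicyCollapseError
        If the density underflows to zero at every action location.
    """
    logp = _log_mixture_at_actions(
        params.intercepts, params.slopes, params.sigma_a, params.n_actions, s
    )
    if not np.all(np.isfinite(logp)):
        bad = logp[np.isfinite(logp)]
        if bad.size == 0:
            raise PolicyCollapseError(
                "mixture density underflowed at every action location"
            )
        logp = np.where(np.isfinite(logp), logp, -np.inf)
    logp = logp - logp.max()
    p = np.exp(logp)
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise PolicyCollapseError("mixture density underflowed at every action location")
    return p / total


def sample_stimulus(env: EnvParams, rng: np.random.Generator) -> float:
    """Draw one stimulus from ``Normal(0, sigma_s^2)``."""
    return float(rng.normal(0.0, env.sigma_s))


def sample_action(params: PolicyParams, s: float, rng: np.random.Generator) -> int:
    """Draw one action label in ``{1..Na}`` from the policy at stimulus ``s``."""
    p = action_pmf(params, s)
    return int(rng.choice(params.n_actions, p=p)) + 1


def reward_mean(env: EnvParams, a: int, s: float) -> float:
    """Mean reward for taking action ``a`` at stimulus ``s``."""
    if env.reward_form == "bilinear":
        return env.alpha * (a - env.beta) * s
    return env.alpha * a + env.beta * s


def sample_reward(env: EnvParams, a: int, s: float, rng: np.random.Generator) -> float:
    """Draw one reward from ``Normal(reward_mean(a, s), sigma_r^2)``."""
    return float(rng.normal(reward_mean(env, a, s), env.sigma_r))
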