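"""Per-step policy re-estimation by derivative-free simplex search.

Each simulation step (once the memory window is full) the weight vector is
re-fit by minimizing the compromise loss with Nelder-Mead.  Only the weights
move; the policy shape (number of components, actions, sigma_a) is fixed.
The caller chooses the start point (the simulator defaults to re-starting
from the run's initial weights each step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import (
    OBJ_CONSISTENCY,
    OBJ_MIXTURE,
    OBJ_REWARD,
    neg_expected_reward_kernel,
    nll_kernel,
    nm_minimize,
)
from .model import EnvParams, PolicyParams
from .objective import LOSS_SENTINEL, History, stimulus_quadrature

logger = logging.getLogger(__name__)

__all__ = ["OptimizerOptions", "minimize_compromise"]

_WEIGHT_WARN = 1e3


@dataclass(frozen=True)
class OptimizerOptions:
    """Nelder-Mead settings (Lagarias et al. coefficients, scipy default)."""

    max_iterations: int | None = None  # None -> 200 * dim
    x_tolerance: float = 1e-6
    f_tolerance: float = 1e-6
    restart_count: int = 0

    def __post_init__(self) -> None:
        if self.x_tolerance <= 0 or self.f_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.restart_count < 0:
            raise ValueError("restart_count must be >= 0")


def _reward_nodes(env, s, reward_form):
    """Stimulus locations and weights of the reward expectation."""
    if reward_form == "prior":
        return stimulus_quadrature(env.sigma_s)
    if reward_form == "mean":
        return s, np.full(s.size, 1.0 / s.size)
    if reward_form == "sum":
        return s, np.ones(s.size)
    raise ValueError("reward_form must be 'prior', 'mean' or 'sum'")


def _objective_on_arrays(env, lambda_, sigma_a, n_actions, s, a, reward_form):
    bilinear = env.reward_form == "bilinear"
    rs, rw = _reward_nodes(env, s, reward_form)
    if lambda_ == 0.0:
        def f(w):
            return nll_kernel(w, sigma_a, n_actions, s, a)
    elif lambda_ == 1.0:
        def f(w):
            return neg_expected_reward_kernel(
                w, sigma_a, n_actions, rs, rw, env.alpha, env.beta, bilinear
            )
    else:
        def f(w):
            la = nll_kernel(w, sigma_a, n_actions, s, a)
            lr = neg_expected_reward_kernel(
                w, sigma_a, n_actions, rs, rw, env.alpha, env.beta, bilinear
            )
            return lambda_ * lr + (1.0 - lambda_) * la
    return f


def minimize_compromise(
    init: PolicyParams,
    history: History,
    env: EnvParams,
    lambda_: float,
    opts: OptimizerOptions = OptimizerOptions(),
    reward_form: str = "prior",
) -> PolicyParams:
    """Minimize the compromise loss over the weight vector.

    Runs Nelder-Mead from ``init.weights`` (optionally restarting from the
    incumbent) and returns the incumbent weights; never returns a point worse
    than ``init`` beyond ``f_tolerance``.  A non-finite loss at the start
    point aborts the update and returns ``init`` unchanged.
    """
    if not history.full:
        raise ValueError("minimization requires a full memory window")
    s, a, _ = history.arrays()
    f = _objective_on_arrays(
        env, lambda_, init.sigma_a, init.n_actions, s, a, reward_form
    )
    x0 = np.asarray(init.weights, dtype=float)
    f0 = f(x0)
    if not np.isfinite(f0) or f0 >= LOSS_SENTINEL:
        logger.warning("non-finite loss at warm start; keeping previous weights")
        return init

    maxiter = opts.max_iterations if opts.max_iterations is not None else 200 * x0.size
    if lambda_ == 0.0:
        which = OBJ_CONSISTENCY
    elif lambda_ == 1.0:
        which = OBJ_REWARD
    else:
        which = OBJ_MIXTURE
    bilinear = env.reward_form == "bilinear"
    rs, rw = _reward_nodes(env, s, reward_form)
    best_x, best_f = x0, f0
    for _ in range(opts.restart_count + 1):
        xk, fk = nm_minimize(
            which, best_x, init.sigma_a, init.n_actions, s, a, rs, rw,
            env.alpha, env.beta, bilinear, lambda_,
            opts.x_tolerance, opts.f_tolerance, maxiter,
        )
        if np.isfinite(fk) and fk < best_f:
            best_x, best_f = xk, float(fk)
        else:
            break

    if best_f > f0 + opts.f_tolerance:  # pragma: no cover - guarded by scipy contract
        return init
    if np.max(np.abs(best_x)) > _WEIGHT_WARN:
        logger.warning("weight magnitude exceeded %g: %s", _WEIGHT_WARN, best_x)
    return init.with_weights(best_x)
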