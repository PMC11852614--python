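"""Sequential simulation loop.

Each discrete step: sample a stimulus, sample an action from the current
policy, sample a reward, append the triple to the bounded memory, and — once
the memory window is full — re-fit the policy weights by simplex minimization
of the compromise loss.  Everything is recorded per step in a
:class:`Trajectory`.

Randomness uses one root seed per run with independent child streams for the
stimulus, action, and reward draws, so altering one sampling role does not
perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import EnvParams, PolicyParams, sample_action, sample_reward, sample_stimulus
from .objective import History, compromise_loss
from .updater import OptimizerOptions, minimize_compromise

__all__ = ["SimConfig", "Trajectory", "SimState", "run", "step"]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulation run.

    Defaults are the standard parameter set: a single mixture component
    started midway between two actions (weights ``(1.5, 0)``), memory length
    20, consistency-only objective (``lambda_=0``), unit dispersions, and
    reward coupling ``alpha=2, beta=3/2``.
    """

    policy: PolicyParams = PolicyParams((1.5, 0.0))
    env: EnvParams = EnvParams()
    lambda_: float = 0.0
    memory_length: int = 20
    n_steps: int = 600
    seed: int = 0
    optimizer: OptimizerOptions = OptimizerOptions()
    reward_loss_form: str = "prior"
    simplex_start: str = "initial"

    def __post_init__(self) -> None:
        if self.simplex_start not in ("initial", "previous"):
            raise ValueError("simplex_start must be 'initial' or 'previous'")
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must lie in [0, 1]")
        if self.memory_length < 1:
            raise ValueError("memory_length must be >= 1")
        if self.n_steps < self.memory_length:
            raise ValueError("n_steps must be >= memory_length")

    def to_dict(self) -> dict:
        return {
            "weights": list(self.policy.weights),
            "n_actions": self.policy.n_actions,
            "sigma_a": self.policy.sigma_a,
            "sigma_s": self.env.sigma_s,
            "alpha": self.env.alpha,
            "beta": self.env.beta,
            "sigma_r": self.env.sigma_r,
            "reward_form": self.env.reward_form,
            "lambda_": self.lambda_,
            "memory_length": self.memory_length,
            "n_steps": self.n_steps,
            "seed": self.seed,
            "max_iterations": self.optimizer.max_iterations,
            "x_tolerance": self.optimizer.x_tolerance,
            "f_tolerance": self.optimizer.f_tolerance,
            "restart_count": self.optimizer.restart_count,
            "reward_loss_form": self.reward_loss_form,
            "simplex_start": self.simplex_start,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        policy = PolicyParams(
            tuple(d.pop("weights", (1.5, 0.0))),
            int(d.pop("n_actions", 2)),
            float(d.pop("sigma_a", 1.0)),
        )
        env = EnvParams(
            sigma_s=float(d.pop("sigma_s", 1.0)),
            alpha=float(d.pop("alpha", 2.0)),
            beta=float(d.pop("beta", 1.5)),
            sigma_r=float(d.pop("sigma_r", 1.0)),
            reward_form=d.pop("reward_form", "bilinear"),
        )
        opt = OptimizerOptions(
            max_iterations=d.pop("max_iterations", None),
            x_tolerance=float(d.pop("x_tolerance", 1e-6)),
            f_tolerance=float(d.pop("f_tolerance", 1e-6)),
            restart_count=int(d.pop("restart_count", 0)),
        )
        known = {"lambda_", "memory_length", "n_steps", "seed", "reward_loss_form", "simplex_start"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            policy=policy,
            env=env,
            lambda_=float(d.get("lambda_", 0.0)),
            memory_length=int(d.get("memory_length", 20)),
            n_steps=int(d.get("n_steps", 600)),
            seed=int(d.get("seed", 0)),
            optimizer=opt,
            reward_loss_form=d.get("reward_loss_form", "prior"),
            simplex_start=d.get("simplex_start", "initial"),
        )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Trajectory:
    """Per-step record of one run: time, stimulus, action, reward, weights, losses."""

    config: SimConfig
    t: np.ndarray
    s: np.ndarray
    a: np.ndarray
    r: np.ndarray
    w: np.ndarray  # (T, 2*Nw), weights after the step's update
    loss_a: np.ndarray
    loss_r: np.ndarray
    loss_lambda: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "s": self.s, "a": self.a, "r": self.r}
        for j in range(self.w.shape[1]):
            cols[f"w_{j}"] = self.w[:, j]
        cols["loss_a"] = self.loss_a
        cols["loss_r"] = self.loss_r
        cols["loss_lambda"] = self.loss_lambda
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".config.json")
        sidecar.write_text(json.dumps(self.config.to_dict(), indent=1))

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".config.json")
        if sidecar.exists():
            config = SimConfig.from_dict(json.loads(sidecar.read_text()))
        else:
            nw = sum(c.startswith("w_") for c in df.columns) // 2
            config = SimConfig(
                policy=PolicyParams(tuple([1.5, 0.0] * nw), int(df["a"].max())),
                n_steps=len(df),
                memory_length=1,
            )
        wcols = [c for c in df.columns if c.startswith("w_")]
        return cls(
            config=config,
            t=df["t"].to_numpy(),
            s=df["s"].to_numpy(dtype=float),
            a=df["a"].to_numpy(dtype=np.int64),
            r=df["r"].to_numpy(dtype=float),
            w=df[wcols].to_numpy(dtype=float),
            loss_a=df["loss_a"].to_numpy(dtype=float),
            loss_r=df["loss_r"].to_numpy(dtype=float),
            loss_lambda=df["loss_lambda"].to_numpy(dtype=float),
        )


@dataclass
class SimState:
    """Mutable state threaded through :func:`step`."""

    config: SimConfig
    policy: PolicyParams
    history: History
    t: int
    rng_s: np.random.Generator
    rng_a: np.random.Generator
    rng_r: np.random.Generator
    records: list = field(default_factory=list)


def _init_state(config: SimConfig) -> SimState:
    ss = np.random.SeedSequence(config.seed)
    child_s, child_a, child_r = ss.spawn(3)
    return SimState(
        config=config,
        policy=config.policy,
        history=History(config.memory_length),
        t=0,
        rng_s=np.random.default_rng(child_s),
        rng_a=np.random.default_rng(child_a),
        rng_r=np.random.default_rng(child_r),
    )


def step(state: SimState) -> SimState:
    """Advance one time step in place (sample, record, maybe re-fit weights)."""
    cfg = state.config
    s = sample_stimulus(cfg.env, state.rng_s)
    a = sample_action(state.policy, s, state.rng_a)
    r = sample_reward(cfg.env, a, s, state.rng_r)
    state.history.append(s, a, r)
    if state.history.full:
        start = cfg.policy if cfg.simplex_start == "initial" else state.policy
        state.policy = minimize_compromise(
            start,
            state.history,
            cfg.env,
            cfg.lambda_,
            cfg.optimizer,
            reward_form=cfg.reward_loss_form,
        )
        losses = compromise_loss(
            state.policy, state.history, cfg.env, cfg.lambda_, cfg.reward_loss_form
        )
    else:
        losses = compromise_loss(
            state.policy, state.history, cfg.env, cfg.lambda_, cfg.reward_loss_form
        )
    state.records.append(
        (state.t, s, a, r, state.policy.weights, losses.l_a, losses.l_r, losses.l_lambda)
    )
    state.t += 1
    return state


def run(config: SimConfig) -> Trajectory:
    """Run the full loop for ``config.n_steps`` steps and return the trajectory."""
    state = _init_state(config)
    for _ in range(config.n_steps):
        step(state)
    t, s, a, r, w, la, lr, ll = zip(*state.records)
    return Trajectory(
        config=config,
        t=np.asarray(t, dtype=np.int64),
        s=np.asarray(s, dtype=float),
        a=np.asarray(a, dtype=np.int64),
        r=np.asarray(r, dtype=float),
        w=np.asarray(w, dtype=float),
        loss_a=np.asarray(la, dtype=float),
        loss_r=np.asarray(lr, dtype=float),
        loss_lambda=np.asarray(ll, dtype=float),
    )
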