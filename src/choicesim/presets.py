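"""Canned experiment configurations.

Each preset is the standard parameter set with the single change that
defines the experiment: a longer memory, more mixture components, more
actions, or a sweep of the reward weight lambda.  Run lengths give the mean
stoppage time roughly three standard deviations of headroom.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import PolicyParams
from .simulator import SimConfig

__all__ = ["ExperimentPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    config: SimConfig
    n_runs: int
    lambda_grid: tuple = ()
    description: str = ""


def _std(**kw) -> SimConfig:
    return SimConfig().replace(**kw)


PRESETS: dict[str, ExperimentPreset] = {
    "fig2_single_run": ExperimentPreset(
        "fig2_single_run",
        _std(n_steps=600),
        n_runs=1,
        description="One standard run; inspect the choice map, loss trace, and weights.",
    ),
    "fig3_stoppage_delta": ExperimentPreset(
        "fig3_stoppage_delta",
        _std(n_steps=600),
        n_runs=40,
        description="Stoppage-time distribution; repeat with memory_length=40, n_steps=1500.",
    ),
    "fig4_individuation": ExperimentPreset(
        "fig4_individuation",
        _std(n_steps=600),
        n_runs=40,
        description="Behavior taxonomy across identically configured runs.",
    ),
    "fig5_four_params": ExperimentPreset(
        "fig5_four_params",
        _std(policy=PolicyParams((1.25, 0.0, 1.75, 0.0)), n_steps=600),
        n_runs=40,
        description="Two mixture components (four weights): sandwich and switching behaviors.",
    ),
    "fig6_multi_choice": ExperimentPreset(
        "fig6_multi_choice",
        _std(policy=PolicyParams((1.5, 0.0), n_actions=3), n_steps=1500),
        n_runs=40,
        description="Three or more actions; segmentation and paired stoppage times.",
    ),
    "fig7_lambda_sweep": ExperimentPreset(
        "fig7_lambda_sweep",
        _std(n_steps=600),
        n_runs=40,
        lambda_grid=(0.0, 0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
        description="Reward-vs-consistency sweep: dominance direction and stoppage vs lambda.",
    ),
}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
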