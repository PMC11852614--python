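"""Trajectory analysis: stoppage times, behavior taxonomy, batch statistics.

A run's headline measurables are (i) the *stoppage time* of each losing
action — the last step at which it is sampled before the winner takes over —
and (ii) a *behavior label* describing how the actions organize along the
stimulus axis: full discrimination into separated stimulus bands,
intermingled choices, a "sandwich" (one action occupying a band between two
bands of another), a switch of the stimulus-action mapping mid-run, or a
single action dominating throughout.  Batches of independent runs are then
summarized as the mean/SD of stoppage times, class frequencies with binomial
standard errors, dominance directions, and (for three or more actions) the
regression of second on first stoppage times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .simulator import SimConfig, Trajectory, run

__all__ = [
    "ClassifierOptions",
    "BehaviorLabel",
    "RunSummary",
    "BatchSummary",
    "running_average",
    "stoppage_times",
    "classify_run",
    "dominance_direction",
    "summarize_run",
    "batch_run",
    "stoppage_regression",
    "lambda_sweep",
]


@dataclass(frozen=True)
class ClassifierOptions:
    """Thresholds of the behavior classifier.

    The taxonomy is defined operationally: actions are compared by the
    stimulus sets that elicit them inside an assessment window of
    ``window`` steps ending at the earliest losing-action stoppage (or at
    the end of the run when nothing stops).  Stimuli of one action are split
    into bands wherever consecutive sorted values gap by more than
    ``band_gap_factor`` times the median spacing; bands holding fewer than
    ``min_band_fraction`` of the action's samples are treated as stray
    points.  Separation requires fewer than ``separation_overlap`` of every
    action's stimuli to fall inside another action's band span; overlap
    above ``intermingled_overlap`` marks intermingling.
    """

    window: int = 100
    separation_overlap: float = 0.15
    intermingled_overlap: float = 0.5
    band_gap_factor: float = 4.0
    min_band_fraction: float = 0.1
    dominance_frequency: float = 0.95
    ordering_alpha: float = 0.01  # window-level false-organized rate
    span_lo: float = 5.0
    span_hi: float = 95.0


@dataclass(frozen=True)
class BehaviorLabel:
    label: str  # full_discrimination | intermingled | sandwich | switching | non_discriminating
    detail: str = ""


@dataclass(frozen=True)
class RunSummary:
    seed: int
    stoppage: dict  # action -> last step sampled (losing actions only)
    censored: tuple  # actions still sampled at the end (winners)
    behavior: BehaviorLabel
    dominance: str  # action2_positive | action1_positive | none
    discrimination_achieved: bool


@dataclass
class BatchSummary:
    n_runs: int
    runs: list
    stoppage_mean: float
    stoppage_sd: float
    n_stopped: int
    n_censored_runs: int
    class_frequencies: dict  # label -> (fraction, binomial SE)
    dominance_counts: dict
    regression: dict | None = None

    def to_dict(self) -> dict:
        def _num(x):  # NaN -> None so the dict serializes to valid JSON
            return None if x is None or not np.isfinite(x) else float(x)

        return {
            "n_runs": self.n_runs,
            "stoppage_mean": _num(self.stoppage_mean),
            "stoppage_sd": _num(self.stoppage_sd),
            "n_stopped": self.n_stopped,
            "n_censored_runs": self.n_censored_runs,
            "class_frequencies": {
                k: {"fraction": f, "se": se} for k, (f, se) in self.class_frequencies.items()
            },
            "dominance_counts": self.dominance_counts,
            "regression": self.regression,
            "runs": [
                {
                    "seed": r.seed,
                    "stoppage": {str(k): int(v) for k, v in r.stoppage.items()},
                    "censored": list(r.censored),
                    "behavior": r.behavior.label,
                    "detail": r.behavior.detail,
                    "dominance": r.dominance,
                    "discrimination_achieved": r.discrimination_achieved,
                }
                for r in self.runs
            ],
        }


def running_average(actions, window: int = 5) -> np.ndarray:
    """Centered moving mean of an action-label series.

    Edges use only the points available inside the (shrinking) window, so
    the output has the same length as the input.
    """
    a = np.asarray(actions, dtype=float)
    if a.size == 0:
        raise ValueError("empty series")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(a)])
    idx = np.arange(a.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, a.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def stoppage_times(traj: Trajectory) -> tuple[dict, tuple]:
    """Last-occurrence step of each losing action, and the censored winners.

    An action still being sampled within the final memory-length steps of
    the run is censored (a winner); any other action's stoppage time is the
    index of its last occurrence.
    """
    a = traj.a
    T = traj.n_steps
    delta = traj.config.memory_length
    losers, winners = {}, []
    for act in range(1, traj.config.policy.n_actions + 1):
        occ = np.nonzero(a == act)[0]
        if occ.size and occ[-1] >= T - delta:
            winners.append(act)
        elif occ.size:
            losers[act] = int(occ[-1])
        else:  # never sampled at all: stopped before the record began
            losers[act] = -1
    return losers, tuple(winners)


def _bands(s_sorted: np.ndarray, s_other: np.ndarray, opts: ClassifierOptions) -> list[np.ndarray]:
    """Split one action's sorted stimuli into bands.

    A gap between consecutive stimuli only separates two bands when it is
    wide relative to the typical spacing AND other actions actually occupy
    it — empty tail gaps of a Gaussian sample are not band boundaries.
    """
    if s_sorted.size <= 1:
        return [s_sorted] if s_sorted.size else []
    gaps = np.diff(s_sorted)
    med = np.median(gaps[gaps > 0]) if np.any(gaps > 0) else 0.0
    min_occupancy = max(3, int(np.ceil(opts.min_band_fraction * s_other.size)))
    cut = []
    for j in np.nonzero(gaps > opts.band_gap_factor * max(med, 1e-12))[0]:
        lo, hi = s_sorted[j], s_sorted[j + 1]
        if ((s_other > lo) & (s_other < hi)).sum() >= min_occupancy:
            cut.append(j)
    pieces = np.split(s_sorted, np.asarray(cut, dtype=int) + 1)
    min_n = max(2, int(np.ceil(opts.min_band_fraction * s_sorted.size)))
    kept = [p for p in pieces if p.size >= min_n]
    return kept if kept else [s_sorted]


def _band_spans(bands, opts):
    return [
        (np.percentile(b, opts.span_lo), np.percentile(b, opts.span_hi)) for b in bands
    ]


def _window_structure(s, a, n_actions, opts: ClassifierOptions):
    """Per-action bands and the worst pairwise stimulus overlap in a window."""
    present = [act for act in range(1, n_actions + 1) if np.any(a == act)]
    stimuli = {act: np.sort(s[a == act]) for act in present}
    bands = {}
    for act in present:
        other = np.sort(np.concatenate([stimuli[o] for o in present if o != act])) if len(present) > 1 else np.empty(0)
        bands[act] = _bands(stimuli[act], other, opts)
    spans = {act: _band_spans(bands[act], opts) for act in present}
    max_overlap = 0.0
    for act_i in present:
        for act_j in present:
            if act_i == act_j:
                continue
            inside = np.zeros(stimuli[act_i].size, dtype=bool)
            for lo, hi in spans[act_j]:
                inside |= (stimuli[act_i] >= lo) & (stimuli[act_i] <= hi)
            max_overlap = max(max_overlap, inside.mean() if inside.size else 0.0)
    return present, bands, max_overlap


def _medians(s, a, acts):
    return {act: float(np.median(s[a == act])) for act in acts}


def _median_gap_tol(x_i, x_j):
    """~2 SE of a median difference, from the pooled within-group spread."""
    n_i, n_j = max(x_i.size, 2), max(x_j.size, 2)
    pooled = np.sqrt(
        ((n_i - 1) * np.var(x_i, ddof=1) + (n_j - 1) * np.var(x_j, ddof=1))
        / (n_i + n_j - 2)
    )
    return 2.0 * 1.2533 * pooled * np.sqrt(1.0 / n_i + 1.0 / n_j)


def _ordered_groups(values, a, present, gamma):
    """True when the per-action stimulus groups are stochastically ordered.

    Each adjacent pair of actions must differ by a one-sided Mann-Whitney
    test (consistent direction across all pairs).  The per-pair level is
    gamma^(1/k) for k pairs so the whole-window false-organized rate stays
    at ~gamma regardless of the number of actions.
    """
    groups = [values[a == act] for act in present]
    if any(g.size < 2 for g in groups):
        return False
    alpha = gamma ** (1.0 / max(len(groups) - 1, 1))
    meds = [np.median(g) for g in groups]
    ascending = meds[-1] > meds[0]
    for i in range(len(groups) - 1):
        lo, hi = (groups[i], groups[i + 1]) if ascending else (groups[i + 1], groups[i])
        p = stats.mannwhitneyu(lo, hi, alternative="less").pvalue
        if p > alpha:
            return False
    return True


def _window_kind(s, a, n_actions, opts, present, bands, max_overlap):
    """How the actions organize in one window.

    Returns ``"full"``, ``"sandwich"`` or ``None`` (not organized).  Clean
    pointwise separation decides directly; otherwise — because at unit
    sigma_a adjacent actions intrinsically share stimulus mass, so pointwise
    sets never separate for three or more actions — an ordered-median
    criterion is used: monotone per-action median stimuli with gaps beyond
    sampling noise count as segmentation, and the same ordering on |s|
    (one action nested inside another's flanks) counts as a sandwich.
    """
    if len(present) != n_actions:
        return None
    if max_overlap < opts.separation_overlap:
        multi = any(len(v) > 1 for v in bands.values())
        return ("sandwich", True) if multi else ("full", True)
    if _ordered_groups(s, a, present, opts.ordering_alpha):
        return ("full", False)
    if _ordered_groups(np.abs(s), a, present, opts.ordering_alpha):
        return ("sandwich", False)
    return None


def _direction_from_window(s, a, present) -> str:
    if 1 not in present or 2 not in present:
        return "none"
    m = _medians(s, a, [1, 2])
    tol = _median_gap_tol(s[a == 1], s[a == 2])
    diff = m[2] - m[1]
    if abs(diff) <= tol:
        return "none"
    return "action2_positive" if diff > 0 else "action1_positive"


def _assessment_slice(traj: Trajectory, opts: ClassifierOptions) -> slice:
    """Window ending at the earliest losing stoppage (or the end of the run),
    never reaching back into the warmup steps."""
    losers, _ = stoppage_times(traj)
    end = min(losers.values()) if losers else traj.n_steps
    end = max(end, 1)
    start = max(min(traj.config.memory_length, end - 1), end - opts.window)
    return slice(start, end)


def _rolling_slices(delta, T, window):
    stride = max(window // 2, 1)
    starts = range(delta, max(T - window, delta) + 1, stride)
    return [slice(s0, min(s0 + window, T)) for s0 in starts] or [slice(delta, T)]


def classify_run(traj: Trajectory, opts: ClassifierOptions = ClassifierOptions()) -> BehaviorLabel:
    """Assign exactly one behavior label to a trajectory.

    Precedence: a single action dominating every part of the post-warmup
    record (non_discriminating), then a reversal of an established
    stimulus-action map between any two rolling windows (switching), then
    the stimulus overlap and band structure inside the assessment window
    (intermingled / sandwich / full_discrimination).
    """
    n_actions = traj.config.policy.n_actions
    delta = traj.config.memory_length
    detail = []

    if traj.n_steps - delta < opts.window:
        detail.append("short-run")

    # one action swamping every part of the post-warmup record: there was
    # never a discrimination phase to speak of
    blocks = _rolling_slices(delta, traj.n_steps, opts.window)
    block_max_freq = [
        max((traj.a[b] == act).mean() for act in range(1, n_actions + 1)) for b in blocks
    ]
    if min(block_max_freq) > opts.dominance_frequency:
        post_a = traj.a[delta:]
        freqs = [(post_a == act).mean() for act in range(1, n_actions + 1)]
        detail.append(f"dominant-action={int(np.argmax(freqs)) + 1}")
        return BehaviorLabel("non_discriminating", ";".join(detail))

    # scan the run for windows in which the actions organize by stimulus
    separated = []  # (slice, kind, clean, direction)
    for b in blocks:
        s_b, a_b = traj.s[b], traj.a[b]
        p_b, bands_b, ov_b = _window_structure(s_b, a_b, n_actions, opts)
        found = _window_kind(s_b, a_b, n_actions, opts, p_b, bands_b, ov_b)
        if found is not None:
            kind, clean = found
            d = _direction_from_window(s_b, a_b, p_b) if kind == "full" else "none"
            separated.append((b, kind, clean, d))
    # a lone median-based (soft) hit can be sampling noise; require either a
    # clean pointwise separation or persistence across windows
    if not any(clean for _, _, clean, _ in separated) and len(separated) < 2:
        separated = []

    # a map that established itself and then reversed direction
    directions = [d for _, _, _, d in separated if d != "none"]
    if len(set(directions)) > 1:
        detail.append("->".join(dict.fromkeys(directions)))
        return BehaviorLabel("switching", ";".join(detail))

    if not separated:
        # choices never sorted themselves by stimulus before the takeover
        sl = _assessment_slice(traj, opts)
        _, _, max_overlap = _window_structure(traj.s[sl], traj.a[sl], n_actions, opts)
        detail.append(f"overlap={max_overlap:.2f}")
        return BehaviorLabel("intermingled", ";".join(detail))

    # judge the organization from the last organized window (closest to the
    # takeover, hence the settled arrangement)
    _, kind_last, _, _ = separated[-1]
    detail.append(f"n_organized_windows={len(separated)}")
    if kind_last == "full":
        return BehaviorLabel("full_discrimination", ";".join(detail))
    return BehaviorLabel("sandwich", ";".join(detail))


def dominance_direction(traj: Trajectory, opts: ClassifierOptions = ClassifierOptions()) -> str:
    """Which of actions 1 and 2 ends up owning the positive stimuli.

    Compares the median stimulus eliciting each action in the assessment
    window; if an action is absent there, the window preceding its stoppage
    is used instead.  Returns ``"none"`` when the medians are within
    sampling noise of each other or no window contains both actions.
    """
    sl = _assessment_slice(traj, opts)
    s_w, a_w = traj.s[sl], traj.a[sl]
    present = [act for act in (1, 2) if np.any(a_w == act)]
    if len(present) == 2:
        return _direction_from_window(s_w, a_w, present)
    losers, _ = stoppage_times(traj)
    missing = [act for act in (1, 2) if act not in present]
    ends = [losers.get(act) for act in missing if losers.get(act, -1) > 0]
    if not ends:
        return "none"
    end = min(ends)
    sl2 = slice(max(0, end - opts.window), end + 1)
    s2, a2 = traj.s[sl2], traj.a[sl2]
    p2 = [act for act in (1, 2) if np.any(a2 == act)]
    if len(p2) < 2:
        return "none"
    return _direction_from_window(s2, a2, p2)


def summarize_run(traj: Trajectory, opts: ClassifierOptions = ClassifierOptions()) -> RunSummary:
    losers, winners = stoppage_times(traj)
    behavior = classify_run(traj, opts)
    return RunSummary(
        seed=traj.config.seed,
        stoppage=losers,
        censored=winners,
        behavior=behavior,
        dominance=dominance_direction(traj, opts),
        discrimination_achieved=behavior.label in ("full_discrimination", "sandwich", "switching"),
    )


def _binomial_se(f: float, n: int) -> float:
    return float(np.sqrt(f * (1.0 - f) / n)) if n else float("nan")


def batch_run(
    config: SimConfig,
    n_runs: int,
    seed_base: int = 0,
    opts: ClassifierOptions = ClassifierOptions(),
    n_jobs: int = 1,
) -> BatchSummary:
    """Run ``n_runs`` independent simulations (seeds ``seed_base + i``) and aggregate."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    configs = [config.replace(seed=seed_base + i) for i in range(n_runs)]
    trajs = Parallel(n_jobs=n_jobs)(delayed(run)(c) for c in configs)
    summaries = [summarize_run(t, opts) for t in trajs]
    return aggregate(summaries)


def aggregate(summaries: list[RunSummary]) -> BatchSummary:
    n = len(summaries)
    all_stops = [t for r in summaries for t in r.stoppage.values() if t >= 0]
    labels = ["full_discrimination", "intermingled", "sandwich", "switching", "non_discriminating"]
    freqs = {}
    for lab in labels:
        f = sum(r.behavior.label == lab for r in summaries) / n
        freqs[lab] = (f, _binomial_se(f, n))
    dom = {}
    for r in summaries:
        dom[r.dominance] = dom.get(r.dominance, 0) + 1
    return BatchSummary(
        n_runs=n,
        runs=summaries,
        stoppage_mean=float(np.mean(all_stops)) if all_stops else float("nan"),
        stoppage_sd=float(np.std(all_stops, ddof=1)) if len(all_stops) > 1 else float("nan"),
        n_stopped=len(all_stops),
        n_censored_runs=sum(1 for r in summaries if not r.stoppage),
        class_frequencies=freqs,
        dominance_counts=dom,
    )


def stoppage_pairs(summaries: list[RunSummary]) -> np.ndarray:
    """(first, second) losing stoppage times from runs with two losing actions."""
    pairs = []
    for r in summaries:
        stops = sorted(t for t in r.stoppage.values() if t >= 0)
        if len(stops) >= 2:
            pairs.append((stops[0], stops[1]))
    return np.asarray(pairs, dtype=float)


def stoppage_regression(summaries: list[RunSummary]) -> dict:
    """Pearson r and OLS fit of the second losing stoppage time on the first."""
    pairs = stoppage_pairs(summaries)
    if len(pairs) < 3:
        raise ValueError("need at least 3 runs with two losing actions")
    first, second = pairs[:, 0], pairs[:, 1]
    r, _ = stats.pearsonr(first, second)
    fit = stats.linregress(first, second)
    return {
        "n_pairs": int(len(pairs)),
        "r": float(r),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "first_mean": float(first.mean()),
        "first_sd": float(first.std(ddof=1)),
        "second_mean": float(second.mean()),
        "second_sd": float(second.std(ddof=1)),
    }


def lambda_sweep(
    config: SimConfig,
    lambda_grid,
    n_runs: int,
    seed_base: int = 0,
    opts: ClassifierOptions = ClassifierOptions(),
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Dominance direction and stoppage statistics across the reward weight grid."""
    rows = []
    for j, lam in enumerate(lambda_grid):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda grid values must lie in [0, 1]")
        batch = batch_run(
            config.replace(lambda_=float(lam)),
            n_runs,
            seed_base=seed_base + j * n_runs,
            opts=opts,
            n_jobs=n_jobs,
        )
        n2 = batch.dominance_counts.get("action2_positive", 0)
        frac = n2 / batch.n_runs
        rows.append(
            {
                "lambda": float(lam),
                "pct_action2_positive": 100.0 * frac,
                "se": 100.0 * _binomial_se(frac, batch.n_runs),
                "mean_stoppage": batch.stoppage_mean,
                "sd": batch.stoppage_sd,
                "n_censored": batch.n_censored_runs,
            }
        )
    return pd.DataFrame(rows)
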