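import numpy as np
import pytest

from choicesim.analysis import (
    ClassifierOptions,
    aggregate,
    batch_run,
    classify_run,
    dominance_direction,
    running_average,
    stoppage_regression,
    stoppage_times,
    summarize_run,
)
from choicesim.simulator import SimConfig

from conftest import make_trajectory, rule_trajectory


class TestRunningAverage:
    def test_constant_series(self):
        np.testing.assert_allclose(running_average([2] * 10), np.full(10, 2.0))

    def test_alternating_center(self):
        out = running_average([1, 2, 1, 2, 1], window=5)
        assert out[2] == pytest.approx(1.4)

    def test_window_one_is_identity(self):
        a = [1, 2, 2, 1]
        np.testing.assert_allclose(running_average(a, window=1), a)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            running_average([])
        with pytest.raises(ValueError):
            running_average([1, 2], window=4)


class TestStoppageTimes:
    def test_handcrafted_last_occurrence(self):
        a = np.full(300, 2)
        a[:138:2] = 1  # action 1 last appears at index 136
        a[137] = 1  # ... now at 137
        traj = make_trajectory(np.random.default_rng(0).normal(size=300), a)
        losers, winners = stoppage_times(traj)
        assert losers == {1: 137}
        assert winners == (2,)

    def test_no_stoppage_all_censored(self):
        g = np.random.default_rng(1)
        s = g.normal(size=300)
        a = np.where(s > 0, 2, 1)
        traj = make_trajectory(s, a)
        losers, winners = stoppage_times(traj)
        assert losers == {}
        assert set(winners) == {1, 2}

    def test_three_actions_two_losers(self):
        g = np.random.default_rng(2)
        s = g.normal(size=400)
        a = np.select([s < -0.4, s > 0.4], [1, 3], default=2)
        a[200:] = 3  # winner takes over
        traj = make_trajectory(s, a, n_actions=3)
        losers, winners = stoppage_times(traj)
        assert winners == (3,)
        assert set(losers) == {1, 2}
        assert all(v < 200 for v in losers.values())


class TestClassifier:
    def test_two_sided_discrimination_with_noise(self):
        traj = rule_trajectory(lambda s: 2 if s > 0 else 1, T=300, seed=3, noise=0.02)
        assert classify_run(traj).label == "full_discrimination"

    def test_independent_actions_intermingled(self):
        g = np.random.default_rng(4)
        s = g.normal(size=300)
        a = g.integers(1, 3, 300)
        assert classify_run(make_trajectory(s, a)).label == "intermingled"

    def test_sandwich_band_structure(self):
        traj = rule_trajectory(lambda s: 1 if abs(s) < 0.5 else 2, T=300, seed=5)
        assert classify_run(traj).label == "sandwich"

    def test_single_action_non_discriminating(self):
        g = np.random.default_rng(6)
        s = g.normal(size=300)
        a = np.full(300, 2)
        a[g.random(300) < 0.02] = 1
        assert classify_run(make_trajectory(s, a)).label == "non_discriminating"

    def test_switching_direction_reversal(self):
        g = np.random.default_rng(7)
        s = g.normal(size=400)
        a = np.where(s > 0, 2, 1)
        a[200:] = np.where(s[200:] > 0, 1, 2)
        assert classify_run(make_trajectory(s, a)).label == "switching"

    def test_three_way_segmentation(self):
        traj = rule_trajectory(
            lambda s: 1 if s < -0.4 else (2 if s < 0.4 else 3), T=400, seed=8, n_actions=3
        )
        assert classify_run(traj).label == "full_discrimination"

    def test_short_run_flagged(self):
        traj = rule_trajectory(lambda s: 2 if s > 0 else 1, T=60, seed=9)
        label = classify_run(traj)
        assert "short-run" in label.detail

    def test_classifier_bank_accuracy(self):
        """>=95% agreement on 500 trajectories built from known rules."""
        makers = {
            "full_discrimination": lambda seed: rule_trajectory(
                lambda s: 2 if s > 0 else 1, T=300, seed=seed, noise=0.02
            ),
            "sandwich": lambda seed: rule_trajectory(
                lambda s: 1 if abs(s) < 0.5 else 2, T=300, seed=seed, noise=0.01
            ),
            "intermingled": lambda seed: make_trajectory(
                np.random.default_rng(seed).normal(size=300),
                np.random.default_rng(seed + 1).integers(1, 3, 300),
            ),
            "non_discriminating": lambda seed: make_trajectory(
                np.random.default_rng(seed).normal(size=300),
                np.where(np.random.default_rng(seed + 1).random(300) < 0.98, 2, 1),
            ),
            "switching": lambda seed: _switching_traj(seed),
        }
        total = correct = 0
        for truth, makefn in makers.items():
            for seed in range(100):
                lab = classify_run(makefn(seed)).label
                total += 1
                correct += lab == truth
        assert total == 500
        assert correct / total >= 0.95


def _switching_traj(seed):
    g = np.random.default_rng(seed)
    s = g.normal(size=400)
    a = np.where(s > 0, 2, 1)
    a[200:] = np.where(s[200:] > 0, 1, 2)
    return make_trajectory(s, a)


class TestDominance:
    def test_positive_rule_action2(self):
        traj = rule_trajectory(lambda s: 2 if s > 0 else 1, T=300, seed=10)
        assert dominance_direction(traj) == "action2_positive"

    def test_mirrored_rule_action1(self):
        traj = rule_trajectory(lambda s: 1 if s > 0 else 2, T=300, seed=11)
        assert dominance_direction(traj) == "action1_positive"

    def test_independent_assignment_none(self):
        g = np.random.default_rng(12)
        traj = make_trajectory(g.normal(size=300), g.integers(1, 3, 300))
        assert dominance_direction(traj) == "none"

    def test_direction_recovered_after_stoppage(self):
        # discrimination then extinction of action 1: judged from the phase
        # preceding its stoppage
        g = np.random.default_rng(13)
        s = g.normal(size=400)
        a = np.where(s > 0, 2, 1)
        a[250:] = 2
        traj = make_trajectory(s, a)
        assert dominance_direction(traj) == "action2_positive"


class TestBatch:
    def test_reproducible_and_order_invariant(self):
        cfg = SimConfig(n_steps=120, memory_length=20)
        b1 = batch_run(cfg, 4, seed_base=0)
        b2 = batch_run(cfg, 4, seed_base=0)
        assert b1.to_dict() == b2.to_dict()
        # aggregation does not depend on run order
        reversed_summary = aggregate(list(reversed(b1.runs)))
        assert reversed_summary.stoppage_mean == b1.stoppage_mean or (
            np.isnan(reversed_summary.stoppage_mean) and np.isnan(b1.stoppage_mean)
        )
        assert reversed_summary.class_frequencies == b1.class_frequencies

    def test_frequencies_sum_to_one(self):
        cfg = SimConfig(n_steps=120, memory_length=20)
        b = batch_run(cfg, 4, seed_base=50)
        assert sum(f for f, _ in b.class_frequencies.values()) == pytest.approx(1.0)

    def test_n_runs_validated(self):
        with pytest.raises(ValueError):
            batch_run(SimConfig(n_steps=100), 1)


class TestRegression:
    def test_exact_collinear_pairs(self):
        summaries = []
        for i, t in enumerate([100, 150, 230, 310]):
            traj = _two_loser_traj(i, t, t + 20)
            summaries.append(summarize_run(traj))
        out = stoppage_regression(summaries)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(20.0)

    def test_shuffled_pairs_low_correlation(self):
        g = np.random.default_rng(20)
        firsts = g.integers(80, 250, 30)
        seconds = g.integers(300, 500, 30)
        summaries = [
            summarize_run(_two_loser_traj(i, int(f), int(s)))
            for i, (f, s) in enumerate(zip(firsts, seconds))
        ]
        out = stoppage_regression(summaries)
        assert abs(out["r"]) < 0.5

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            stoppage_regression([summarize_run(_two_loser_traj(0, 100, 120))])


def _two_loser_traj(seed, stop1, stop2, T=600):
    """Na=3 trajectory where actions 1 and 2 stop at the given steps exactly."""
    g = np.random.default_rng(seed)
    s = g.normal(size=T)
    a = np.select([s < -0.4, s > 0.4], [1, 2], default=3)
    a[stop1 + 1 :][a[stop1 + 1 :] == 1] = 3
    a[stop2 + 1 :][a[stop2 + 1 :] == 2] = 3
    a[stop1] = 1
    a[stop2] = 2
    return make_trajectory(s, a, n_actions=3)
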