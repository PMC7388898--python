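"""Softmax policy, the episode loop, and the experiment protocols."""

import numpy as np
import pytest

import ovarlap as ov
from ovarlap.runner import softmax_probabilities


class TestSoftmax:
    def test_equal_values_uniform(self):
        assert softmax_probabilities([0.3] * 4, 0.5) == pytest.approx([0.25] * 4)

    def test_printed_softmax_value(self):
        """p1 = e^{0.1/0.5} / (e^{0.1/0.5} + 3) for values (0.1, 0, 0, 0)."""
        p = softmax_probabilities([0.1, 0.0, 0.0, 0.0], 0.5)
        assert p[0] == pytest.approx(np.exp(0.2) / (np.exp(0.2) + 3),
                                     abs=1e-10)
        assert p.sum() == pytest.approx(1.0)

    def test_high_temperature_limit_uniform(self):
        p = softmax_probabilities([5.0, -5.0, 1.0, 0.0], 1e9)
        assert p == pytest.approx([0.25] * 4, abs=1e-6)

    def test_probabilities_positive_and_normalized(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = softmax_probabilities(rng.normal(size=4) * 10,
                                      float(rng.uniform(0.01, 5)))
            assert np.all(p > 0)
            assert p.sum() == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            softmax_probabilities([0, 0, 0, 0], 0.0)
        with pytest.raises(FloatingPointError):
            softmax_probabilities([np.nan, 0, 0, 0], 0.5)

    def test_sampling_frequencies_follow_distribution(self):
        rng = np.random.default_rng(3)
        values = [1.0, 0.0, 0.0, -1.0]
        counts = np.bincount(
            [ov.select_action(values, 0.5, rng) for _ in range(20_000)],
            minlength=4)
        assert counts / 20_000 == pytest.approx(
            softmax_probabilities(values, 0.5), abs=0.02)


class TestRunEpisode:
    def test_greedy_entry_is_single_step(self, painful_world):
        a = ov.TabularAgent()
        a.values[18, 9] = 100.0  # value of the goal square (19, 10)
        trace = ov.run_episode(painful_world, a, np.random.default_rng(0),
                               tau=0.01, start=(18, 10))
        assert trace.steps == 1
        assert trace.total_reward == 1.0
        assert trace.transitions[0].terminal

    def test_wall_hits_match_transition_flags(self, painful_world):
        a = ov.TabularAgent()
        trace = ov.run_episode(painful_world, a, np.random.default_rng(1),
                               step_cap=300)
        assert trace.wall_hits == sum(t.wall_hit for t in trace.transitions)
        assert trace.steps == len(trace.transitions)
        assert trace.total_reward == pytest.approx(
            sum(t.reward for t in trace.transitions))

    def test_truncation_flagged_not_raised(self, painful_world):
        a = ov.TabularAgent()
        trace = ov.run_episode(painful_world, a, np.random.default_rng(2),
                               step_cap=5)
        assert trace.truncated and trace.steps == 5

    def test_bit_identical_under_fixed_seed(self, painful_world):
        traces = []
        for _ in range(2):
            a = ov.make_agent("ovarlap", painful_world, basis_seed=7)
            t = ov.run_episode(painful_world, a, np.random.default_rng(42),
                               step_cap=2000)
            traces.append((t.steps, t.total_reward, t.wall_hits,
                           [tr.action for tr in t.transitions]))
        assert traces[0] == traces[1]


@pytest.fixture(scope="module")
def painful_results(painful_world):
    return ov.run_painful_experiment(
        painful_world, n_runs=2, n_episodes=30, seed=5,
        snapshot_episodes=(5, 30))


@pytest.fixture(scope="module")
def disturbed_results(painless_world):
    return ov.run_disturbed_experiment(
        painless_world, n_runs=2, total_steps=3000, gamma=0.8, seed=4,
        noise_strength=1.0, noise_fraction=0.005)


class TestPainfulExperiment:
    def test_schema(self, painful_results):
        assert set(painful_results) == {"ovarlap", "tabular", "maxpain"}
        for runs in painful_results.values():
            assert len(runs) == 2
            for r in runs:
                assert list(r.episodes.columns) == [
                    "episode", "steps", "total_reward", "wall_hits",
                    "reward_per_step"]
                assert len(r.episodes) == 30
                assert set(r.snapshots) == {5, 30}
                assert r.snapshots[5].shape == (20, 20)

    def test_time_accounting(self, painful_results):
        for runs in painful_results.values():
            for r in runs:
                assert r.total_steps == r.episodes["steps"].sum()
                assert (r.episodes["steps"] >= 1).all()
                assert (r.episodes["wall_hits"] <= r.episodes["steps"]).all()

    def test_deterministic_in_master_seed(self, painful_world, painful_results):
        again = ov.run_painful_experiment(
            painful_world, agent_kinds=("tabular",), n_runs=2, n_episodes=30,
            seed=5, snapshot_episodes=(5, 30))
        for r1, r2 in zip(painful_results["tabular"], again["tabular"]):
            assert r1.episodes.equals(r2.episodes)
            assert np.array_equal(r1.final_value_map, r2.final_value_map)

    def test_runs_differ_across_indices(self, painful_results):
        r0, r1 = painful_results["tabular"]
        assert not r0.episodes.equals(r1.episodes)


class TestRelearningExperiment:
    def test_switch_disables_pain_and_logs_wall_values(self, painful_world):
        res = ov.run_relearning_experiment(
            painful_world, agent_kinds=("tabular",), n_runs=1,
            switch_episode=10, post_episodes=10, seed=3)["tabular"][0]
        assert len(res.wall_values) == 20
        pre = res.episodes.iloc[:10]
        post = res.episodes.iloc[10:]
        # painful phase: wall hits cost -1 each
        assert (pre["total_reward"] ==
                pre["total_reward"].round()).all()
        # painless phase: episode reward is exactly the entered goal reward
        goal_rewards = {1.0, 2.0}
        assert set(post["total_reward"].round(9)) <= goal_rewards

    def test_pre_switch_identical_to_painful_run(self, painful_world):
        relearn = ov.run_relearning_experiment(
            painful_world, agent_kinds=("ovarlap",), n_runs=1,
            switch_episode=8, post_episodes=4, seed=11)["ovarlap"][0]
        painful = ov.run_painful_experiment(
            painful_world, agent_kinds=("ovarlap",), n_runs=1, n_episodes=8,
            seed=11, snapshot_episodes=())["ovarlap"][0]
        assert relearn.episodes.iloc[:8].reset_index(drop=True).equals(
            painful.episodes)


class TestDisturbedExperiment:
    def test_total_step_budget_exact(self, disturbed_results):
        for r in disturbed_results:
            assert r.episodes["steps"].sum() == 3000

    def test_summary_present(self, disturbed_results):
        for r in disturbed_results:
            assert r.summary is not None
            assert r.final_value_map.shape == (20, 20)
            assert r.summary.max_value == r.final_value_map.max()

    def test_impaired_setting_never_decrements_values(self, painless_world):
        res = ov.run_disturbed_experiment(
            painless_world, n_runs=1, total_steps=1500, gamma=0.8,
            alpha2=0.0, seed=9)[0]
        assert res.final_value_map.min() >= -1e-12


def test_experiment_config_validation():
    cfg = ov.ExperimentConfig(n_episodes=500, n_total_steps=40_000)
    with pytest.raises(ValueError):
        cfg.validate()
    cfg = ov.ExperimentConfig(n_episodes=100, snapshots=(5, 150))
    with pytest.raises(ValueError):
        cfg.validate()


def test_randomized_start_places_start_on_passable_nongoal(painful_world):
    res = ov.run_painful_experiment(
        painful_world, agent_kinds=("tabular",), n_runs=1, n_episodes=20,
        seed=1, snapshot_episodes=(), randomize_start=True)["tabular"][0]
    assert len(res.episodes) == 20  # runs to completion under random starts
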