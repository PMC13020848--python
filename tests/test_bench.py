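"""Bench: deviation ratios, evaluation, training plumbing, Pareto logic."""

import json

import numpy as np
import pandas as pd
import pytest

from ghctl import bench
from ghctl.challenge import AGENT_KEY, TEAM_RESOURCE_USAGE
from ghctl.env import GreenhouseEnv


class TestDeviationRatio:
    def test_published_irrigation_row(self):
        others = [10.96, 10.90, 11.01, 11.13, 10.52, 11.13]
        assert bench.deviation_ratio(8.31, others) == pytest.approx(
            -24.05, abs=0.005)

    def test_published_co2_row(self):
        others = [56.20, 56.15, 56.45, 55.84, 56.11, 56.04]
        assert bench.deviation_ratio(55.09, others) == pytest.approx(
            -1.86, abs=0.005)

    def test_agent_at_mean_is_zero(self):
        assert bench.deviation_ratio(5.0, [4.0, 5.0, 6.0]) == 0.0

    def test_exact_antisymmetry_identity(self):
        """agent = m(1+x) against a list with mean m gives exactly 100x."""
        m, x = 7.3, 0.42
        assert bench.deviation_ratio(m * (1 + x), [m - 1, m + 1]) == (
            pytest.approx(100 * x, abs=1e-10))

    def test_empty_or_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            bench.deviation_ratio(1.0, [])
        with pytest.raises(ValueError, match="zero"):
            bench.deviation_ratio(1.0, [-1.0, 1.0])


class TestDeviationReport:
    def test_reproduces_published_ratios(self):
        report = bench.challenge_deviation_report()
        by_param = report.set_index("parameter")["deviation_pct"]
        expected = {"CO2": -1.86, "Elec high": 0.63, "Elec low": 1.59,
                    "Heat": 1.60, "Irrigation": -24.05}
        for parameter, value in expected.items():
            assert by_param[parameter] == pytest.approx(value, abs=0.005)

    def test_agent_cloned_as_only_comparison_gives_zero(self):
        table = TEAM_RESOURCE_USAGE.loc[[AGENT_KEY]].copy()
        table.loc["clone"] = table.loc[AGENT_KEY]
        report = bench.deviation_report(table, AGENT_KEY)
        assert (report["deviation_pct"] == 0).all()

    def test_missing_resource_column_named(self):
        broken = TEAM_RESOURCE_USAGE.drop(columns=["Heat"])
        with pytest.raises(KeyError, match="Heat"):
            bench.deviation_report(broken, AGENT_KEY)

    def test_export_round_trip(self, tmp_path):
        report = bench.challenge_deviation_report()
        path = tmp_path / "dev.csv"
        bench.export_deviation_report(report, path)
        loaded = pd.read_csv(path)
        assert list(loaded.columns) == ["parameter", "agent", "mean_others",
                                        "deviation_pct"]
        np.testing.assert_allclose(loaded["deviation_pct"],
                                   report["deviation_pct"])


class TestFixedStrategies:
    def test_schedule_is_cyclic(self):
        strat = bench.FixedStrategy("two-week", np.array([[0.1] * 8,
                                                          [0.9] * 8]))
        np.testing.assert_array_equal(strat.action(0), strat.action(2))
        np.testing.assert_array_equal(strat.action(1), strat.action(3))

    def test_out_of_range_schedule_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            bench.constant_strategy("bad", np.full(8, 1.5))

    def test_builtin_baselines_are_valid(self):
        for strat in bench.builtin_baselines():
            a = strat.action(0)
            assert a.shape == (8,)
            assert ((a >= 0) & (a <= 1)).all()


class TestEvaluatePolicy:
    def test_reproducible_mean_reward(self):
        strat = bench.constant_strategy("mid", np.full(8, 0.5))
        a = bench.evaluate_policy(strat, GreenhouseEnv, n_episodes=2, seed=5)
        b = bench.evaluate_policy(strat, GreenhouseEnv, n_episodes=2, seed=5)
        assert a.mean_reward == b.mean_reward
        assert a.episode_rewards == b.episode_rewards

    def test_single_episode_sd_is_zero(self):
        strat = bench.constant_strategy("mid", np.full(8, 0.5))
        report = bench.evaluate_policy(strat, GreenhouseEnv, n_episodes=1,
                                       seed=3)
        assert report.sd_reward == 0.0

    def test_invalid_episode_count_rejected(self):
        with pytest.raises(ValueError, match="n_episodes"):
            bench.evaluate_policy(lambda obs: np.full(8, 0.5), GreenhouseEnv,
                                  n_episodes=0)


class TestTrainingPlumbing:
    def test_smoke_run_writes_checkpoint(self, tmp_path):
        cfg = bench.TrainConfig(algorithm="CEM", total_steps=500,
                                checkpoint_freq=400, population=6, seed=0)
        result = bench.run_training(GreenhouseEnv, cfg, out_dir=tmp_path)
        assert result.env_steps >= 500
        assert len(result.checkpoints) >= 1
        saved = json.loads((tmp_path / "best_policy.json").read_text())
        assert np.asarray(saved["schedule"]).shape == (23, 8)

    def test_td3_preset_maps_field_for_field(self):
        cfg = bench.TrainConfig.for_algorithm("TD3")
        kwargs = bench.to_backend_kwargs(cfg)
        assert kwargs["learning_rate"] == 1e-4
        assert kwargs["tau"] == 0.005
        assert kwargs["policy_kwargs"]["net_arch"] == [256, 256, 128]
        assert kwargs["gamma"] == 0.99
        assert kwargs["batch_size"] == 256
        assert kwargs["buffer_size"] == 1000
        assert kwargs["train_freq"] == (1, "episode")
        assert kwargs["gradient_steps"] == 100

    def test_ppo_preset_has_no_buffer(self):
        kwargs = bench.to_backend_kwargs(bench.TrainConfig.for_algorithm("PPO"))
        assert "buffer_size" not in kwargs
        assert kwargs["ent_coef"] == 0.05

    def test_deep_rl_without_backend_raises(self):
        cfg = bench.TrainConfig.for_algorithm("TD3", total_steps=100)
        with pytest.raises(bench.MissingRLBackendError, match="TD3"):
            bench.run_training(GreenhouseEnv, cfg)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            bench.TrainConfig.for_algorithm("A2C")

    def test_same_seed_same_training_curve(self):
        cfg = bench.TrainConfig(algorithm="CEM", total_steps=300,
                                population=4, seed=9)
        a = bench.run_training(GreenhouseEnv, cfg)
        b = bench.run_training(GreenhouseEnv, cfg)
        assert a.eval_rewards == b.eval_rewards
        np.testing.assert_array_equal(a.policy.schedule, b.policy.schedule)


def brute_force_frontier(points):
    """O(n²) dominance check, written independently of the bench logic."""
    front = []
    for p in points:
        dominated = False
        for q in points:
            if q is p:
                continue
            better_yield = q.yield_score >= p.yield_score
            better_res = q.resource_score <= p.resource_score
            strictly = (q.yield_score > p.yield_score
                        or q.resource_score < p.resource_score)
            if better_yield and better_res and strictly:
                dominated = True
                break
        if not dominated:
            front.append(p)
    return front


class TestParetoFrontier:
    def make_points(self, rng, n=100):
        return [bench.ParetoPoint(alpha=1.0, beta=0.2,
                                  yield_score=float(y),
                                  resource_score=float(r),
                                  mean_reward=0.0)
                for y, r in rng.uniform(0, 1, size=(n, 2))]

    def test_single_point_is_its_own_frontier(self):
        p = bench.ParetoPoint(1.0, 0.2, 0.5, 0.5, 0.0)
        assert bench.pareto_frontier([p]) == [p]

    def test_dominated_point_is_marked(self):
        good = bench.ParetoPoint(1.0, 0.2, 0.9, 0.1, 0.0)
        bad = bench.ParetoPoint(1.0, 0.2, 0.5, 0.5, 0.0)
        front = bench.pareto_frontier([good, bad])
        assert bad.dominated and not good.dominated
        assert front == [good]

    def test_matches_brute_force_on_random_points(self, rng):
        points = self.make_points(rng)
        front = bench.pareto_frontier(points)
        expected = brute_force_frontier(points)
        assert {id(p) for p in front} == {id(p) for p in expected}

    def test_ties_kept_on_frontier(self):
        a = bench.ParetoPoint(1.0, 0.2, 0.7, 0.3, 0.0)
        b = bench.ParetoPoint(1.0, 0.2, 0.7, 0.3, 0.0)
        front = bench.pareto_frontier([a, b])
        assert len(front) == 2

    def test_export_round_trip_preserves_flags(self, tmp_path, rng):
        points = self.make_points(rng, n=20)
        bench.pareto_frontier(points)
        path = tmp_path / "pareto.csv"
        bench.export_pareto_points(points, path)
        loaded = bench.load_pareto_points(path)
        assert [p.dominated for p in loaded] == [p.dominated for p in points]

    def test_empty_report_export_writes_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        bench.export_eval_reports([], path)
        loaded = pd.read_csv(path)
        assert len(loaded) == 0 and "mean_reward" in loaded.columns
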