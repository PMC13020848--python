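"""Reward engine: worked examples, boundary identities, oracle equivalence.

The independent check re-evaluates the multi-objective reward as straight-line
arithmetic with no shared code, so an implementation slip in the engine cannot
cancel out of the comparison.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ghctl import rewards
from ghctl.rewards import RewardConfig


CFG = RewardConfig()


def straight_line_reward(crop, res, prev_a, next_a, cfg, overuse=False):
    """Independent re-implementation: plain arithmetic, no engine calls."""
    e = crop[0] / cfg.max_stem_elong
    t = crop[1] / cfg.max_stem_thick
    u = crop[2] / cfg.max_cum_trusses
    crop_reward = 0.4 * e + 0.3 * t + 0.3 * u
    heat, co2, eh, el, irr = res
    penalty = (0.2 * heat / cfg.max_heat + 0.3 * co2 / cfg.max_co2
               + 0.2 * (eh + el) / cfg.max_electricity
               + 0.3 * irr / cfg.max_irrigation)
    stability = cfg.s * sum(abs(b - a) for a, b in zip(prev_a, next_a))
    efficiency = crop_reward / (1.0 + penalty)
    bonus = 0.0
    for v in (e, t, u):
        if v >= 0.7:
            bonus += 0.2
    if e >= 0.8 and t >= 0.8 and u >= 0.8:
        bonus += 1.0
    punish = 0.0
    for v in (e, t, u):
        if v < 0.5:
            punish -= 0.1
    if e < 0.5 and t < 0.5 and u < 0.5:
        punish -= 1.0
    if overuse:
        punish -= 1.0
    return (cfg.alpha * crop_reward - cfg.beta * penalty + punish + bonus
            + cfg.delta * efficiency - cfg.gamma * stability)


def crop_from_normalized(e, t, u, cfg=CFG):
    return (e * cfg.max_stem_elong, t * cfg.max_stem_thick,
            u * cfg.max_cum_trusses)


class TestCropReward:
    def test_all_at_maxima_scores_one(self):
        crop = (CFG.max_stem_elong, CFG.max_stem_thick, CFG.max_cum_trusses)
        assert rewards.crop_reward(crop, CFG) == pytest.approx(1.0)

    def test_zero_crop_scores_zero(self):
        assert rewards.crop_reward((0, 0, 0), CFG) == 0.0

    def test_published_team_row_weighted_sum(self):
        # normalized triple (0.79, 0.73, 0.42) under weights (0.4, 0.3, 0.3)
        crop = crop_from_normalized(0.79, 0.73, 0.42)
        assert rewards.crop_reward(crop, CFG) == pytest.approx(0.661)

    def test_negative_crop_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            rewards.crop_reward((-1.0, 0.5, 0.5), CFG)


class TestResourcePenalty:
    def test_zero_and_maximal_usage(self):
        assert rewards.resource_penalty((0, 0, 0, 0, 0), CFG) == 0.0
        full = (CFG.max_heat, CFG.max_co2, CFG.max_electricity / 2,
                CFG.max_electricity / 2, CFG.max_irrigation)
        assert rewards.resource_penalty(full, CFG) == pytest.approx(1.0)

    def test_half_usage_is_linear(self):
        half = (CFG.max_heat / 2, CFG.max_co2 / 2, CFG.max_electricity / 4,
                CFG.max_electricity / 4, CFG.max_irrigation / 2)
        assert rewards.resource_penalty(half, CFG) == pytest.approx(0.5)


class TestStabilityPenalty:
    def test_identical_actions_cost_nothing(self):
        a = np.full(8, 0.3)
        assert rewards.stability_penalty(a, a, CFG) == 0.0

    def test_full_change_of_all_components(self):
        assert rewards.stability_penalty(
            np.zeros(8), np.ones(8), CFG) == pytest.approx(0.008)

    def test_half_change_of_one_component(self):
        a, b = np.zeros(8), np.zeros(8)
        b[3] = 0.5
        assert rewards.stability_penalty(a, b, CFG) == pytest.approx(0.0005)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rewards.stability_penalty(np.zeros(8), np.zeros(7), CFG)


class TestEfficiencyFactor:
    def test_no_penalty_passes_crop_through(self):
        assert rewards.efficiency_factor(0.7, 0.0) == 0.7

    def test_zero_crop_is_zero(self):
        assert rewards.efficiency_factor(0.0, 0.8) == 0.0

    def test_worked_example(self):
        assert rewards.efficiency_factor(0.661, 0.5) == pytest.approx(
            0.44067, abs=1e-5)


class TestIncentives:
    def test_all_parameters_excellent(self):
        punish, big, term = rewards.incentive_terms(
            (0.85, 0.85, 0.85), False, CFG)
        assert big == pytest.approx(1.6)  # 3×0.2 + 1.0
        assert punish == 0.0 and not term

    def test_all_parameters_poor(self):
        punish, big, term = rewards.incentive_terms(
            (0.4, 0.4, 0.4), False, CFG)
        assert punish == pytest.approx(-1.3)  # 3×(−0.1) − 1.0
        assert big == 0.0 and not term

    def test_overuse_penalizes_and_terminates(self):
        punish, _, term = rewards.incentive_terms((0.6, 0.6, 0.6), True, CFG)
        assert punish == pytest.approx(-1.0) and term


class TestTotalReward:
    def test_optimal_crop_zero_resources(self):
        crop = (CFG.max_stem_elong, CFG.max_stem_thick, CFG.max_cum_trusses)
        bd = rewards.total_reward(crop, (0, 0, 0, 0, 0), np.full(8, 0.5),
                                  np.full(8, 0.5), CFG)
        # 1.0·1.0 − 0 + 0 + 1.6 + 0.01·1.0 − 0
        assert bd.total == pytest.approx(2.61)
        assert not bd.terminate

    def test_total_is_recomputable_from_breakdown(self, rng):
        crop = crop_from_normalized(*rng.uniform(0, 1, 3))
        res = rng.uniform(0, 5, 5)
        a, b = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
        bd = rewards.total_reward(crop, res, a, b, CFG)
        assert bd.total == pytest.approx(bd.recompute_total(CFG), abs=1e-12)

    def test_worst_case_crop(self):
        bd = rewards.total_reward((0, 0, 0), (0, 0, 0, 0, 0),
                                  np.zeros(8), np.zeros(8), CFG)
        assert bd.total == pytest.approx(-1.3)

    def test_matches_straight_line_oracle_on_random_inputs(self, rng):
        for _ in range(2000):
            crop = crop_from_normalized(*rng.uniform(0, 1.2, 3))
            res = rng.uniform(0, 3, 5) * np.array(
                [CFG.max_heat, CFG.max_co2, CFG.max_electricity / 2,
                 CFG.max_electricity / 2, CFG.max_irrigation]) / 2
            a = rng.uniform(0, 1, 8)
            b = rng.uniform(0, 1, 8)
            overuse = bool(rng.integers(2))
            bd = rewards.total_reward(crop, res, a, b, CFG,
                                      res_overuse=overuse)
            expected = straight_line_reward(crop, res, a, b, CFG, overuse)
            assert bd.total == pytest.approx(expected, abs=1e-12)

    def test_affine_in_crop_reward(self):
        """Perturbing crop_reward by ε moves the total by
        α·ε + δ·ε/(1+penalty) while incentives are unchanged."""
        cfg = CFG
        res = (cfg.max_heat / 2, cfg.max_co2 / 2, cfg.max_electricity / 4,
               cfg.max_electricity / 4, cfg.max_irrigation / 2)
        a = np.full(8, 0.2)
        base = crop_from_normalized(0.60, 0.60, 0.60)
        eps_norm = 0.05  # stays inside (0.5, 0.7): no incentive flips
        bumped = crop_from_normalized(0.65, 0.65, 0.65)
        bd0 = rewards.total_reward(base, res, a, a, cfg)
        bd1 = rewards.total_reward(bumped, res, a, a, cfg)
        eps = eps_norm  # weights sum to 1, so crop_reward moves by eps_norm
        expected = eps * (cfg.alpha + cfg.delta / (1 + bd0.resource_penalty))
        assert bd1.total - bd0.total == pytest.approx(expected, abs=1e-12)


@given(e=st.floats(0, 1), t=st.floats(0, 1), u=st.floats(0, 1),
       h=st.floats(0, 1), c=st.floats(0, 1), el=st.floats(0, 1),
       ir=st.floats(0, 1))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_bounds_within_maxima(e, t, u, h, c, el, ir):
    """crop_reward, resource_penalty, efficiency all stay in [0, 1] for
    inputs within the configured maxima."""
    crop = crop_from_normalized(e, t, u)
    res = (h * CFG.max_heat, c * CFG.max_co2, el * CFG.max_electricity / 2,
           el * CFG.max_electricity / 2, ir * CFG.max_irrigation)
    cr = rewards.crop_reward(crop, CFG)
    rp = rewards.resource_penalty(res, CFG)
    assert 0.0 <= cr <= 1.0 + 1e-12
    assert 0.0 <= rp <= 1.0 + 1e-12
    assert 0.0 <= rewards.efficiency_factor(cr, rp) <= 1.0 + 1e-12


class TestTermination:
    def test_horizon_truncates_at_23(self):
        terminated, truncated, _ = rewards.check_termination(
            23, (0.8, 0.8, 0.8), False, CFG)
        assert truncated and not terminated

    def test_overuse_terminates_early(self):
        terminated, truncated, _ = rewards.check_termination(
            5, (0.8, 0.8, 0.8), True, CFG)
        assert terminated and not truncated

    def test_healthy_mid_episode_continues(self):
        terminated, truncated, streak = rewards.check_termination(
            10, (0.8, 0.8, 0.8), False, CFG)
        assert not terminated and not truncated and streak == 0

    def test_sustained_quality_failure_terminates(self):
        bad = (0.3, 0.3, 0.3)
        term1, _, streak = rewards.check_termination(4, bad, False, CFG)
        assert not term1 and streak == 1
        term2, _, streak = rewards.check_termination(5, bad, False, CFG,
                                                     low_quality_streak=streak)
        assert term2 and streak == 2


class TestConfigValidation:
    def test_weight_sums_enforced(self):
        with pytest.raises(ValueError, match="crop weights"):
            RewardConfig(crop_weights=(0.5, 0.3, 0.3))
        with pytest.raises(ValueError, match="resource weights"):
            RewardConfig(resource_weights=(0.5, 0.3, 0.2, 0.3))

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            RewardConfig(bonus_threshold=0.9)

    def test_collapsed_stability_scaling(self):
        cfg = RewardConfig(collapse_stability_scaling=True)
        crop = crop_from_normalized(0.6, 0.6, 0.6)
        bd_a = rewards.total_reward(crop, (0, 0, 0, 0, 0), np.zeros(8),
                                    np.ones(8), cfg)
        bd_b = rewards.total_reward(crop, (0, 0, 0, 0, 0), np.zeros(8),
                                    np.ones(8), CFG)
        # collapsed: −0.001·8; literal double scaling: −0.001·0.001·8
        assert bd_b.total - bd_a.total == pytest.approx(
            0.001 * 8 - 0.001 * 0.001 * 8, abs=1e-12)
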