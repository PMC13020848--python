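"""Multi-objective reward engine for weekly greenhouse control.

The per-step reward balances crop growth against resource consumption:

    reward = α·crop_reward − β·resource_penalty + punishment + big_reward
             + δ·efficiency_factor − γ·stability_penalty

with

    crop_reward      = w₁·elong/max_elong + w₂·thick/max_thick
                       + w₃·trusses/max_trusses                (w sums to 1)
    resource_penalty = p₁·heat/max_heat + p₂·CO₂/max_CO₂
                       + p₃·elec/max_elec + p₄·irr/max_irr     (p sums to 1)
    stability_penalty = s·Σ|action(t+1) − action(t)|
    efficiency_factor = crop_reward / (1 + resource_penalty)

plus threshold incentives: +0.2 per normalized crop parameter ≥ 0.7 and an
extra +1.0 when all three reach 0.8; −0.1 per parameter < 0.5 and an extra
−1.0 when all three fall below 0.5; overusing any resource beyond its weekly
threshold costs an extra 1.0 and terminates the episode.

The stability term is defined as a non-negative penalty, so it enters the
total with a minus sign (adding it would reward abrupt actions).  Both the
outer γ and the inner s scale factors are applied literally by default; set
``collapse_stability_scaling`` to fold them into a single 0.001 factor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RewardConfig:
    """Coefficients, normalization maxima, and thresholds of the reward."""

    alpha: float = 1.0      # crop-reward scale
    beta: float = 0.2       # resource-penalty scale
    delta: float = 0.01     # efficiency-factor scale
    gamma: float = 0.001    # stability-penalty scale (outer)
    s: float = 0.001        # stability-penalty scale (inner, in Eq form)

    crop_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    resource_weights: tuple[float, float, float, float] = (0.2, 0.3, 0.2, 0.3)

    # Normalization maxima (weekly scale).  The denominators are
    # dataset-level constants: these defaults are the observed maxima of a
    # seeded random-policy reference dataset on the dynamics oracle
    # (crop maxima coincide with the oracle's optimal-condition increments).
    max_stem_elong: float = 18.0     # cm/week
    max_stem_thick: float = 1.1      # mm/week
    max_cum_trusses: float = 1.3     # new trusses/stem·week
    max_heat: float = 85.0           # MJ/m²·week
    max_co2: float = 2.6             # kg/m²·week
    max_electricity: float = 11.0    # kWh/m²·week (high + low combined)
    max_irrigation: float = 82.0     # L/m²·week

    # Crop-quality thresholds and incentive magnitudes.
    bonus_threshold: float = 0.7
    big_bonus_threshold: float = 0.8
    low_quality_threshold: float = 0.5
    per_param_bonus: float = 0.2
    all_param_bonus: float = 1.0
    per_param_penalty: float = -0.1
    all_param_penalty: float = -1.0
    overuse_penalty: float = 1.0

    # Weekly per-resource overuse thresholds; ``None`` defaults to
    # 0.9 × the corresponding maximum.
    overuse_thresholds: dict | None = None
    overuse_fraction: float = 0.9

    max_steps: int = 23
    quality_failure_weeks: int = 2   # consecutive all-low weeks that terminate

    # Conventions
    collapse_stability_scaling: bool = False
    exclusive_bonuses: bool = False  # big bonus replaces per-param bonuses

    def __post_init__(self) -> None:
        if abs(sum(self.crop_weights) - 1.0) > 1e-9:
            raise ValueError("crop weights must sum to 1")
        if abs(sum(self.resource_weights) - 1.0) > 1e-9:
            raise ValueError("resource weights must sum to 1")
        for name in ("max_stem_elong", "max_stem_thick", "max_cum_trusses",
                     "max_heat", "max_co2", "max_electricity",
                     "max_irrigation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.low_quality_threshold < self.bonus_threshold
                < self.big_bonus_threshold):
            raise ValueError("quality thresholds must be ordered "
                             "low < bonus < big-bonus")

    def replace(self, **kw) -> "RewardConfig":
        return dataclasses.replace(self, **kw)

    def resource_maxima(self) -> dict[str, float]:
        return {"heat": self.max_heat, "co2": self.max_co2,
                "electricity": self.max_electricity,
                "irrigation": self.max_irrigation}

    def effective_overuse_thresholds(self) -> dict[str, float]:
        if self.overuse_thresholds is not None:
            return dict(self.overuse_thresholds)
        return {k: self.overuse_fraction * v
                for k, v in self.resource_maxima().items()}


@dataclass
class RewardBreakdown:
    """Per-term decomposition of one step's reward."""

    crop_reward: float
    resource_penalty: float
    punishment: float
    big_reward: float
    efficiency_factor: float
    stability_penalty: float
    total: float
    terminate: bool
    audit: dict = field(default_factory=dict)

    def recompute_total(self, cfg: RewardConfig) -> float:
        """Re-evaluate the top-level combination from the stored terms."""
        stability_scale = (1.0 if cfg.collapse_stability_scaling
                           else cfg.gamma)
        return (cfg.alpha * self.crop_reward
                - cfg.beta * self.resource_penalty
                + self.punishment + self.big_reward
                + cfg.delta * self.efficiency_factor
                - stability_scale * self.stability_penalty)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("audit")
        return d


def normalized_crop(crop, cfg: RewardConfig) -> np.ndarray:
    """(elong, thick, trusses) scaled by the configured maxima."""
    elong, thick, trusses = crop
    if elong < 0 or thick < 0 or trusses < 0:
        raise ValueError(f"crop values must be non-negative, got {crop}")
    return np.array([elong / cfg.max_stem_elong,
                     thick / cfg.max_stem_thick,
                     trusses / cfg.max_cum_trusses])


def normalized_resources(res, cfg: RewardConfig) -> np.ndarray:
    """(heat, co2, electricity, irrigation) scaled by the maxima.

    ``res`` is (heat, co2, elec_high, elec_low, irrigation); the two
    electricity bands are combined into one term normalized by their joint
    maximum.
    """
    heat, co2, elec_high, elec_low, irr = res
    if min(heat, co2, elec_high, elec_low, irr) < 0:
        raise ValueError(f"resource usage must be non-negative, got {res}")
    return np.array([heat / cfg.max_heat,
                     co2 / cfg.max_co2,
                     (elec_high + elec_low) / cfg.max_electricity,
                     irr / cfg.max_irrigation])


def crop_reward(crop, cfg: RewardConfig) -> float:
    """Weighted sum of max-normalized crop increments; 1.0 at the maxima."""
    return float(np.dot(cfg.crop_weights, normalized_crop(crop, cfg)))


def resource_penalty(res, cfg: RewardConfig) -> float:
    """Weighted sum of max-normalized resource draws; 1.0 at the maxima."""
    return float(np.dot(cfg.resource_weights, normalized_resources(res, cfg)))


def stability_penalty(prev_action, next_action, cfg: RewardConfig) -> float:
    """s times the L1 distance between consecutive action vectors."""
    prev = np.asarray(prev_action, dtype=float)
    nxt = np.asarray(next_action, dtype=float)
    if prev.shape != nxt.shape:
        raise ValueError(
            f"action shape mismatch: {prev.shape} vs {nxt.shape}")
    return float(cfg.s * np.abs(nxt - prev).sum())


def efficiency_factor(crop_rew: float, res_pen: float) -> float:
    """Crop reward discounted by resource use: crop/(1+penalty)."""
    if res_pen < 0:
        raise ValueError("resource penalty must be non-negative")
    return crop_rew / (1.0 + res_pen)


def incentive_terms(crop_norm, res_overuse, cfg: RewardConfig
                    ) -> tuple[float, float, bool]:
    """Threshold incentives: (punishment, big_reward, overuse_terminate).

    ``crop_norm`` is the normalized crop triple; ``res_overuse`` either a
    boolean (any resource over threshold) or an iterable of per-resource
    flags.
    """
    crop_norm = np.asarray(crop_norm, dtype=float)
    above = crop_norm >= cfg.bonus_threshold
    below = crop_norm < cfg.low_quality_threshold

    big_reward = cfg.per_param_bonus * above.sum()
    all_big = bool((crop_norm >= cfg.big_bonus_threshold).all())
    if all_big:
        big_reward = (cfg.all_param_bonus if cfg.exclusive_bonuses
                      else big_reward + cfg.all_param_bonus)

    punishment = cfg.per_param_penalty * below.sum()
    if below.all():
        punishment = (cfg.all_param_penalty if cfg.exclusive_bonuses
                      else punishment + cfg.all_param_penalty)

    overuse = bool(np.any(res_overuse))
    if overuse:
        punishment -= cfg.overuse_penalty
    return float(punishment), float(big_reward), overuse


def total_reward(crop, res, prev_action, next_action, cfg: RewardConfig,
                 res_overuse=False) -> RewardBreakdown:
    """Full per-step reward with its term-by-term decomposition."""
    c = crop_reward(crop, cfg)
    p = resource_penalty(res, cfg)
    stab = stability_penalty(prev_action, next_action, cfg)
    eff = efficiency_factor(c, p)
    crop_norm = normalized_crop(crop, cfg)
    punish, big, overuse = incentive_terms(crop_norm, res_overuse, cfg)
    breakdown = RewardBreakdown(
        crop_reward=c, resource_penalty=p, punishment=punish,
        big_reward=big, efficiency_factor=eff, stability_penalty=stab,
        total=0.0, terminate=overuse,
        audit={"crop_norm": crop_norm.tolist(),
               "res_norm": normalized_resources(res, cfg).tolist()})
    breakdown.total = breakdown.recompute_total(cfg)
    return breakdown


def check_termination(step_index: int, crop_norm, overuse: bool,
                      cfg: RewardConfig, low_quality_streak: int = 0
                      ) -> tuple[bool, bool, int]:
    """Episode-control decision: (terminated, truncated, new_streak).

    The horizon truncates at ``max_steps`` weeks.  Early termination occurs
    on resource overuse or when every crop parameter stays below the
    low-quality threshold for ``quality_failure_weeks`` consecutive weeks.
    """
    if step_index < 1:
        raise ValueError("step_index counts completed steps, starting at 1")
    crop_norm = np.asarray(crop_norm, dtype=float)
    streak = (low_quality_streak + 1
              if bool((crop_norm < cfg.low_quality_threshold).all()) else 0)
    terminated = overuse or streak >= cfg.quality_failure_weeks
    truncated = (not terminated) and step_index >= cfg.max_steps
    return terminated, truncated, streak
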