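"""Training harness, fixed-action baselines, and evaluation analytics.

The bench provides:

* the deviation-ratio benchmark — percent difference of an agent's cumulative
  resource usage from the mean of comparison strategies — applied to the
  published challenge table or to freshly evaluated strategies,
* fixed-action baseline strategies (the challenge teams' actual schedules are
  not public; parameterized synthetic stand-ins are shipped instead),
* a seeded policy-search trainer (cross-entropy method over weekly setpoint
  schedules) plus a field-for-field mapping of the published deep-RL
  hyperparameter configurations onto backend keyword dictionaries for use
  with an injected RL library,
* the (α, β) reward-weight sweep with Pareto-frontier extraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .challenge import AGENT_KEY, RESOURCE_PARAMETERS, TEAM_RESOURCE_USAGE
from .env import ACTION_COMPONENTS, GreenhouseEnv


class MissingRLBackendError(RuntimeError):
    """A deep-RL algorithm was requested but no backend was injected."""


# --------------------------------------------------------------------------
# deviation-ratio benchmark
# --------------------------------------------------------------------------

def deviation_ratio(agent_value: float, comparison_values) -> float:
    """Percent deviation of the agent from the mean of the comparisons.

    ``(agent − mean(others)) / mean(others) × 100``; negative when the agent
    uses less than the comparison average.
    """
    comparison_values = np.asarray(comparison_values, dtype=float)
    if comparison_values.size == 0:
        raise ValueError("comparison list must be non-empty")
    mean = comparison_values.mean()
    if mean == 0:
        raise ValueError("comparison mean is zero; ratio undefined")
    return float((agent_value - mean) / mean * 100.0)


def deviation_report(resource_table: pd.DataFrame,
                     agent_key: str = AGENT_KEY) -> pd.DataFrame:
    """Per-resource deviation ratios of one strategy vs all others.

    ``resource_table`` has one row per strategy and one column per resource
    (the published cumulative-usage layout).  Returns a frame with columns
    ``parameter, agent, mean_others, deviation_pct``.
    """
    missing = [c for c in RESOURCE_PARAMETERS
               if c not in resource_table.columns]
    if missing:
        raise KeyError(f"resource table missing columns: {missing}")
    if agent_key not in resource_table.index:
        raise KeyError(f"agent row {agent_key!r} not in table")
    others = resource_table.drop(index=agent_key)
    if len(others) < 1:
        raise ValueError("need at least one comparison strategy")
    rows = []
    for parameter in RESOURCE_PARAMETERS:
        agent_value = float(resource_table.loc[agent_key, parameter])
        comp = others[parameter].to_numpy(dtype=float)
        rows.append({
            "parameter": parameter,
            "agent": agent_value,
            "mean_others": float(comp.mean()),
            "deviation_pct": deviation_ratio(agent_value, comp),
        })
    return pd.DataFrame(rows)


def challenge_deviation_report() -> pd.DataFrame:
    """Deviation ratios recomputed from the published challenge table."""
    return deviation_report(TEAM_RESOURCE_USAGE, AGENT_KEY)


# --------------------------------------------------------------------------
# policies
# --------------------------------------------------------------------------

@dataclass
class FixedStrategy:
    """A predetermined weekly action schedule (cyclic if shorter than the
    episode); the non-adaptive baseline class."""

    name: str
    schedule: np.ndarray  # (n_weeks, 8) in [0, 1]

    def __post_init__(self) -> None:
        self.schedule = np.atleast_2d(np.asarray(self.schedule, dtype=float))
        if self.schedule.shape[1] != len(ACTION_COMPONENTS):
            raise ValueError("schedule must have 8 action components")
        if ((self.schedule < 0) | (self.schedule > 1)).any():
            raise ValueError("schedule entries must lie in [0, 1]")

    def action(self, week: int) -> np.ndarray:
        return self.schedule[week % len(self.schedule)]

    def __call__(self, obs) -> np.ndarray:
        return self.action(int(obs["week_index"]))


def constant_strategy(name: str, action) -> FixedStrategy:
    return FixedStrategy(name, np.asarray(action, dtype=float)[None, :])


def builtin_baselines() -> list[FixedStrategy]:
    """Synthetic stand-ins for the challenge teams' fixed schedules."""
    mid = constant_strategy("constant-mid", np.full(8, 0.5))
    conservative = constant_strategy(
        "constant-conservative",
        [0.2, 0.0, 0.0, 0.3, 0.6, 0.8, 0.4, 0.1])
    aggressive = constant_strategy(
        "constant-aggressive",
        [0.9, 0.0, 0.0, 0.8, 0.3, 0.1, 0.5, 0.9])
    weeks = np.linspace(0.0, 1.0, 23)[:, None]
    seasonal = FixedStrategy(
        "scheduled-seasonal",
        np.clip(0.3 + 0.5 * np.sin(np.pi * weeks) * np.ones((1, 8)), 0, 1))
    return [mid, conservative, aggressive, seasonal]


class RandomPolicy:
    """Uniform-random actions; the no-knowledge reference."""

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def __call__(self, obs) -> np.ndarray:
        return self.rng.uniform(0.0, 1.0, len(ACTION_COMPONENTS))


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Summary of seeded evaluation episodes for one strategy."""

    name: str
    n_episodes: int
    mean_reward: float
    sd_reward: float
    episode_rewards: list[float]
    mean_crop: dict[str, float]
    mean_weekly_resources: dict[str, float]
    mean_yield_score: float       # mean per-step crop_reward
    mean_resource_score: float    # mean per-step resource_penalty
    mean_episode_length: float


def rollout(env: GreenhouseEnv, policy, seed: int) -> dict:
    """Run one episode; returns cumulative reward and per-step summaries."""
    obs, _ = env.reset(seed=seed)
    total = 0.0
    crops, yields, penalties, weekly = [], [], [], []
    done = False
    steps = 0
    while not done:
        action = np.asarray(policy(obs), dtype=float)
        obs, reward, terminated, truncated, info = env.step(action)
        total += reward
        steps += 1
        bd = info["reward_breakdown"]
        yields.append(bd["crop_reward"])
        penalties.append(bd["resource_penalty"])
        crops.append(info["crop_increments"])
        weekly.append(info["weekly_resources"])
        done = terminated or truncated
    return {
        "reward": total,
        "steps": steps,
        "yield_score": float(np.mean(yields)),
        "resource_score": float(np.mean(penalties)),
        "mean_crop": pd.DataFrame(crops).mean().to_dict(),
        "mean_weekly_resources": pd.DataFrame(weekly).mean().to_dict(),
        "final_info": info,
    }


def evaluate_policy(policy, env_factory, n_episodes: int = 10,
                    seed: int = 0, name: str | None = None) -> EvalReport:
    """Evaluate a policy over seeded episodes; per-episode seeds derive
    reproducibly from the base seed."""
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    rng = np.random.default_rng(seed)
    env = env_factory()
    episodes = [rollout(env, policy, seed=int(rng.integers(2 ** 31)))
                for _ in range(n_episodes)]
    rewards_ = [e["reward"] for e in episodes]
    return EvalReport(
        name=name or getattr(policy, "name", type(policy).__name__),
        n_episodes=n_episodes,
        mean_reward=float(np.mean(rewards_)),
        sd_reward=float(np.std(rewards_)) if n_episodes > 1 else 0.0,
        episode_rewards=[float(r) for r in rewards_],
        mean_crop=pd.DataFrame([e["mean_crop"] for e in episodes])
        .mean().to_dict(),
        mean_weekly_resources=pd.DataFrame(
            [e["mean_weekly_resources"] for e in episodes]).mean().to_dict(),
        mean_yield_score=float(np.mean([e["yield_score"] for e in episodes])),
        mean_resource_score=float(
            np.mean([e["resource_score"] for e in episodes])),
        mean_episode_length=float(np.mean([e["steps"] for e in episodes])),
    )


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

#: Published hyperparameter configurations per deep-RL algorithm.
ALGO_PRESETS = {
    "TD3": dict(learning_rate=1e-4, batch_size=256, buffer_size=1000,
                entropy="N/A", train_freq="1 episode", gradient_steps=100,
                tau=0.005),
    "SAC": dict(learning_rate=1e-4, batch_size=16, buffer_size=10000,
                entropy="auto", train_freq="1 episode", gradient_steps=23,
                tau=0.005),
    "DDPG": dict(learning_rate=1e-3, batch_size=8, buffer_size=1000,
                 entropy="N/A", train_freq="1 episode", gradient_steps=1,
                 tau=0.002),
    "PPO": dict(learning_rate=1e-5, batch_size=64, buffer_size=None,
                entropy=0.05, train_freq="2048 steps", gradient_steps=20,
                tau=None),
}


@dataclass
class TrainConfig:
    """Training configuration; deep-RL fields mirror the published table."""

    algorithm: str = "CEM"
    net_arch: tuple = (256, 256, 128)
    learning_rate: float = 1e-4
    discount: float = 0.99
    batch_size: int = 256
    buffer_size: int | None = 1000
    entropy: object = "N/A"
    train_freq: str = "1 episode"
    gradient_steps: int = 100
    tau: float | None = 0.005
    total_steps: int = 120_000
    eval_freq: int = 10_000
    checkpoint_freq: int = 10_000
    seed: int = 0

    # CEM-specific knobs
    population: int = 20
    elite_frac: float = 0.3
    init_std: float = 0.25
    std_floor: float = 0.02
    smoothing: float = 0.7
    #: score every candidate on one fixed weather episode (sample-path
    #: optimization); None draws a fresh episode per candidate
    fixed_episode_seed: int | None = None
    #: length of the searched schedule in weeks; 0 means the full horizon,
    #: 1 searches a constant policy (the schedule cycles during rollout)
    schedule_weeks: int = 0

    def __post_init__(self) -> None:
        if self.total_steps < 1 or self.learning_rate <= 0:
            raise ValueError("rates and sizes must be positive")
        if not 0.0 < self.discount <= 1.0:
            raise ValueError("discount must be in (0, 1]")

    @classmethod
    def for_algorithm(cls, algorithm: str, **overrides) -> "TrainConfig":
        algo = algorithm.upper()
        if algo == "CEM":
            return cls(algorithm="CEM", **overrides)
        if algo not in ALGO_PRESETS:
            raise ValueError(f"unknown algorithm: {algorithm!r}")
        return cls(algorithm=algo, **{**ALGO_PRESETS[algo], **overrides})


def to_backend_kwargs(cfg: TrainConfig) -> dict:
    """Map a deep-RL TrainConfig field-for-field onto the keyword layout of
    the common RL-library constructors (for use with an injected backend)."""
    if cfg.algorithm.upper() == "CEM":
        raise ValueError("CEM trains natively; no backend mapping")
    kwargs = {
        "policy": "MultiInputPolicy",
        "policy_kwargs": {"net_arch": list(cfg.net_arch)},
        "learning_rate": cfg.learning_rate,
        "gamma": cfg.discount,
        "batch_size": cfg.batch_size,
        "seed": cfg.seed,
    }
    if cfg.buffer_size is not None:
        kwargs["buffer_size"] = cfg.buffer_size
        kwargs["train_freq"] = ((1, "episode")
                                if "episode" in str(cfg.train_freq)
                                else (2048, "step"))
        kwargs["gradient_steps"] = cfg.gradient_steps
    if cfg.tau is not None:
        kwargs["tau"] = cfg.tau
    if cfg.algorithm.upper() == "SAC":
        kwargs["ent_coef"] = "auto"
    if cfg.algorithm.upper() == "PPO":
        kwargs.pop("batch_size", None)
        kwargs["n_steps"] = 2048
        kwargs["batch_size"] = cfg.batch_size
        kwargs["ent_coef"] = float(cfg.entropy)
        kwargs["n_epochs"] = cfg.gradient_steps
    return kwargs


@dataclass
class TrainResult:
    policy: FixedStrategy
    eval_rewards: list[tuple[int, float]]   # (env steps, mean elite reward)
    env_steps: int
    checkpoints: list[str] = field(default_factory=list)


def train_cem(env_factory, cfg: TrainConfig,
              out_dir=None) -> TrainResult:
    """Cross-entropy-method search over weekly setpoint schedules.

    Each candidate is a full (23 × 8) open-loop schedule scored by one
    seeded episode; the sampling distribution contracts around the elite
    fraction until the environment-step budget is exhausted.
    """
    rng = np.random.default_rng(cfg.seed)
    env = env_factory()
    horizon = cfg.schedule_weeks or env.reward_config.max_steps
    mean = np.full((horizon, len(ACTION_COMPONENTS)), 0.5)
    std = np.full_like(mean, cfg.init_std)
    n_elite = max(1, int(round(cfg.population * cfg.elite_frac)))
    steps_done = 0
    eval_rewards: list[tuple[int, float]] = []
    checkpoints: list[str] = []
    next_checkpoint = cfg.checkpoint_freq
    best = (-np.inf, mean.copy())

    while steps_done < cfg.total_steps:
        candidates = np.clip(
            rng.normal(mean, std, size=(cfg.population, *mean.shape)),
            0.0, 1.0)
        scores = np.empty(cfg.population)
        for i, cand in enumerate(candidates):
            policy = FixedStrategy("cem-candidate", cand)
            ep_seed = (cfg.fixed_episode_seed
                       if cfg.fixed_episode_seed is not None
                       else int(rng.integers(2 ** 31)))
            result = rollout(env, policy, seed=ep_seed)
            scores[i] = result["reward"]
            steps_done += result["steps"]
        elite_idx = np.argsort(scores)[-n_elite:]
        elite = candidates[elite_idx]
        mean = cfg.smoothing * elite.mean(axis=0) + (1 - cfg.smoothing) * mean
        std = np.maximum(
            cfg.smoothing * elite.std(axis=0) + (1 - cfg.smoothing) * std,
            cfg.std_floor)
        elite_mean_reward = float(scores[elite_idx].mean())
        eval_rewards.append((steps_done, elite_mean_reward))
        if elite_mean_reward > best[0]:
            best = (elite_mean_reward, mean.copy())
        if out_dir is not None and steps_done >= next_checkpoint:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            path = out / f"checkpoint_{steps_done}.json"
            path.write_text(json.dumps({"steps": steps_done,
                                        "schedule": mean.tolist()}))
            checkpoints.append(str(path))
            next_checkpoint += cfg.checkpoint_freq

    policy = FixedStrategy("cem", best[1])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        best_path = out / "best_policy.json"
        best_path.write_text(json.dumps({"schedule": best[1].tolist()}))
        checkpoints.append(str(best_path))
    return TrainResult(policy, eval_rewards, steps_done, checkpoints)


def run_training(env_factory, cfg: TrainConfig, out_dir=None,
                 backend=None) -> TrainResult:
    """Train a policy; deep-RL algorithms delegate to an injected backend.

    ``backend`` is a callable ``(env_factory, cfg, backend_kwargs)`` wrapping
    an external RL library.  The built-in algorithm is ``CEM``.
    """
    algo = cfg.algorithm.upper()
    if algo == "CEM":
        return train_cem(env_factory, cfg, out_dir=out_dir)
    if algo not in ALGO_PRESETS:
        raise ValueError(f"unknown algorithm: {cfg.algorithm!r}")
    if backend is None:
        raise MissingRLBackendError(
            f"{algo} requires an injected deep-RL backend; "
            "pass backend=... or use algorithm='CEM'")
    return backend(env_factory, cfg, to_backend_kwargs(cfg))


# --------------------------------------------------------------------------
# reward-weight sweep and Pareto frontier
# --------------------------------------------------------------------------

@dataclass
class ParetoPoint:
    alpha: float
    beta: float
    yield_score: float
    resource_score: float
    mean_reward: float
    dominated: bool = False


def _dominates(a: ParetoPoint, b: ParetoPoint) -> bool:
    """a dominates b: no worse in both objectives, strictly better in one
    (maximize yield, minimize resource use)."""
    return (a.yield_score >= b.yield_score
            and a.resource_score <= b.resource_score
            and (a.yield_score > b.yield_score
                 or a.resource_score < b.resource_score))


def pareto_frontier(points: list[ParetoPoint]) -> list[ParetoPoint]:
    """Mark dominated points; return the non-dominated subset (ties kept)."""
    for p in points:
        p.dominated = any(_dominates(q, p) for q in points if q is not p)
    return [p for p in points if not p.dominated]


def sweep_reward_weights(env_factory_for, alphas, betas,
                         steps_per_cell: int = 2000, n_eval_episodes: int = 5,
                         seed: int = 0) -> list[ParetoPoint]:
    """Train one policy per (α, β) cell and summarize its trade-off.

    ``env_factory_for(alpha, beta)`` builds an environment whose reward uses
    the given weights.  Yield/resource scores are the evaluation-mean
    per-step crop reward and resource penalty, which are weight-independent
    and hence comparable across cells.  All cells share common random
    numbers (the same training and evaluation seeds), so cross-cell
    differences reflect the weights rather than sampling noise.
    """
    alphas = list(alphas)
    betas = list(betas)
    if not alphas or not betas:
        raise ValueError("alpha and beta grids must be non-empty")
    points = []
    for alpha in alphas:
        for beta in betas:
            cell_seed = seed
            factory = lambda a=alpha, b=beta: env_factory_for(a, b)
            cfg = TrainConfig(algorithm="CEM", total_steps=steps_per_cell,
                              seed=cell_seed, fixed_episode_seed=cell_seed,
                              schedule_weeks=1)
            result = train_cem(factory, cfg)
            report = evaluate_policy(result.policy, factory,
                                     n_episodes=n_eval_episodes,
                                     seed=cell_seed)
            points.append(ParetoPoint(
                alpha=float(alpha), beta=float(beta),
                yield_score=report.mean_yield_score,
                resource_score=report.mean_resource_score,
                mean_reward=report.mean_reward))
    pareto_frontier(points)
    return points


# --------------------------------------------------------------------------
# report export
# --------------------------------------------------------------------------

def export_deviation_report(report: pd.DataFrame, path) -> None:
    report[["parameter", "agent", "mean_others", "deviation_pct"]].to_csv(
        path, index=False)


def export_pareto_points(points: list[ParetoPoint], path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in points])[
        ["alpha", "beta", "yield_score", "resource_score",
         "mean_reward", "dominated"]].to_csv(path, index=False)


def load_pareto_points(path) -> list[ParetoPoint]:
    df = pd.read_csv(path)
    return [ParetoPoint(**row) for row in df.to_dict("records")]


def export_eval_reports(reports: list[EvalReport], path) -> None:
    rows = []
    for r in reports:
        row = {"name": r.name, "n_episodes": r.n_episodes,
               "mean_reward": r.mean_reward, "sd_reward": r.sd_reward,
               "mean_yield_score": r.mean_yield_score,
               "mean_resource_score": r.mean_resource_score,
               "mean_episode_length": r.mean_episode_length}
        row.update({f"crop_{k}": v for k, v in r.mean_crop.items()})
        row.update({f"res_{k}": v
                    for k, v in r.mean_weekly_resources.items()})
        rows.append(row)
    columns = list(rows[0].keys()) if rows else [
        "name", "n_episodes", "mean_reward", "sd_reward"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
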