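# ghctl — autonomous greenhouse control testbed

`ghctl` is a Python toolkit for studying reinforcement-learning-style
control of greenhouse climate for a cherry-tomato crop.  It is aimed at
researchers in controlled-environment agriculture and at control/ML people
who want a fast, fully seeded greenhouse benchmark: a stochastic weather
generator with multi-day extremes, a parametric greenhouse-dynamics oracle
that emits datasets in the public autonomous-greenhouse-challenge table
layout, trainable surrogate estimators (feed-forward climate model,
Conv1D+LSTM crop and resource models with random-forest feature selection),
an exactly specified multi-objective reward, a weekly-cycle episodic control
environment, and an evaluation bench.

## The control problem

An agent sets eight weekly setpoints (CO₂, two screens, heating and
ventilation temperatures, irrigation interval, drain pH, white LED
intensity), each chosen in [0, 1] and scaled to physical ranges.  One step
advances 2016 five-minute timesteps (one week); an episode is a 23-week
production cycle.  The per-step reward balances crop growth against
resource consumption:

    reward = α·crop_reward − β·resource_penalty + punishment + big_reward
             + δ·efficiency_factor − γ·stability_penalty

where `crop_reward = w₁·elong/max + w₂·thick/max + w₃·trusses/max` with
weights (0.4, 0.3, 0.3), `resource_penalty` is the (0.2, 0.3, 0.2, 0.3)-
weighted sum of normalized heat, CO₂, electricity, and irrigation use,
`efficiency_factor = crop_reward/(1 + resource_penalty)`,
`stability_penalty = s·Σ|Δaction|`, and threshold incentives add +0.2 per
crop parameter ≥ 0.7, +1.0 when all reach 0.8, −0.1 per parameter < 0.5,
−1.0 when all fall below 0.5, and −1.0 plus episode termination on resource
overuse.  Defaults: α = 1.0, β = 0.2, δ = 0.01, γ = s = 0.001.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

```python
import numpy as np
from ghctl import GreenhouseEnv
from ghctl.bench import TrainConfig, run_training, evaluate_policy, \
    constant_strategy, challenge_deviation_report

# benchmark table: per-resource deviation of the agent vs the other teams
print(challenge_deviation_report().to_string(index=False,
      float_format=lambda v: f"{v:.2f}"))

# train a policy-search agent at desk scale and compare with a baseline
result = run_training(GreenhouseEnv,
                      TrainConfig(algorithm="CEM", total_steps=6000, seed=42))
agent = evaluate_policy(result.policy, GreenhouseEnv, n_episodes=20, seed=7)
mid = evaluate_policy(constant_strategy("constant-mid", np.full(8, 0.5)),
                      GreenhouseEnv, n_episodes=20, seed=7)
print(f"agent {agent.mean_reward:.2f} ± {agent.sd_reward:.2f}  "
      f"vs constant-mid {mid.mean_reward:.2f}")
```

Output:

```
 parameter  agent  mean_others  deviation_pct
       CO2  55.09        56.13          -1.86
 Elec high  76.45        75.97           0.63
  Elec low  89.58        88.18           1.59
      Heat  49.56        48.78           1.60
Irrigation   8.31        10.94         -24.05
agent 37.91 ± 2.32  vs constant-mid 12.43
```

The deviation table recomputes, from the published cumulative resource
usage of the six challenge strategies, how far the learning agent deviates
from their average: 24 % less irrigation and 1.9 % less CO₂ at the price of
slightly more heat and electricity.  The second line shows a cross-entropy
policy search after only 6,000 environment steps earning roughly three
times the cumulative reward of a fixed mid-range setpoint schedule over 20
seeded evaluation episodes.

The same functionality is available from the shell:

```bash
ghctl simulate-weather --days 7 --mode stochastic --seed 1 --out weather.csv
ghctl make-dataset --weeks 12 --seed 1 --out data/
ghctl train-estimators --weeks 40 --seed 1 --out models/
ghctl train-agent --algo cem --steps 6000 --seed 42 --out runs/
ghctl evaluate --policy runs/best_policy.json --episodes 20
ghctl deviate
ghctl sweep --alphas 0.25,1,4 --betas 0.1,1,4 --out sweep.csv
```

## Layout

```
src/ghctl/
  weather.py     stochastic outside-weather generator + table IO
  oracle.py      parametric greenhouse dynamics + dataset emission
  _nn.py         numpy MLP / Conv1D+LSTM core (MAE loss, Adam)
  estimators.py  surrogate training, normalization, feature selection
  rewards.py     multi-objective reward engine + termination rules
  env.py         weekly-cycle episodic control environment
  bench.py       baselines, CEM trainer, deviation ratios, Pareto sweep
  challenge.py   published challenge comparison tables
  cli.py         `ghctl` command-line interface
```
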