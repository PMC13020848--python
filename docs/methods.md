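# Methods

`ghctl` is a virtual testbed for autonomous greenhouse climate control of a
cherry-tomato crop.  It couples a stochastic outside-weather generator, a
parametric greenhouse-dynamics "oracle", trainable surrogate estimators of
those dynamics, a multi-objective reward engine, a weekly-cycle episodic
control environment, and an evaluation bench.  This note records the models,
the parameters that matter, the numerical conventions, and what the synthetic
setting does and does not establish about real greenhouses.

## Time structure

Everything shares one time grid: 5-minute weather records, hourly indoor
climate, daily resource totals, weekly crop observations.  One environment
step is one crop-registration week — 2016 five-minute records, reduced
internally to 168 hourly climate states, 7 daily resource rows, and one
weekly crop increment.  An episode is a 23-week production cycle; it can end
earlier on resource overuse or sustained crop-quality failure.

## Weather generator (`ghctl.weather`)

Each channel follows

    x(t) = seasonal(t) + diurnal(t) + AR(1) noise(t) + regime offset(t).

The seasonal term is an annual sinusoid peaking in mid-July; the diurnal term
peaks mid-afternoon (temperature) or at night (relative humidity).  AR(1)
innovations give short-term persistence (temperature ρ = 0.98 on the 5-minute
grid ≈ multi-hour memory).  Solar radiation instead uses a clear-sky
half-sine over a season-dependent daylight window multiplied by a slowly
varying logistic cloudiness factor, and is exactly zero at night; PAR is
2.1 µmol/J of global radiation.  `RadSum` is the running daily integral of
`Iglob` (J/cm², reset at midnight).  Rain is an hourly two-state Markov
chain; wind direction a reflected random walk on [0, 128].

Extreme regimes — multi-day heatwaves (+8 °C), cold spells (−7 °C), and
prolonged low-radiation periods (cloud factor × 0.25) — start with a per-day
probability and last 2–5 days.  The generator reports sampled events so
tests can check the realized mean shift against offset × coverage.

Defaults describe a temperate season starting at day-of-year 60 (early
March), matching a spring-planted production cycle.  Column names and units
follow the public autonomous-greenhouse-challenge table layout so real CSV
exports drop in unchanged.

## Dynamics oracle (`ghctl.oracle`)

The oracle is a deliberately simple stand-in for a physical compartment —
first-order relaxation per climate channel with qualitatively correct
couplings, not a physics-grade model (no radiative transfer, no exact
psychrometrics):

* **Air temperature** relaxes (rate 0.7 h⁻¹) toward a convex combination of
  the heating setpoint, ventilation setpoint, and outside temperature plus a
  solar gain term attenuated by closed screens; heating lifts it toward the
  heating setpoint and creates a *heating demand* in degree-hours;
  vents open proportionally above the ventilation setpoint and cool with a
  slope-bounded (tanh) term so that the map stays monotone in the setpoints.
* **CO₂** follows a ppm mass balance: infiltration and ventilation leaks
  plus a PAR-proportional photosynthetic draw-down must be replenished by
  dosing for the concentration to track its setpoint; dosing (kg/ha·h) is
  proportional to the injected ppm.
* **Humidity deficit** tracks its setpoint, modulated by ventilation and
  irrigation; relative humidity follows from a cubic saturation-density
  polynomial in temperature.
* **Light**: sun PAR through glass (transmission 0.6) and screens (blackout
  blocks 90 %, energy screen 25 %), plus HPS (180 µmol/m²·s at 100 %) and
  LED (120 µmol/m²·s at intensity 1000) lamps that switch on when outside
  radiation falls below 50 W/m².
* **Irrigation**: supply events spaced by the interval setpoint inside a
  04:00–20:00 window, 0.28 L/m² per event scaled by the day's radiation.
* **EC/pH of drain** are slow seeded random walks; pH tracks the drain-pH
  setpoint (the drain pH appears both as an action and as a measured state;
  we interpret the state as tracking the setpoint — flagged as an
  interpretation).

Daily resources: heating energy = 0.055 MJ/m² per degree-hour of demand
(screen insulation reduces demand by up to 35 %); lamp electricity split at
the 07:00–23:00 peak boundary; CO₂ use integrated from dosing; irrigation
from the supply events.

Weekly crop increments are separable saturating responses

    increment = max · f_T(mean Tair) · f_PAR(weekly mol) · f_CO2 · f_water,

with a Gaussian-shoulder optimum band of 19–23 °C, a Michaelis–Menten PAR
response referenced to 180 mol/m²·week (≈ 26 mol/m²·day DLI, the commercial
tomato lighting target — the crop stays light-limited under temperate spring
radiation, as in practice), a concave CO₂ response referenced to 800 ppm,
and a concave water-adequacy response against a 14 L/m²·week demand.  Maxima
are 18 cm stem elongation, 1.1 mm stem thickening, and 1.3 new trusses per
stem and week; cumulative trusses accumulate monotonically.

All coefficients live in one dataclass (`OracleParams`) so tests can build
closed-form-checkable degenerate cases (no noise, constant weather).

## Surrogate estimators (`ghctl.estimators`)

Three models learn the oracle from its emitted tables, exactly as a
data-driven controller would have to learn a real compartment:

* **Climate estimator** — feed-forward network, two ReLU hidden layers
  (256/128 by default), mapping hourly outside weather + control setpoints +
  a days-since-transplant feature to the 18 indoor-climate channels.
* **Crop estimator** — 1-D convolution (kernel 3, 16 channels) + LSTM
  (hidden 32) over the 7 daily aggregate rows of a week, predicting the
  three weekly crop increments.
* **Resource estimator** — same architecture over the 24 hourly rows of a
  day, predicting the five daily resource totals.

All features and targets are min–max normalized to [0, 1] (constant columns
rejected); training minimizes mean absolute error with Adam on an in-repo
numpy implementation whose gradients are finite-difference-checked in the
test suite.  Predictions are clamped to [0, 1] before denormalization so
downstream reward inputs stay in range.  Held-out MAE is reported on a
seeded 20 % split.  Feature selection ranks predictors by random-forest
importance (one forest per target, normalized importances averaged) and
retrains on the top-k set; on oracle data the selected models stay within
+0.02 normalized MAE of the full-feature models while using fewer
parameters.

Typical held-out normalized MAE on low-noise oracle data at the sizes used
by the acceptance script (120 weeks for climate/resources, 200 weeks for
crop): ≈ 0.017 (climate), ≈ 0.035 (crop), ≈ 0.012 (resources).  These are
recovery checks of a smooth synthetic system — they show the architectures
and pipeline work, not that real-greenhouse error would be this small.

## Reward engine (`ghctl.rewards`)

Per weekly step:

    reward = α·crop_reward − β·resource_penalty + punishment + big_reward
             + δ·efficiency_factor − γ·stability_penalty

with α = 1.0, β = 0.2, δ = 0.01, γ = 0.001.  `crop_reward` is the
(0.4, 0.3, 0.3)-weighted sum of the max-normalized weekly crop increments;
`resource_penalty` the (0.2, 0.3, 0.2, 0.3)-weighted sum of normalized heat,
CO₂, electricity (peak + off-peak combined against one maximum), and
irrigation; `stability_penalty` = s·Σ|Δaction| with s = 0.001;
`efficiency_factor` = crop_reward/(1 + resource_penalty).  Threshold
incentives: +0.2 per crop parameter ≥ 0.7 and +1.0 more when all three reach
0.8; −0.1 per parameter < 0.5 and −1.0 more when all three fall below 0.5;
exceeding any weekly resource-overuse threshold costs 1.0 and terminates the
episode.

Conventions worth stating explicitly:

* The stability term is defined as a non-negative *penalty*, so it enters
  the total with a minus sign; adding it would reward abrupt actions.  Both
  the outer γ and inner s scales are applied literally by default (an
  effective 10⁻⁶ per unit L1 change); `collapse_stability_scaling` folds
  them into a single 0.001.
* Per-parameter bonuses and the all-parameter bonuses stack additively by
  default; `exclusive_bonuses` switches to replace-semantics.
* Normalization maxima are dataset-level constants.  The defaults are the
  observed weekly maxima of a seeded random-policy reference dataset on the
  oracle (85 MJ/m² heat, 2.6 kg/m² CO₂, 11 kWh/m² electricity, 82 L/m²
  irrigation); crop maxima coincide with the oracle's optimal-condition
  increments.  Overuse thresholds default to 0.9 × each maximum.
* Quality-failure termination requires two consecutive all-below-0.5 weeks
  (a documented default; single bad weeks happen in dull weather).

An independent straight-line re-implementation of the full reward, written
in the tests with no shared code, agrees with the engine to 1e-12 on 10,000
random inputs.

## Environment (`ghctl.env`)

Standard episodic contract: `reset(seed) -> (obs, info)`,
`step(action) -> (obs, reward, terminated, truncated, info)`.  The action is
an 8-vector in [0, 1] mapped affinely to physical ranges (CO₂ 400–1000 ppm,
heating 14–26 °C, ventilation 16–30 °C, irrigation interval 30–360 min,
drain pH 5.0–6.5, white LED 0–1000; the two screens are binary and threshold
at 0.5).  Out-of-range actions are clipped with a logged warning, following
continuous-control conventions.  Uncontrolled setpoints are held at
documented per-episode constants.  The observation is a dictionary of
normalized components: last climate state (18), last weekly crop increments
(3), last weekly resources (5), the coming week's weather summary (10
channel means + radiation sum), and the week index.

`weather_mode="stochastic"` regenerates the 23-week weather realization each
episode from the reset seed; `"historical"` replays one fixed seeded season.
Backends are interchangeable: the oracle, or a bundle of trained estimators
(climate → resources → crop, chained exactly as the weekly cycle describes).
Every step's `info` carries the full reward decomposition, physical
setpoints, weekly and cumulative resources; the environment reward always
equals the reward engine applied to those logged states.

## Bench (`ghctl.bench`)

*Deviation ratio*: (agent − mean of others)/mean of others × 100, applied
per resource to a strategies × resources table.  The published
challenge comparison table ships as a packaged constant and the ratios are
recomputed from it at run time.

*Training*: the shipped trainer is a cross-entropy-method (CEM) search over
weekly setpoint schedules (population 20, elite 30 %, smoothed updates),
scored by seeded episodes and budgeted in environment steps.  The published
deep-RL hyperparameter configurations (TD3/SAC/DDPG/PPO) are mapped
field-for-field to backend keyword dictionaries for use with an injected RL
library; without an injected backend those algorithms raise a clear error
rather than silently substituting.  At desk scale (6,000 steps ≈ 260
episodes) the CEM agent reaches ≈ 47 mean cumulative reward versus ≈ 12 for
a constant mid-range strategy and ≈ 5 for uniform-random actions.

*Reward-weight sweep*: one policy is trained per (α, β) cell and summarized
by weight-independent scores — mean per-step crop reward (yield) and mean
per-step resource penalty.  Three variance-reduction choices make the trend
measurable at desk budgets (5–10k steps/cell): all cells share common random
numbers; candidates are scored on one fixed weather episode (sample-path
optimization), making each cell's search deterministic; and the sweep
searches constant policies (8 parameters) so cells converge within budget.
The default grid α, β ∈ {0.25, 1, 4} × {0.1, 1, 4} is deliberately wide: at
the default β = 0.2 the resource cost is small against the crop-quality
bonuses and all optima coincide (the narrow-Pareto-band regime).  Because
yield saturates whenever resources are nearly free, the yield trend is
asserted against the relative price α/β (rank correlation ≈ +0.7 to +0.8
across seeds) while resource use falls directly with β (≈ −0.8).  The
frontier uses maximize-yield/minimize-resource dominance, strict in at least
one objective, ties kept.

## What the synthetic setting does not show

The oracle is smooth, low-dimensional, and exactly the process the
estimators and agent are evaluated on; real compartments have actuator
dynamics, delays, spatial gradients, sensor faults, and crop physiology far
beyond three weekly scalars.  Passing tests demonstrate that the pipeline —
data layout, estimator training, reward arithmetic, episode mechanics,
benchmark analytics — is correct and reproducible, not that the specific
MAE values or reward magnitudes transfer to a physical greenhouse.
Published full-scale results (dataset-dependent MAE values and 120,000-step
deep-RL rewards) are therefore treated as context, replaced here by
property-based analogues at desk scale.

## Numerical conventions

Every stochastic component takes an explicit seed; seeded runs are
bit-reproducible on one machine.  Derived seeds stay below 2³¹.  Min–max
normalization rejects constant features rather than dividing by zero.
Crop and efficiency terms are exactly 1.0/left-identity at their boundary
conditions, asserted without tolerance.  CEM clips candidates into [0, 1];
its standard deviation is floored at 0.02 to avoid premature collapse.
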