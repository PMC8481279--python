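# social-diffusion

Agent-based simulation of how social conventions change: a committed
minority pushes an alternative against an established status quo in a
well-mixed population whose members weigh **social coordination**,
**inertia** and **trend-seeking** when revising their choice.  The
package is aimed at computational social scientists who want to study
tipping points, take-off delays and the explosiveness of social
diffusion, and at experimentalists who need to classify participants of
multi-round group games and calibrate the model against them.

## The model

Each of `n` agents plays one of two strategies, `0` (status quo) or `1`
(alternative).  Every round, each non-committed agent `v` redraws its
strategy by noisy best response (log-linear / logit learning):

    P[x_v(t+1) = 1] = exp(β π_v(1)) / (exp(β π_v(0)) + exp(β π_v(1)))

with payoffs that are a convex combination (`b + k + r = 1`) of three
mechanisms:

    π_v(1) = b/(n−1) · Σ_{w≠v} x_w(t)   +   k · x_v(t)   +   r · x̂_v(t)

— coordination with the others' current play, inertia toward the
agent's own current strategy, and trend-seeking via

    x̂_v(t) = ½ [ 1 + 1/(n−1) · Σ_{w≠v} (x_w(t) − x_w(t−1)) ],

which exceeds ½ exactly when adoption of the alternative grew in the
last round.  `π_v(0)` is the mirror image, so `π_v(0) + π_v(1) = 1`.
A committed minority is frozen on the alternative; the remaining
*regular* agents split into two behavioural classes: **explorers**
(low inertia, strong trend-seeking; calibrated `b=0.48, k=0.10,
r=0.42`) and **non-explorers** (`b=0.42, k=0.42, r=0.16`), with shared
rationality `β=7.8`.

Diffusion observables of a run: the diffusion time `T*` (first round
with ≥ 99% adoption), the take-off time `T̄` (last round at or below
40% adoption), the transition time `ΔT = T* − T̄` (small = explosive),
and per-agent switching rates `y_v` (strategy revisions per round up to
`T*`, discounting the final switch into consensus).

Beyond simulation, the package processes 12-seat multi-round trial
records (8–10 participants plus 2–4 committed bots, 24-round cap):
irregular-behaviour cleaning, a behavioural discriminant
`Δ_v = sw_v/T* + min_v − maj_v/2` that separates explorers from
non-explorers, a synthetic-trial generator, and a Monte Carlo
grid-search calibration of `(β, k_e, r_e, k_f, r_f)` that matches
simulated class switching-rate statistics to empirical ones through a
weighted absolute-error cost.

## Worked example

```python
import numpy as np
from social_diffusion import PopulationSpec, SimulationConfig, run_campaign

spec = PopulationSpec(n=200, committed_count=50, rho_e=0.2)   # 25% committed
results = run_campaign([spec], SimulationConfig(seed=7), reps=50)
cell = results.summary().iloc[0]
print(f"mean take-off time  T̄ = {cell.mean_t_bar:.1f} rounds")
print(f"mean transition time ΔT = {cell.mean_delta_t:.1f} rounds")
print(f"rounds per switch     = {cell.rounds_per_switch:.1f}")
```

prints

```
mean take-off time  T̄ = 85.7 rounds
mean transition time ΔT = 29.6 rounds
rounds per switch     = 19.1
```

The population lingers in a meta-stable, status-quo-dominated state for
some 86 rounds, then flips to the alternative in under 30 — delayed
take-off followed by an explosive transition — while a regular agent
revises its strategy only about once every 19 rounds.  Raising the
explorer fraction to `rho_e=0.6` cuts the mean take-off time to ~15
rounds and the interval between switches to ~10.5.

The same objects drive the CLI:

```sh
social-diffusion generate --n-trials 20 --seed 3 --out out/
social-diffusion classify --trials out/trials.csv --out out/
social-diffusion calibrate --trials out/trials.csv --config grid.yaml --seed 5 --out out/
```

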