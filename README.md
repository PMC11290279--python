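# platformsim

Simulation study of **heterogeneity in two-stage platform trials** with
normally distributed outcomes: what happens to hypothesis tests and
treatment-effect estimates when an arm is added mid-trial and the
stages differ — in treatment effects, in outcome variance, or through
shared cohort effects.

A platform trial keeps one control arm recruiting while intervention
arms come and go.  When a new arm C joins a trial that started with
control (0) and interventions A and B, the comparison C vs control can
either use only *concurrent* controls (randomized while C was open) or
pool the earlier *non-concurrent* control data.  If the stages are not
exchangeable — a step time trend τ, a shared random cohort effect σ_c,
or extra stage-two variance σ_e — pooling can wreck the type-I error,
and different regression models silently estimate different estimands.
This package quantifies both effects.

## What is implemented

* **Designs** (`platformsim.design`): the three timing settings (arm C
  added after 25/50/75% of recruitment, 120 subjects per arm) with
  two-step randomization ratios, and exact noncentral-t power.
* **Data generation** (`platformsim.datagen`): stage-wise multivariate
  normal outcomes, y = μ_jk + τ·1{k=2} + u_k + ε with
  u_k ~ N(0, σ_c²) shared per stage and Var(ε) = σ² + σ_e²·1{k=2};
  the scenario grid (S0, SC.m, SC.b, SA.m, SA.b) × {σ_c, σ_e} ∈
  {0, 0.38}² × τ ∈ {0, −0.5}.
* **Testing** (`platformsim.testing`): one-sided pooled-variance
  t-tests with concurrent or pooled controls, Bonferroni, closed
  Dunnett testing (multivariate-t max-t p-values via deterministic
  Gauss quadrature, including mixed control pools), and a two-stage
  Fisher combination test with closed testing
  (reject when p₁p₂ ≤ exp(−χ²₄(1−α)/2)).
* **Estimation** (`platformsim.estimation`): OLS models M0, M.stage,
  M.stageXA, M.stageXAXB and the pairwise trials analysis M.new —
  control-data duplication per comparison with cluster-robust sandwich
  standard errors.  M0/M.new point estimates equal the stage-weighted
  mean difference Σ_k w_jk X̄_jk − Σ_k w_0k X̄_0k exactly.
* **Engine** (`platformsim.simengine`): seeded replication loop,
  rejection-rate and estimate summaries with Monte-Carlo bands, rMSE,
  YAML configuration, tidy CSV output, and a CLI.

The numbered scripts under `analysis/` run the study end to end:
`01_design_power.py`, `02_null_calibration.py`,
`03_nonconcurrent_controls.py`, `04_estimator_means.py`, `05_rmse.py`.
Each writes its table under `results/` and accepts `--reps`/`--seed`.

## Worked example

```python
import numpy as np
from platformsim import (build_design, make_scenario, simulate_trial,
                         run_all_strategies, fit_model)

design = build_design("one")                  # arm C added at midpoint
scenario = make_scenario("S0", variance_scenario=2, tau=0.0)  # sigma_c = 0.38
data = simulate_trial(design, scenario, np.random.default_rng(72))

out = run_all_strategies(data, alpha=0.05)
print(out["T-test C"].p_values, out["T-test C-nc"].p_values)

est = fit_model(data, "M.new")
print({j: round(v, 3) for j, v in est.theta.items()})
```

prints

```
{'C': 0.8453…} {'C': 0.0086…}
{'A': 0.123, 'B': 0.039, 'C': -0.163}
```

— a deliberately stark draw: the pooled-control test for comparison C
rejects (p = 0.009) while the concurrent test does not come close
(p = 0.85), even though the null is true.  The stage-one cohort
happened to score low, dragging the pooled control mean down, and the
pooled variance estimate understates the uncertainty of the contrast.
Repeated 5000 times, the pooled-control t-test rejects about 23% of the
time at nominal 5%, while every concurrent-control strategy stays at or
below the nominal level; the pairwise-analysis estimates stay centred
on zero.

At the command line:

```sh
platformsim power --n 120 --delta 0.38      # power = 0.9015
platformsim run --config cfg.yaml --reps 2000 --out results/
platformsim replicate --config cfg.yaml --index 0   # dump one dataset
```

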