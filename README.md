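# informdrop

Models for longitudinal health-related quality-of-life (HRQoL) scores under
informative dropout, with a synthetic two-arm trial generator for validating
them by parameter recovery.

## The problem

In oncology trials, HRQoL is measured repeatedly with 0–100 questionnaire
dimension scores. Patients stop returning questionnaires — often because
their health deteriorates — so the missingness can depend on the very scores
that are missing (missing not at random, MNAR). A linear mixed model (LMM)
fitted to the observed data is only valid when missingness depends on
observed data alone (MAR); under informative dropout it is biased.

`informdrop` implements the LMM and the three standard joint approaches to
monotone informative dropout, sharing one trajectory sub-model

    Y_i(t_j) = β₀ + β₁ t_j + β₂ (arm_i × t_j) + b₀ᵢ + b₁ᵢ t_j + ε_ij,
    (b₀ᵢ, b₁ᵢ) ~ N(0, G),   ε_ij ~ N(0, σ²)

where `β₁` is the control-arm slope (points/month) and `β₂` the difference
between arms. The dropout index `D_i` is the last visit with an available
score (`D_i = J` for completers). The four estimators are:

* **LMM** (`informdrop.lmm`) — maximum/restricted maximum likelihood on the
  observed data; the MAR reference.
* **Selection model, SM** (`informdrop.selection_model`) — factorizes
  [scores] × [dropout | scores] with a visit-wise logistic hazard
  `logit P(D=j | D≥j) = ψ₀ + ψ₁ Y(t_j) + ψ₂ Y(t_{j+1})`; a non-zero `ψ₂`
  (the coefficient of the *unobserved* current score) indicates MNAR. The
  likelihood integrates the hazard over the Gaussian conditional law of the
  unobserved score (Gauss–Hermite quadrature).
* **Pattern-mixture model, PMM** (`informdrop.pattern_mixture`) —
  factorizes [pattern] × [scores | pattern]: pattern-specific fixed effects
  from a single LMM with pattern interactions, multinomial pattern
  proportions π_k, and marginal effects `β_l = Σ_k π_k β_l^k` with
  delta-method confidence intervals.
* **Shared-parameter model, SPM** (`informdrop.spm`) — a joint model
  linking the trajectory to a continuous-time dropout hazard
  `λ(t) = ξ_q(t) exp{γ·arm + α·Y*(t)}` through the error-free current value
  `Y*(t)`; piecewise-constant baseline hazard (knots at months 1.25, 3, 4,
  6, 12, 24), adaptive Gauss–Hermite integration over the random effects,
  and hazard-ratio summaries (the dropout-risk multiplier for a given score
  change) via `dropout_hazard_ratio`.

`informdrop.synthetic_data` generates trials with the same structure (two
arms, eight visits at months 0, 1.25, 3, 4, 6, 12, 24, 36) under MCAR, MAR,
or MNAR dropout — visit-wise logistic or continuous-time hazard — keeping
the complete trajectories, random effects, and latent dropout times as
ground truth. `informdrop.report` fits all four models on one dataset and
tabulates estimates, Wald intervals, and predicted trajectories.

## Worked example

```python
import numpy as np
from informdrop import (SimConfig, DKParams, simulate_trial, run_comparison)

# a trial of 2 x 125 subjects whose dropout probability increases with the
# (unobserved) current score: psi2 = 0.06 per point
cfg = SimConfig(n_per_arm=125, mechanism="mnar_dk",
                dk=DKParams(-4.5, 0.0, 0.06), seed=200)
trial = simulate_trial(cfg)
res = run_comparison(trial.dataset)
print(res.table[res.table.parameter == "beta1"]
      [["model", "estimate", "se", "p"]].to_string(index=False))
```

prints

```
model  estimate       se        p
  lmm -0.258419 0.120216 0.031585
   sm  0.443785 0.229358 0.053002
  pmm -1.628167 0.917040 0.075822
  spm  0.205198 0.195548 0.294019
```

The generating control-arm slope is 0.5 points/month. The MAR-only LMM is
badly biased (−0.26; higher-scoring subjects drop out preferentially, so the
observed trajectories sag), the selection model — whose dropout sub-model
matches the generator — recovers the slope (0.44 ± 0.23), the joint model
corrects part of the bias (0.21), and the pattern-mixture marginal slope
extrapolates the early-dropout patterns linearly and lands low (−1.63) with
a much wider interval: the same qualitative ordering these models show on
real trial data.

A command-line interface wraps the same pipeline:

```sh
informdrop simulate -c config.yaml -o sim/
informdrop fit --data sim/observed.csv --model all -o fits/
informdrop report --data sim/observed.csv -o report/ --plots
```

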