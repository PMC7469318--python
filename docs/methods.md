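# Methods

This note records the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one defensible option existed.

## Trajectory sub-model

All four estimators share a random-coefficients linear mixed model for the
0–100 score at the planned visit times t ∈ {0, 1.25, 3, 4, 6, 12, 24, 36}
months:

    Y_i(t) = β₀ + β₁ t + β₂ (arm_i × t) + b₀ᵢ + b₁ᵢ t + ε_i(t)

with (b₀ᵢ, b₁ᵢ) ~ N(0, G) and ε ~ N(0, σ²). There is no main arm effect:
randomization justifies a common baseline, so the arm enters only through
the slope difference β₂ (points/month). Design matrices always use the
planned times, never the observed ones (observed times must match a
schedule entry within ±0.01 month).

Marginally Y_i ~ N(X_i β, Z_i G Z_iᵀ + σ² I). Fitting profiles the fixed
effects out by generalized least squares and optimizes the 4-parameter
profiled criterion over the log-Cholesky factor of G plus log σ² — an
unconstrained, smooth parametrization that enforces positive
(semi-)definiteness. Bounds (log-sd within [e⁻¹⁰, e⁸], log σ² within
[−24, 12]) keep the covariance numerically positive definite while letting
variance components go effectively to zero (the noise-free and
ordinary-least-squares limits). Optimization is L-BFGS-B with three
jittered restarts on failure; a non-finite profiled likelihood is mapped to
a large finite penalty so line searches can backtrack across the
near-singular region instead of aborting. The standalone LMM defaults to
REML (the convention of the mixed-model software family used for such
trials); the joint SM and SPM likelihoods use the ML form, which has a
clean joint-likelihood extension. Wald inference uses the normal reference
distribution with the GLS covariance (X V̂⁻¹ X)⁻¹; no small-sample
correction is applied.

Subjects are grouped by their availability mask, so each distinct
missingness pattern's covariance matrix is factorized once per likelihood
evaluation; with monotone dropout there are at most J such groups, which is
what makes the replicate-level simulations in the test suite affordable.

## Selection model (Diggle–Kenward)

Joint law = [marginal scores] × [dropout | scores], with visit-wise
logistic hazard logit P(D=j | D≥j) = ψ₀ + ψ₁ Y(t_j) + ψ₂ Y(t_{j+1}); ψ are
per raw point on the 0–100 scale. A subject with last visit d < J
contributes the observed-data normal density, survival factors
Π_{j<d}(1−p_j), and one integral of the hazard over the Gaussian
conditional law of the unobserved next score given the history (Schur
complement of the joint normal). The integral uses Gauss–Hermite quadrature
on the standardized conditional scale (default 30 nodes — the integrand is
logistic × Gaussian, essentially polynomial after the change of variables);
an adaptive Gauss–Kronrod rule is available as a cross-check. Subjects
observed only at baseline contribute the baseline density times the
integral term; completers contribute survival factors only. Hazard and
survival factors are evaluated through `log1p`/`logaddexp`, so extreme ψ
values during optimization cannot overflow.

The 10 parameters (β, log-Cholesky variance components, ψ) are maximized
jointly with L-BFGS-B on internally rescaled axes — the intercept is of
order 10² while ψ₁, ψ₂ are of order 10⁻² and the optimizer stalls without
rescaling. Initialization: REML LMM plus an MCAR logistic fit (ψ₁ = ψ₂ = 0,
ψ₀ at the crude per-opportunity dropout rate). Standard errors come from
the central-difference observed information; when that matrix is not
invertible the fit is returned with `hessian_ok = False` and no SEs, a
failure mode this model family is known for on real data.

## Pattern-mixture model

Dropout indices are grouped into K patterns (default: D∈{1,2,3},
D∈{4,5}, D∈{6}, D∈{7,8} — the last pattern merges late dropouts and
completers). Pattern proportions are multinomial, π̂_k = n_k/n with
covariance (diag π − ππᵀ)/n. The default fit is a single LMM with
pattern-indexed fixed effects and shared (G, σ²) — the "indicator
variables for the pattern" formulation — with a fully stratified variant
(independent LMM per pattern) retained for sensitivity. Marginal effects
are β_l = Σ_k π̂_k β̂_l^k with delta-method variance
wᵀΣ_β w + βᵀΣ_π β, treating β̂ and π̂ as independent (π̂ depends on
dropout only; β̂ is estimated conditionally on pattern). Weighting uses the
pooled π̂ for every effect by default; an arm-specific weighting (each
arm's slope weighted by that arm's own pattern proportions, interaction =
difference) is available, because with unbalanced pattern×arm tables the
two can differ noticeably and published analyses are not always explicit
about which they used. The marginal trajectory extrapolates every pattern's
straight line over the full schedule — deliberately, as the method
requires; this extrapolation is why PMM marginal slopes react so strongly
to steep early-dropout patterns.

Degenerate cases: patterns with fewer than two subjects are dropped (π̂
renormalized, flagged); a pattern whose subjects all fall in one arm loses
its interaction column, and β₂^k is treated as 0 in marginalization with a
prominent warning.

## Shared-parameter (joint) model

Scores and a continuous-time dropout process are conditionally independent
given the random effects. The hazard is λ(t) = ξ_q(t) exp{γ·arm + α·Y*(t)}
with Y*(t) = β₀ + b₀ + (β₁ + β₂·arm + b₁)t the error-free current value,
and a piecewise-constant baseline with internal knots at months 1.25, 3, 4,
6, 12, 24 (Q = 7 levels, log-parametrized; intervals left-closed,
right-open, the last open-ended). Because Y* is linear in t, the cumulative
hazard is a closed-form sum of per-interval terms
ξ_q e^{γ·arm+α(β₀+b₀)} (e^{αsu} − e^{αsl})/(αs), with the linear limit
substituted when |αs| is tiny.

**Dropout-time likelihood.** The recorded dropout time is the last visit
with an available score; completers are censored at month 36. All recorded
event times therefore lie on the visit grid, and two consequences follow.
First, subjects observed only at baseline have events at t = 0 with zero
at-risk exposure; under the exact-time density form
λ(T)^event e^{−Λ(T)}, each such subject contributes a factor whose
posterior expectation grows like exp(α²·Var(b₀|y)/2), making the joint
likelihood *unbounded* in α. Second, even away from t = 0 the within-interval
hazard shape (exponential in t through α) lets the likelihood concentrate
mass at the grid points. Both were observed in practice: optimizations ran
away to |α| ≈ 0.1–0.6 with log-likelihoods thousands of nats above the
generating values, stable under quadrature refinement — a genuine
degeneracy, not a numerical artifact. The default likelihood therefore
treats dropout as interval-censored between the last available and the
first missed visit, P(D=d | b) = S(t_d|b) − S(t_{d+1}|b) (completers:
S(t_J|b)), which is a bounded, proper probability and is exactly the
distribution a continuous-time dropout process induces on D. The
exact-time density form remains available (`form="exact"`) for diagnostics
and for the α = 0 decoupling identity, where it is benign.

**Integration over the random effects.** Default: a tensor Gauss–Hermite
rule (9 nodes/dimension) centered per subject at the *exact*
empirical-Bayes posterior of b implied by the current longitudinal
parameters. With that centering the Gaussian factors integrate exactly —
the subject contribution reduces to the marginal normal density times a
weighted posterior average of the dropout factor — so the rule cannot
reward parameter regions where it is inaccurate. The pseudo-adaptive
variant (nodes fixed at a preliminary REML fit's posteriors, importance
reweighted; `pseudo_adaptive_config`) is cheaper per evaluation and
matches the adaptive rule to ~10⁻¹² when evaluated at
centering-consistent parameters, but the e^{|u|²} reweighting is exploitable
far from the centering — the optimizer found regions where the fixed rule
overestimates the log-likelihood by hundreds of nats — so it is not the
default. Fitted log-likelihoods and standard errors agree to four to five
decimals between 3, 5, 9, and 25 nodes per dimension on trial-sized
datasets; the recovery simulations in the test suite and acceptance script
use 3–5 nodes on that basis, while single-fit defaults stay at 9.

Initialization: REML LMM for the trajectory, profile-likelihood
piecewise-exponential fit (α = 0) for (ξ, γ). The 16 parameters are
maximized with L-BFGS-B on rescaled axes; SEs from the central-difference
observed information, with baseline levels reported with log-scale
intervals (positivity).

The association summary `dropout_hazard_ratio(α, δ)` = exp(αδ) gives the
dropout-risk multiplier for a score change of δ points, with CI endpoints
transformed from α's interval.

## Synthetic-data generator

The generator emulates the structure of a two-arm esophageal-cancer trial:
~130 subjects per arm, eight visits at months 0–36, monotone dropout, high
cumulative dropout (~95%) concentrated early. Defaults, chosen once:
β = (60, 0.5, −0.13) points / points·month⁻¹ (global-health-like
magnitudes), G = diag(400, 0.25) (between-subject sd 20 points at baseline,
slope sd 0.5 points/month), σ² = 225 (residual sd 15 points) — typical
values for 0–100 cancer-trial questionnaire dimensions; MCAR dropout uses
ψ₀ = −0.6 (per-visit probability 0.354), which leaves ≈4.7% completers,
matching the emulated trial. The continuous-time mechanism defaults to a
decreasing baseline hazard ξ = (1.2, 1.0, 0.8, 0.5, 0.25, 0.15, 0.12)
events/month with γ = 0.2 and α = −0.02, giving ≈95% cumulative dropout
for a typical subject.

Visit-wise mechanisms draw dropout sequentially with probability
expit(ψ₀ + ψ₁y_j + ψ₂y_{j+1}) evaluated on the *complete* scores (the
current value is exactly the quantity the selection model treats as
unobserved). The continuous-time mechanism inverts each subject's
cumulative hazard analytically (inverse-transform sampling), censors at
month 36, records D as the last visit strictly before the drawn time, and
stores the latent time. The pattern mechanism draws a pattern label from
supplied proportions, simulates pattern-specific fixed effects, and places
D uniformly within the pattern's dropout indices. All randomness flows
from one PCG64 stream (`numpy.random.default_rng`), so a configuration and
seed reproduce byte-identical data across platforms.

What the generator does *not* emulate — and what passing recovery tests
therefore do not establish about real data: scores are unbounded Gaussian
(0–100 truncation is an opt-in stressor flagged on the dataset, violating
every model's assumptions by design); trajectories are linear in time with
no serial correlation beyond the random coefficients; dropout depends on
at most one lagged score and carries no covariates; death is not
distinguished from questionnaire non-response; there is no intermittent
missingness (the `monotonize` policy exists for real data that has it) and
no staggered entry.

## Numerical conventions and degenerate inputs

* Percentages in missingness summaries are rounded half-up to integers;
  raw fractions are kept alongside.
* Missing scores in files: empty field or literal `NA`; anything else
  non-numeric is an error naming the row. Subjects with no score at all
  are excluded with a logged count (the evaluable intent-to-treat rule).
* Monotonization policy `truncate_at_first_gap` blanks everything after a
  subject's first internal gap; the selection model refuses non-monotone
  input rather than silently handling it.
* Convergence: profiled/joint optimizations use ftol 10⁻¹⁰–10⁻¹², gtol
  10⁻⁶–10⁻⁷, with jittered restarts; non-convergence is flagged on the
  fit, never raised.
* No dropout events: SM drives ψ₀ to its guard bound with a warning; SPM
  returns the ML LMM with a degenerate survival part and a warning.
* Wald p-values are two-sided from the standard normal; estimates print to
  three decimals in the comparison table.

## Known limitations

* The SM's MNAR evidence (ψ̂₂) is driven entirely by the untestable
  normality of the complete-score distribution; the model is known to be
  fragile in exactly the settings it is used for, and the `hessian_ok`
  flag exists because its observed information is often near-singular.
* PMM marginal estimates inherit the linear-extrapolation assumption; with
  steep early patterns they can contradict the other three models while
  being internally consistent.
* The SPM's interval-censored dropout likelihood treats the visit grid as
  exact; clinically-timed events between visits (e.g. death) are only
  located to an interval.
* Delta-method PMM intervals undershoot the bootstrap by ~15% at trial
  size (the independence working assumption and conditioning on pattern
  sizes); the acceptance suite quantifies this.
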