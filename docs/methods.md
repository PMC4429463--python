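# Methods

## Model

`parfrail` implements parametric shared-frailty survival models for
clustered right-censored data. Conditional on a cluster-level frailty
`Z_i`, subjects are independent with hazard `Z_i·h_c(t|x_ij)`, so the
cluster survival copula is `S(t|x,z) = S_c(t|x)^z`. The conditional
hazard `h_c` combines one of three baseline families — exponential,
Weibull, log-logistic, parameterized by scale λ and shape ρ — with a
covariate formulation: proportional hazards (`H_c = H0·e^{x'β}`) or
accelerated failure time (`S_c(t|x) = S0(t·e^{−x'β})`). Defaults pair
exponential/Weibull with PH and log-logistic with AFT (a log-logistic
hazard is not proportional under covariate shifts, but the family is
closed under time rescaling); either can be overridden where valid, and
for the Weibull the two routes are the same model with `β_AFT = −β_PH/ρ`
— a fact the tests exploit as an internal consistency check.

The frailty acts multiplicatively on the conditional hazard for all
baselines, including the AFT-form log-logistic. Both frailty families are
constrained to mean 1 so the single dispersion parameter is the variance
θ; θ → 0 recovers independence.

The AFT location/scale view (intercept μ, scale σ) maps to the hazard
view by ρ = 1/σ, λ = exp(−μ/σ); the mapping is validated by exact
round-trip rather than against any external table, since published
(λ, ρ) values are generally rounded independently of (μ, σ).

## Marginal likelihood

A cluster with event count `d_i` and summed conditional cumulative hazard
`H_i` contributes

    log L_i = Σ_j δ_ij log h_c(t_ij|x_ij) + log[(−1)^{d_i} 𝓛^{(d_i)}(H_i)],

with `𝓛` the frailty Laplace transform. Derivative evaluation is the
numerical crux:

* gamma: `(−1)^d 𝓛^{(d)}(s) = (1+θs)^{−1/θ−d} ∏_{l<d}(1+lθ)`, accumulated
  in log space;
* inverse-Gaussian: `𝓛^{(d)}(s) = 𝓛(s)·Q_d(v)` with `v = (1+2θs)^{−1/2}`
  and `Q_{d+1} = −θv³Q_d' − vQ_d`. The signed polynomial `(−1)^d Q_d` has
  only nonnegative coefficients (verified symbolically in the tests up to
  d = 8), so the recursion is carried on log-coefficients with
  `logaddexp` and evaluates with no cancellation at any order. Bessel
  closed forms were deliberately avoided: half-integer Bessel functions
  underflow for moderately large `d·θ` while the polynomial route stays
  finite.

Derivative orders are capped at 200 per cluster (a cluster with more
events than that would need asymptotic handling that is out of scope);
the error message says how to raise the cap.

Kendall's τ uses `θ/(θ+2)` (gamma) and
`1/2 − 1/θ + (2/θ²)e^{2/θ}E₁(2/θ)` (inverse-Gaussian). `E₁` comes from
`scipy.special.exp1`; for `2/θ > 700`, where `e^{2/θ}` overflows, the
product `e^x E₁(x)` switches to a Lentz continued fraction, keeping τ
continuous down to θ → 0.

## Estimation

Maximization runs on unconstrained transforms (β, log λ, log ρ, log θ)
with L-BFGS-B and finite-difference gradients; tolerance 1e−10 on the
relative objective change, with wide box bounds for numerical safety
(log θ is floored at log 1e−8, which is operationally θ = 0). A frailty
model is initialized from the corresponding no-frailty fit plus θ₀ = 0.1.
Line searches occasionally stall on gradient noise exactly at the
optimum; a stall is accepted as convergence only when the projected
gradient is below 1e−5 relative to the objective, otherwise fitting
raises with a diagnostic trace. Fits are deterministic: same data and
options give bit-identical results.

Standard errors come from the inverse central-difference Hessian (step:
cube root of machine epsilon, scaled per parameter) with the delta method
back to the natural scale (θ, λ, ρ); Wald 95% intervals use z = 1.96.
For AFT fits, effects are reported as acceleration factors
`ϕ = exp(β)` with CI `exp(β ± 1.96·SE)`, starred when the CI excludes 1.
A singular Hessian flags SEs unavailable but still returns estimates.
AIC is `−2ℓ + 2p` with p counting β's, λ, ρ (where free) and θ (where
present).

The frailty-variance test compares nested fits with and without frailty.
Because θ = 0 lies on the boundary, the statistic `Λ = max(0, 2(ℓ₁−ℓ₀))`
is referred to the mixture `½χ²₀ + ½χ²₁`; null calibration of this
mixture is verified by simulation in the acceptance suite.

The univariable screen fits one single-covariate model per candidate
(default: no-frailty log-logistic AFT, which is cheap and matches the
reporting scale) and keeps covariates with any Wald-significant
non-reference level at α = 0.05. Wald screening was chosen over
score/LRT variants for consistency with the interval logic of the
acceleration table; whether screening models should themselves carry a
frailty term is configurable and off by default.

## Diagnostics

* Cox–Snell residuals default to the conditional form
  `r_ij = ẑ_i·Ĥ_c(t_ij|x_ij)` using the posterior-mean frailty; marginal
  residuals (`−log` of the frailty-marginal survival) are available by
  flag. Under a correct model the residuals behave as censored
  unit-exponential data, operationalized as the origin-constrained LS
  slope of their Nelson–Aalen cumulative hazard lying near 1
  (band 0.85–1.15 at ~1000 subjects).
* Baseline adequacy maps each family to coordinates that are linear when
  the family is right — (t, Ĥ), (log t, log Ĥ), (log t, log failure
  odds) — and scores linearity by OLS R², turning a by-eye judgment into
  a number. Ĥ is Nelson–Aalen and Ŝ Kaplan–Meier (the −log KM alternative
  differs only in small risk sets); points with Ĥ = 0 or Ŝ ∈ {0,1} are
  dropped and counted.
* The q-q AFT check pairs KM quantiles of two covariate groups on a
  probability grid; under an AFT model they lie on a line through the
  origin with slope equal to the acceleration factor. The slope is fitted
  through the origin (shared origin is forced by the model); the
  unconstrained OLS slope is also reported.
* Conditional hazard curves evaluate `z_p·h_c(t|x)` at requested frailty
  quantiles — theoretical quantiles of the fitted frailty distribution by
  default, or empirical quantiles of the predicted cluster frailties,
  since the two differ (the theoretical inverse-Gaussian median is below
  1; empirical medians of predicted frailties cluster near 1).

The product-limit and Nelson–Aalen estimators are implemented as plain
step-function tables (simultaneous-death tie convention) and are checked
against both a brute-force risk-set oracle and lifelines. Descriptive
medians in `describe` are censoring-aware KM medians with
Brookmeyer–Crowley-style CIs via lifelines; raw sample medians are
available by flag since sources rarely state which estimator a summary
table used.

## Synthetic cohort generator

`simulate_dataset` draws event times by inverse transform:
`T = S_c^{-1}(U^{1/Z})`, which is exact for any baseline/formulation and
is itself property-tested (the PIT `S_c(T|x)^Z` is uniform). Censoring is
an administrative horizon plus independent exponential dropout —
non-informative by construction, matching the analysis assumption.

`sam_like_design()` encodes the motivating cohort's shape as defaults:

| quantity | value | rationale |
|---|---|---|
| clusters | 280, ~26% singletons | filter leaves ≈206 clusters / ≈855 children |
| cluster size (non-singleton) | 2 + NB(2, p), mean ≈ 4.15 | matches before/after-filter totals; only the margins are constrained |
| baseline | log-logistic, ρ = 3.5, median 12.1 d | unimodal hazard; population median lands ≈14 d after covariate effects |
| frailty | inverse-Gaussian, θ = 0.21 | the dependence level the analysis targets |
| covariates | sex (null), 6 age bands, 3 malnutrition types, co-infection 56% | category frequencies follow the cohort mix; effect sizes on the AFT scale with co-infection ≈ +0.16 |
| censoring | horizon 63 d + dropout 0.0105/d | ≈17% censored overall |

The generator emulates the cohort's margins — cluster structure, event
fraction, time scale, covariate mix — not any real-world features beyond
them: no admission-date seasonality, no competing risk of death (deaths
censor, as in the analysis), no informative dropout, no cluster-level
covariates. Passing tests therefore demonstrate that the estimators
recover the truth of this generative family and that model selection and
diagnostics discriminate within it; they cannot certify behavior under
informative censoring or misspecified frailty sharing.

## Problem sizes in the verification suite

The statistical acceptance tests use simulation scales chosen as the
package's own verification design: 50 replicates of 150 clusters × 5 for
recovery/coverage, 100 replicates for AIC selection consistency, 200
replicates of 80 clusters × 4 for LRT null calibration, 100 replicates at
~1000 subjects for the Cox–Snell band, and 30 for the linearity contest.
At these scales the binomial bands quoted in each test have the stated
coverage; all seeds are fixed, so reruns are exact.

## Known limitations

* No left truncation, time-varying covariates, or recurrent events.
* Frailty families beyond gamma and inverse-Gaussian (positive stable,
  log-normal) are out of scope, as are semi-parametric (unspecified
  baseline) frailty fits.
* Wald intervals can be poor for θ near 0 (the boundary); the LRT is the
  recommended test for the clustering effect.
* The univariable screen makes no multiplicity correction — it mirrors
  the classical screen-then-model workflow, with its known caveats.
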