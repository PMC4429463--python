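# parfrail — parametric shared-frailty survival models for clustered time-to-event data

`parfrail` fits and compares parametric shared-frailty survival models for
clustered, right-censored time-to-event data, built around a motivating
application: time-to-cure of children hospitalized with severe acute
malnutrition (SAM), where children from the same kebele (village) share
unmeasured risk factors and so cannot be treated as independent.

It is aimed at biostatisticians and epidemiologists who need the full
workflow for such data: descriptive summaries, univariable covariate
screening, marginal maximum-likelihood fitting of a grid of frailty
models, AIC-based model choice, dependence measures, frailty prediction,
and adequacy diagnostics — plus a clustered-data simulator so that every
step can be exercised and tested without access to any hospital records.

## The model

Subject *j* in cluster *i* has conditional hazard

```
h(t | x_ij, Z_i) = Z_i · h_c(t | x_ij),       S(t | x, z) = S_c(t | x)^z
```

where `h_c` is a parametric hazard with covariates entering either
proportionally (PH: `h_c = h0(t)·exp(x'β)`) or by rescaling time (AFT:
`S_c(t|x) = S0(t·exp(−x'β))`), and `Z_i > 0` is an unobserved cluster
frailty shared by everyone in cluster *i*. Baseline families (scale λ,
shape ρ):

| family       | h0(t)                  | H0(t)           |
|--------------|------------------------|-----------------|
| exponential  | λ                      | λt              |
| Weibull      | λρt^(ρ−1)              | λt^ρ            |
| log-logistic | λρt^(ρ−1)/(1 + λt^ρ)   | log(1 + λt^ρ)   |

Frailties are mean-one with variance θ, either gamma
(`𝓛(s) = (1+θs)^(−1/θ)`) or inverse-Gaussian
(`𝓛(s) = exp[(1/θ)(1 − √(1+2θs))]`). Integrating `Z_i` out against its
Laplace transform gives the marginal log-likelihood of a cluster with
`d_i` events and summed conditional cumulative hazard `H_i`:

```
log L_i = Σ_j δ_ij log h_c(t_ij|x_ij) + log[ (−1)^{d_i} 𝓛^{(d_i)}(H_i) ]
```

The gamma derivatives have a closed form; the inverse-Gaussian ones are
evaluated by a sign-stable polynomial recursion in log space. Within-cluster
dependence is summarized by Kendall's τ (gamma: `τ = θ/(θ+2)`;
inverse-Gaussian: `τ = 1/2 − 1/θ + (2/θ²)e^{2/θ}E₁(2/θ)`), cluster
frailties are predicted by the empirical-Bayes posterior mean
`ẑ_i = −𝓛^{(d_i+1)}(H_i)/𝓛^{(d_i)}(H_i)`, and AFT effects are reported as
acceleration factors `ϕ = exp(β)` (ϕ > 1 prolongs time to the event).

## Worked example

The `analysis/` scripts run the whole workflow on a synthetic cohort whose
structure matches the motivating study (~280 kebeles of which a quarter
contribute a single child, ~855 children after the singleton filter, ~83%
cured, median cure time ~14 days):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_descriptives.py
python analysis/03_univariable_screen.py
python analysis/04_model_comparison.py
python analysis/05_best_model_report.py
python analysis/06_diagnostics.py
```

With seed 1 this prints, stage by stage:

```
simulated 947 children in 280 kebeles (seed 1)
singleton filter: 78 single-child kebeles removed -> 202 kebeles / 869 children
cured fraction 0.815, median cure time 13.9 days
...
   baseline  frailty      aic  theta   tau  rank
exponential    gamma 5597.326  0.000 0.000   5.0
exponential invgauss 5597.333  0.000 0.000   6.0
    weibull    gamma 5187.083  0.445 0.182   3.0
    weibull invgauss 5199.937  0.622 0.172   4.0
loglogistic    gamma 5087.899  0.164 0.076   2.0
loglogistic invgauss 5087.716  0.202 0.079   1.0
best model by AIC: loglogistic-invgauss
theta = 0.202 (SE 0.062), Kendall's tau = 0.079
shape rho = 3.36 (unimodal hazard), scale lam = 1.939e-04
frailty LRT: statistic 28.11, p = 5.75e-08
predicted kebele frailties span 0.427 to 2.017
| co_infection | Yes | 0.194 | 0.040 | 1.214 | (1.121, 1.314)* |
baseline linearity R²: {'loglogistic': 0.9953, 'exponential': 0.9766, 'weibull': 0.9477}
Cox–Snell origin slopes (1 = adequate): {'exponential': 1.139, 'weibull': 0.995, 'loglogistic': 1.056}
q-q slope for co-infection (≈ acceleration factor): 1.245
```

Reading this: the log-logistic baseline with inverse-Gaussian frailty wins
the AIC comparison (as it should — it is the generating model); the
frailty variance θ̂ = 0.202 recovers the simulated truth of 0.21 and
implies mild within-kebele dependence (τ ≈ 0.08); the likelihood-ratio
test firmly rejects θ = 0, so clustering matters; co-infection prolongs
time-to-cure by a factor ϕ ≈ 1.21 with a CI excluding 1; and all three
diagnostics (linearity of the log failure odds, near-unit Cox–Snell
slopes, q-q slope close to ϕ) point the same way. Every artifact lands
under `results/` as CSV/JSON.

The same pipeline runs on any data in the standard form — a CSV with
columns `cluster,time,event,<covariates...>` plus a YAML/JSON schema
listing each covariate's ordered labels (first label = reference) — either
through the library or the `parfrail` command line
(`simulate`, `fit`, `compare`, `diagnose`, `report`, `run`).

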