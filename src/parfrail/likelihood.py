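"""Marginal likelihood of parametric shared-frailty models, and fitting.

Conditional on its cluster frailty Z_i, subject j's hazard is
Z_i · h_c(t|x_ij), with h_c the covariate-adjusted parametric hazard (PH or
AFT form).  Integrating the cluster's frailty out against its density gives
the marginal contribution of cluster i with d_i events and summed
conditional cumulative hazard H_i = Σ_j H_c(t_ij|x_ij):

    log L_i = Σ_j δ_ij log h_c(t_ij|x_ij) + log[(-1)^{d_i} 𝓛^{(d_i)}(H_i)]

where 𝓛 is the frailty Laplace transform.  With no frailty the second term
collapses to -H_i.  Maximum likelihood runs on unconstrained transforms
(log λ, log ρ, log θ); standard errors come from the inverse numerical
Hessian with the delta method back to the natural scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .baselines import (
    BaselineSpec,
    RegressionSpec,
    conditional_functions,
    hazard_to_aft_params,
)
from .frailty import FrailtySpec, log_laplace_derivative_many, posterior_frailty

_DEFAULT_FORMULATION = {"exponential": "PH", "weibull": "PH", "loglogistic": "AFT"}


@dataclass(frozen=True)
class ModelSpec:
    """A baseline family × formulation × frailty family × covariate set."""

    baseline: str
    frailty: Optional[str] = None  # "gamma" | "invgauss" | None
    covariates: tuple[str, ...] = ()
    formulation: Optional[str] = None  # default: PH for exp/weibull, AFT for loglogistic

    def __post_init__(self) -> None:
        if self.baseline not in _DEFAULT_FORMULATION:
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if self.formulation is None:
            object.__setattr__(self, "formulation", _DEFAULT_FORMULATION[self.baseline])
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def label(self) -> str:
        fr = self.frailty or "none"
        return f"{self.baseline}-{fr}"


def design_matrix(ds, covariates) -> tuple[np.ndarray, list[str]]:
    """Dummy-encode the requested covariates, dropping reference levels."""
    cols, names = [], []
    for name in covariates:
        if name not in ds.schema:
            raise ValueError(f"covariate {name!r} not in dataset schema")
        labels = ds.schema[name]
        col = ds.frame[name]
        for label in labels[1:]:
            cols.append((col == label).to_numpy(dtype=float))
            names.append(f"{name}[{label}]")
    X = np.column_stack(cols) if cols else np.empty((ds.n_subjects, 0))
    return X, names


@dataclass
class _Arrays:
    """Fitting-ready views of a dataset: design, times, events, clusters."""

    X: np.ndarray
    names: list[str]
    t: np.ndarray
    delta: np.ndarray
    codes: np.ndarray
    n_clusters: int
    cluster_ids: np.ndarray


def _prepare(ds, covariates) -> _Arrays:
    X, names = design_matrix(ds, covariates)
    codes, uniques = pd.factorize(ds.frame["cluster"], sort=True)
    return _Arrays(
        X=X,
        names=names,
        t=ds.frame["time"].to_numpy(dtype=float),
        delta=ds.frame["event"].to_numpy(dtype=float),
        codes=codes,
        n_clusters=len(uniques),
        cluster_ids=np.asarray(uniques, dtype=str),
    )


def _loglik(
    model: ModelSpec,
    beta: np.ndarray,
    lam: float,
    rho: float,
    theta: Optional[float],
    arr: _Arrays,
) -> float:
    spec = BaselineSpec(model.baseline, lam, rho)
    reg = RegressionSpec(model.formulation, beta)
    cond = conditional_functions(spec, reg, arr.X, arr.t)
    event_term = float(np.dot(arr.delta, cond["logh"]))
    H_i = np.bincount(arr.codes, weights=cond["H"], minlength=arr.n_clusters)
    if model.frailty is None:
        return event_term - float(H_i.sum())
    d_i = np.rint(
        np.bincount(arr.codes, weights=arr.delta, minlength=arr.n_clusters)
    ).astype(int)
    fr = FrailtySpec(model.frailty, theta)
    return event_term + float(log_laplace_derivative_many(fr, H_i, d_i).sum())


def cluster_loglik(model: ModelSpec, params: dict, cluster_ds) -> float:
    """Marginal log-likelihood contribution of one cluster (or any subset
    of whole clusters).  ``params`` holds beta, lam, rho and, for frailty
    models, theta."""
    arr = _prepare(cluster_ds, model.covariates)
    beta = np.asarray(params.get("beta", np.zeros(arr.X.shape[1])), dtype=float)
    return _loglik(model, beta, params["lam"], params.get("rho", 1.0),
                   params.get("theta"), arr)


def total_loglik(model: ModelSpec, params: dict, ds) -> float:
    """Sum of cluster contributions over the whole dataset."""
    return cluster_loglik(model, params, ds)


@dataclass
class ModelFit:
    """A fitted shared-frailty survival model."""

    model: ModelSpec
    coef: dict[str, float]
    se: dict[str, float]
    lam: float
    rho: float
    theta: Optional[float]
    lam_se: Optional[float]
    rho_se: Optional[float]
    theta_se: Optional[float]
    loglik: float
    n_params: int
    n_clusters: int
    n_subjects: int
    cluster_table: pd.DataFrame
    converged: bool
    n_iter: int
    grad_norm: float
    hessian_cond: Optional[float]
    se_available: bool
    mu: Optional[float] = None
    log_scale: Optional[float] = None
    cov_unconstrained: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def predicted_frailties(self) -> np.ndarray:
        return self.cluster_table["z_hat"].to_numpy()

    def wald_ci(self, z: float = 1.959963984540054) -> dict[str, tuple[float, float]]:
        return {
            k: (self.coef[k] - z * self.se[k], self.coef[k] + z * self.se[k])
            for k in self.coef
        }

    def acceleration_factors(self) -> dict[str, float]:
        if self.model.formulation != "AFT":
            raise ValueError("acceleration factors require an AFT-formulation fit")
        return {k: float(np.exp(v)) for k, v in self.coef.items()}

    def to_json(self, **kwargs) -> str:
        payload = {
            "model": {
                "baseline": self.model.baseline,
                "frailty": self.model.frailty,
                "formulation": self.model.formulation,
                "covariates": list(self.model.covariates),
            },
            "coef": self.coef,
            "se": self.se,
            "lam": self.lam,
            "rho": self.rho,
            "theta": self.theta,
            "lam_se": self.lam_se,
            "rho_se": self.rho_se,
            "theta_se": self.theta_se,
            "mu": self.mu,
            "log_scale": self.log_scale,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_clusters": self.n_clusters,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "frailties": {
                str(c): float(z)
                for c, z in zip(self.cluster_table["cluster"], self.cluster_table["z_hat"])
            },
        }
        return json.dumps(payload, indent=2, **kwargs)


class FitError(RuntimeError):
    pass


def _unpack(model: ModelSpec, x: np.ndarray, k: int):
    beta = x[:k]
    lam = np.exp(x[k])
    if model.baseline == "exponential":
        rho, j = 1.0, k + 1
    else:
        rho, j = np.exp(x[k + 1]), k + 2
    theta = np.exp(x[j]) if model.frailty is not None else None
    return beta, lam, rho, theta


def _neg_loglik_factory(model: ModelSpec, arr: _Arrays):
    k = arr.X.shape[1]

    def nll(x: np.ndarray) -> float:
        beta, lam, rho, theta = _unpack(model, x, k)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                val = _loglik(model, beta, lam, rho, theta, arr)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    return nll


def _num_hessian(f, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian; step per-parameter, cube-root eps scaled."""
    n = x.shape[0]
    h = np.cbrt(np.finfo(float).eps) * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


_THETA_FLOOR = 1e-8


def fit(
    model: ModelSpec,
    ds,
    init: Optional[dict] = None,
    tol: float = 1e-10,
    max_iter: int = 500,
    compute_se: bool = True,
) -> ModelFit:
    """Fit a model by marginal maximum likelihood.

    Frailty models are initialized from the corresponding no-frailty fit
    with θ₀ = 0.1 unless ``init`` overrides.  Deterministic: refitting with
    the same inputs reproduces the result bit for bit.
    """
    arr = _prepare(ds, model.covariates)
    k = arr.X.shape[1]
    if k:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(arr.t)), arr.X]))
        if rank < k + 1:
            raise FitError("design matrix (with intercept) is rank deficient")

    if init is None:
        init = {}
    if model.frailty is not None and not init:
        base_fit = fit(
            ModelSpec(model.baseline, None, model.covariates, model.formulation),
            ds, tol=tol, max_iter=max_iter, compute_se=False,
        )
        init = {
            "beta": np.array([base_fit.coef[n] for n in arr.names]),
            "lam": base_fit.lam,
            "rho": base_fit.rho,
            "theta": 0.1,
        }

    lam0 = float(init.get("lam", max(arr.delta.sum(), 1.0) / arr.t.sum()))
    rho0 = float(init.get("rho", 1.0))
    x0 = list(np.asarray(init.get("beta", np.zeros(k)), dtype=float))
    x0.append(np.log(lam0))
    bounds = [(-20.0, 20.0)] * k + [(-40.0, 40.0)]
    if model.baseline != "exponential":
        x0.append(np.log(rho0))
        bounds.append((np.log(0.02), np.log(50.0)))
    if model.frailty is not None:
        x0.append(np.log(float(init.get("theta", 0.1))))
        bounds.append((np.log(_THETA_FLOOR), np.log(100.0)))
    x0 = np.asarray(x0)

    nll = _neg_loglik_factory(model, arr)
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9, "maxfun": 20000},
    )
    converged = bool(res.success)
    if not converged:
        # line searches can stall on finite-difference gradient noise right
        # at the optimum; accept if the projected gradient is negligible
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if gnorm <= 1e-5 * max(1.0, abs(res.fun)):
            converged = True
        else:
            raise FitError(
                f"optimizer failed: {res.message}; nit={res.nit}, "
                f"max|grad|={gnorm:.3g}, f={res.fun:.6g}"
            )

    beta, lam, rho, theta = _unpack(model, res.x, k)
    loglik = -float(res.fun)

    se = {n: float("nan") for n in arr.names}
    lam_se = rho_se = theta_se = None
    hess_cond = None
    cov = None
    se_ok = False
    if compute_se:
        H = _num_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
            hess_cond = float(np.linalg.cond(H))
            with np.errstate(invalid="ignore"):
                dse = np.sqrt(np.diag(cov))
            if np.all(np.isfinite(dse)):
                se_ok = True
                se = {n: float(dse[i]) for i, n in enumerate(arr.names)}
                lam_se = float(lam * dse[k])  # delta method through exp
                j = k + 1
                if model.baseline != "exponential":
                    rho_se = float(rho * dse[j]); j += 1
                if model.frailty is not None:
                    theta_se = float(theta * dse[j])
        except np.linalg.LinAlgError:
            pass

    # per-cluster event counts, cumulative hazards, predicted frailties
    spec = BaselineSpec(model.baseline, lam, rho)
    reg = RegressionSpec(model.formulation, beta)
    cond = conditional_functions(spec, reg, arr.X, arr.t)
    H_i = np.bincount(arr.codes, weights=cond["H"], minlength=arr.n_clusters)
    d_i = np.rint(
        np.bincount(arr.codes, weights=arr.delta, minlength=arr.n_clusters)
    ).astype(int)
    if model.frailty is not None:
        z_hat = np.atleast_1d(posterior_frailty(FrailtySpec(model.frailty, theta), d_i, H_i))
    else:
        z_hat = np.ones(arr.n_clusters)
    cluster_table = pd.DataFrame(
        {"cluster": arr.cluster_ids, "d": d_i, "H": H_i, "z_hat": z_hat}
    )

    n_params = k + 1  # beta + log lam
    if model.baseline != "exponential":
        n_params += 1
    if model.frailty is not None:
        n_params += 1

    mu = log_scale = None
    if model.formulation == "AFT":
        mu, sigma = hazard_to_aft_params(lam, rho)
        log_scale = float(np.log(sigma))

    return ModelFit(
        model=model,
        coef={n: float(b) for n, b in zip(arr.names, beta)},
        se=se,
        lam=float(lam), rho=float(rho),
        theta=None if theta is None else float(theta),
        lam_se=lam_se, rho_se=rho_se, theta_se=theta_se,
        loglik=loglik,
        n_params=n_params,
        n_clusters=arr.n_clusters,
        n_subjects=len(arr.t),
        cluster_table=cluster_table,
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan"),
        hessian_cond=hess_cond,
        se_available=se_ok,
        mu=mu, log_scale=log_scale,
        cov_unconstrained=cov,
    )


def lrt_frailty(fit_with: ModelFit, fit_without: ModelFit) -> dict[str, float]:
    """Likelihood-ratio test of H0: θ = 0 against a shared-frailty model.

    θ = 0 sits on the boundary of the parameter space, so the statistic's
    null distribution is the mixture ½χ²₀ + ½χ²₁, not χ²₁.
    """
    m1, m0 = fit_with.model, fit_without.model
    if m1.frailty is None or m0.frailty is not None:
        raise ValueError("expected (frailty fit, no-frailty fit) in that order")
    if (m1.baseline, m1.formulation, m1.covariates) != (
        m0.baseline, m0.formulation, m0.covariates
    ):
        raise ValueError("models are not nested: baseline/covariates differ")
    stat = max(0.0, 2.0 * (fit_with.loglik - fit_without.loglik))
    p = 0.5 * stats.chi2.sf(stat, df=1) if stat > 0 else 0.5
    return {"statistic": float(stat), "p_value": float(p)}
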