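"""Parametric baseline hazard families and covariate formulations.

Three baseline families are supported, each parameterized by a scale
``lam`` (λ) and shape ``rho`` (ρ):

exponential
    h0(t) = λ, H0(t) = λt (ρ fixed at 1).
weibull
    h0(t) = λρ t^{ρ-1}, H0(t) = λ t^ρ.
loglogistic
    h0(t) = λρ t^{ρ-1} / (1 + λ t^ρ), H0(t) = log(1 + λ t^ρ).

Covariates enter either proportionally on the hazard (PH) or by rescaling
time (AFT).  Everything hazard-side is evaluated in log space so that very
large λ t^ρ cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FAMILIES = ("exponential", "weibull", "loglogistic")
FORMULATIONS = ("PH", "AFT")


@dataclass(frozen=True)
class BaselineSpec:
    """A baseline hazard family with scale λ and shape ρ.

    The exponential family has no free shape; ρ is pinned to 1 and any
    other value is rejected.
    """

    family: str
    lam: float
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown baseline family {self.family!r}")
        if not (self.lam > 0):
            raise ValueError("scale lam must be positive")
        if not (self.rho > 0):
            raise ValueError("shape rho must be positive")
        if self.family == "exponential" and self.rho != 1.0:
            raise ValueError("exponential baseline fixes rho = 1")


@dataclass(frozen=True)
class RegressionSpec:
    """Covariate effects on the baseline.

    ``coefficients`` aligns with the dummy-encoded design (reference levels
    omitted).  For AFT fits the location/scale (intercept μ, log σ) view of
    the same model is available through :func:`hazard_to_aft_params`.
    """

    formulation: str
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")
        object.__setattr__(
            self, "coefficients", np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        )

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k = self.coefficients.shape[0]
        if x.ndim == 1 and k not in (x.shape[0],):
            raise ValueError(f"covariate vector length {x.shape[0]} != {k} coefficients")
        if x.ndim == 2 and x.shape[1] != k:
            raise ValueError(f"design matrix has {x.shape[1]} columns, expected {k}")
        return x @ self.coefficients


def _check_t(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be strictly positive")
    return t


def log_hazard0(spec: BaselineSpec, t) -> np.ndarray:
    """log h0(t), vectorized over t."""
    t = _check_t(t)
    loglam, logrho = np.log(spec.lam), np.log(spec.rho)
    logt = np.log(t)
    if spec.family == "exponential":
        return np.full_like(t, loglam)
    core = loglam + logrho + (spec.rho - 1.0) * logt
    if spec.family == "weibull":
        return core
    # log-logistic: divide by 1 + lam t^rho, stably via softplus
    u = loglam + spec.rho * logt
    return core - np.logaddexp(0.0, u)


def cumulative_hazard0(spec: BaselineSpec, t) -> np.ndarray:
    """H0(t), vectorized over t."""
    t = _check_t(t)
    if spec.family == "exponential":
        return spec.lam * t
    u = np.log(spec.lam) + spec.rho * np.log(t)
    if spec.family == "weibull":
        return np.exp(u)
    return np.logaddexp(0.0, u)  # log(1 + lam t^rho)


def baseline_functions(spec: BaselineSpec, t) -> dict[str, np.ndarray]:
    """Evaluate {h0, H0, S0, log h0} at times t > 0."""
    logh0 = log_hazard0(spec, t)
    H0 = cumulative_hazard0(spec, t)
    return {"h0": np.exp(logh0), "H0": H0, "S0": np.exp(-H0), "logh0": logh0}


def conditional_functions(
    spec: BaselineSpec, reg: RegressionSpec, x, t
) -> dict[str, np.ndarray]:
    """Conditional hazard/cumulative-hazard/survival given covariates.

    PH:  h(t|x) = h0(t) e^{x'β},  H(t|x) = H0(t) e^{x'β}.
    AFT: S(t|x) = S0(t e^{-x'β}), so H(t|x) = H0(t e^{-x'β}) and
         h(t|x) = h0(t e^{-x'β}) e^{-x'β}.

    The frailty is *not* applied here; it multiplies the conditional hazard
    in the marginal likelihood, i.e. S(t|x,z) = S(t|x)^z.
    """
    t = _check_t(t)
    eta = reg.linear_predictor(x)
    if reg.formulation == "PH":
        logh = log_hazard0(spec, t) + eta
        logH = np.log(cumulative_hazard0(spec, t)) + eta
        H = np.exp(logH)
    else:
        tstar = t * np.exp(-eta)
        logh = log_hazard0(spec, tstar) - eta
        H = cumulative_hazard0(spec, tstar)
    return {"h": np.exp(logh), "logh": logh, "H": H, "S": np.exp(-H)}


def aft_to_hazard_params(mu: float, sigma: float) -> tuple[float, float]:
    """Map AFT location/scale (μ, σ) to hazard-side (λ, ρ).

    For Weibull and log-logistic alike, log T = μ + σW implies ρ = 1/σ and
    λ = exp(-μ/σ).  Exact inverse of :func:`hazard_to_aft_params`.
    """
    if not (sigma > 0):
        raise ValueError("sigma must be positive")
    rho = 1.0 / sigma
    lam = np.exp(-mu / sigma)
    return float(lam), float(rho)


def hazard_to_aft_params(lam: float, rho: float) -> tuple[float, float]:
    """Map (λ, ρ) back to AFT intercept μ and scale σ."""
    if not (lam > 0 and rho > 0):
        raise ValueError("lam and rho must be positive")
    sigma = 1.0 / rho
    mu = -np.log(lam) / rho
    return float(mu), float(sigma)


def invert_conditional_survival(
    spec: BaselineSpec, reg: RegressionSpec, x, q
) -> np.ndarray:
    """Solve S(t|x) = q for t (simulation workhorse; closed form per family)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must lie strictly inside (0, 1)")
    eta = reg.linear_predictor(x)
    H = -np.log(q)
    if reg.formulation == "PH":
        H = H * np.exp(-eta)
        shift = 0.0
    else:
        shift = eta
    if spec.family == "exponential":
        t0 = H / spec.lam
    elif spec.family == "weibull":
        t0 = (H / spec.lam) ** (1.0 / spec.rho)
    else:
        # H = log(1 + lam t^rho)  =>  t = ((e^H - 1)/lam)^{1/rho}
        t0 = (np.expm1(H) / spec.lam) ** (1.0 / spec.rho)
    return t0 * np.exp(shift)
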