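"""Gamma and inverse-Gaussian shared-frailty math.

Both families are constrained to mean E[Z] = 1 so that the single free
parameter is the frailty variance θ (θ → 0 recovers independence):

gamma
    Z ~ Gamma(shape 1/θ, scale θ);  𝓛(s) = (1 + θs)^{-1/θ}.
invgauss
    Z ~ IG(mean 1, shape 1/θ);      𝓛(s) = exp[(1/θ)(1 - √(1 + 2θs))].

The marginal likelihood of a cluster with d events needs the d-th
derivative 𝓛^{(d)}(s), whose sign alternates as (-1)^d (complete
monotonicity).  Derivatives are carried as (log magnitude, sign) pairs:

* gamma has the closed form
  (-1)^d 𝓛^{(d)}(s) = (1+θs)^{-1/θ-d} ∏_{l=1}^{d-1} (1 + lθ);
* inverse-Gaussian derivatives satisfy 𝓛^{(d)}(s) = 𝓛(s) Q_d(v) with
  v = (1+2θs)^{-1/2} and the polynomial recursion
  Q_{d+1}(v) = -θ v³ Q_d'(v) - v Q_d(v), Q_0 = 1.
  The signed polynomial P_d = (-1)^d Q_d has all-nonnegative coefficients,
  so it can be accumulated in log space with no cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats
from scipy.special import logsumexp

FRAILTY_FAMILIES = ("gamma", "invgauss")

#: Largest per-cluster event count the derivative recursion will serve.
DERIVATIVE_ORDER_CAP = 200


@dataclass(frozen=True)
class FrailtySpec:
    """A mean-one frailty family with variance theta (dimensionless)."""

    family: str
    theta: float

    def __post_init__(self) -> None:
        if self.family not in FRAILTY_FAMILIES:
            raise ValueError(f"unknown frailty family {self.family!r}")
        if not (self.theta > 0):
            raise ValueError("frailty variance theta must be positive")


@dataclass(frozen=True)
class LogDerivative:
    """(-1)^d-signed Laplace-transform derivative held as log|·| + sign."""

    log_magnitude: float
    sign: int
    order: int
    argument: float

    @property
    def value(self) -> float:
        return self.sign * np.exp(self.log_magnitude)


def log_laplace(spec: FrailtySpec, s) -> np.ndarray:
    """log 𝓛(s), vectorized over s ≥ 0."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("Laplace argument s must be nonnegative")
    th = spec.theta
    if spec.family == "gamma":
        return -np.log1p(th * s) / th
    return (1.0 - np.sqrt(1.0 + 2.0 * th * s)) / th


def laplace(spec: FrailtySpec, s) -> np.ndarray:
    """𝓛(s) = E[e^{-sZ}] ∈ (0, 1]; 𝓛(0) = 1 by the mean-one constraint."""
    return np.exp(log_laplace(spec, s))


@lru_cache(maxsize=512)
def _ig_log_coeffs(theta: float, dmax: int) -> tuple[np.ndarray, ...]:
    """Log coefficients of P_d(v) = (-1)^d Q_d(v) for d = 0..dmax.

    P_0 = 1 and P_{d+1}(v) = θ v³ P_d'(v) + v P_d(v); every update adds
    nonnegative terms, so the recursion is exact in log space.
    """
    logth = np.log(theta)
    coeffs = [np.zeros(1)]  # P_0 coefficients (log scale): [log 1]
    for d in range(dmax):
        c = coeffs[-1]
        deg = c.shape[0] - 1
        new = np.full(deg + 3, -np.inf)
        for k in range(deg + 1):
            if not np.isfinite(c[k]):
                continue
            new[k + 1] = np.logaddexp(new[k + 1], c[k])  # v * c_k v^k
            if k > 0:  # θ v³ * k c_k v^{k-1}
                new[k + 2] = np.logaddexp(new[k + 2], logth + np.log(k) + c[k])
        coeffs.append(new)
    return tuple(coeffs)


def log_laplace_derivative_many(spec: FrailtySpec, s, d) -> np.ndarray:
    """log|𝓛^{(d)}(s)| for paired arrays s, d (the likelihood hot path)."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    d = np.atleast_1d(np.asarray(d))
    if np.any(s < 0):
        raise ValueError("Laplace argument s must be nonnegative")
    if np.any(d < 0) or not np.issubdtype(d.dtype, np.integer):
        raise ValueError("derivative order d must be a nonnegative integer")
    dmax = int(d.max()) if d.size else 0
    if dmax > DERIVATIVE_ORDER_CAP:
        raise ValueError(
            f"derivative order {dmax} exceeds cap {DERIVATIVE_ORDER_CAP}; raise "
            "parfrail.frailty.DERIVATIVE_ORDER_CAP if clusters really are this large"
        )
    th = spec.theta
    out = np.empty(np.broadcast(s, d).shape)
    if spec.family == "gamma":
        # log ∏_{l<d}(1+lθ) accumulated once up to dmax
        prod = np.concatenate([[0.0], np.cumsum(np.log1p(th * np.arange(1, dmax + 1)))])
        out = (-1.0 / th - d) * np.log1p(th * s) + prod[np.maximum(d - 1, 0)]
        return out
    logL = log_laplace(spec, s)
    logv = -0.5 * np.log1p(2.0 * th * s)
    coeffs = _ig_log_coeffs(float(th), dmax)
    s_b, d_b = np.broadcast_arrays(s, d)
    logv_b = np.broadcast_to(logv, s_b.shape)
    logL_b = np.broadcast_to(logL, s_b.shape)
    out = np.empty(s_b.shape)
    for order in np.unique(d_b):
        m = d_b == order
        c = coeffs[int(order)]
        k = np.arange(c.shape[0])
        # log P_d(v) = logsumexp_k (log c_k + k log v)
        out[m] = logL_b[m] + logsumexp(c[None, :] + np.outer(logv_b[m], k), axis=1)
    return out


def log_laplace_derivative(spec: FrailtySpec, s: float, d: int) -> LogDerivative:
    """𝓛^{(d)}(s) as a signed log magnitude; sign is (-1)^d."""
    logmag = float(log_laplace_derivative_many(spec, s, int(d))[0])
    return LogDerivative(logmag, -1 if d % 2 else 1, int(d), float(s))


def _expx_e1(x: float) -> float:
    """e^x E1(x), stable for large x via a continued fraction."""
    if x < 700.0:
        return float(np.exp(x) * special.exp1(x))
    # Lentz continued fraction for e^x E1(x) = 1/(x+1-1/(x+3-4/(x+5-...)))
    b = x + 1.0
    c, dd = 1e300, 1.0 / b
    h = dd
    for i in range(1, 200):
        a = -i * i
        b += 2.0
        dd = 1.0 / (a * dd + b)
        c = b + a / c
        h *= dd * c
        if abs(dd * c - 1.0) < 1e-15:
            break
    return h


def kendalls_tau(spec: FrailtySpec) -> float:
    """Kendall's τ of within-cluster event-time dependence implied by θ.

    gamma: τ = θ/(θ+2); inverse-Gaussian:
    τ = 1/2 - 1/θ + (2/θ²) e^{2/θ} E₁(2/θ).
    """
    th = spec.theta
    if spec.family == "gamma":
        return th / (th + 2.0)
    x = 2.0 / th
    return 0.5 - 1.0 / th + (2.0 / th**2) * _expx_e1(x)


def _frozen(spec: FrailtySpec):
    if spec.family == "gamma":
        return stats.gamma(a=1.0 / spec.theta, scale=spec.theta)
    # scipy invgauss(mu, scale): mean = mu*scale, var = mu^3 scale^2;
    # mean 1, variance θ  =>  mu = θ, scale = 1/θ.
    return stats.invgauss(mu=spec.theta, scale=1.0 / spec.theta)


def frailty_density(spec: FrailtySpec, z) -> np.ndarray:
    return _frozen(spec).pdf(z)


def frailty_quantile(spec: FrailtySpec, p) -> np.ndarray:
    """Quantile of the frailty distribution (monotone in p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probability p must lie in (0, 1)")
    return _frozen(spec).ppf(p)


def frailty_cdf(spec: FrailtySpec, z) -> np.ndarray:
    return _frozen(spec).cdf(z)


def sample_frailty(spec: FrailtySpec, n: int, seed) -> np.ndarray:
    """n reproducible positive frailty draws."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spec.family == "gamma":
        return rng.gamma(1.0 / spec.theta, spec.theta, size=n)
    return _frozen(spec).rvs(size=n, random_state=rng)


def posterior_frailty(spec: FrailtySpec, d, H) -> np.ndarray:
    """Empirical-Bayes posterior mean frailty of a cluster.

    ẑ = -𝓛^{(d+1)}(H)/𝓛^{(d)}(H) given the cluster's event count d and
    summed conditional cumulative hazard H.  Gamma reduces to the familiar
    (1/θ + d)/(1/θ + H).  With no information (d = 0, H = 0) the posterior
    mean is the prior mean 1.
    """
    d = np.atleast_1d(np.asarray(d))
    H = np.atleast_1d(np.asarray(H, dtype=float))
    if np.any(d < 0) or np.any(H < 0):
        raise ValueError("need d >= 0 and H >= 0")
    if spec.family == "gamma":
        out = (1.0 / spec.theta + d) / (1.0 / spec.theta + H)
    else:
        num = log_laplace_derivative_many(spec, H, d + 1)
        den = log_laplace_derivative_many(spec, H, d)
        out = np.exp(num - den)
    return out if out.shape != (1,) else float(out[0])
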