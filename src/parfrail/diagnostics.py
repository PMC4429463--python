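"""Model-adequacy diagnostics for parametric frailty fits.

Covers the usual graphical checks, each reduced to plain coordinates (and
a summary number) so a visual judgment becomes testable:

* Cox–Snell residuals r_ij = ẑ_i Ĥ_c(t_ij|x_ij): under a correct model
  the pairs (r, δ) behave like censored unit-exponential data, so the
  Nelson–Aalen cumulative hazard of the residuals should hug the 45° line.
* Baseline-adequacy coordinates: each family implies a straight line in a
  transformed scale — exponential (t, Ĥ), Weibull (log t, log Ĥ),
  log-logistic (log t, log failure odds) — and an OLS R² scores linearity.
* q-q plot between two covariate groups: under an AFT model the paired
  Kaplan–Meier quantiles lie on a line through the origin whose slope is
  the acceleration factor.
* Conditional hazard curves at chosen frailty quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .baselines import BaselineSpec, RegressionSpec, conditional_functions
from .frailty import FrailtySpec, frailty_quantile


def _sorted_risk_sets(times, events):
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty input")
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    uniq = np.unique(t)
    n_at_risk = np.array([(t >= u).sum() for u in uniq], dtype=float)
    n_events = np.array([d[t == u].sum() for u in uniq], dtype=float)
    return uniq, n_at_risk, n_events


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival) step table.

    Ties are handled by the simultaneous-death convention; censored
    observations leave the estimate flat but shrink later risk sets.
    """
    uniq, n_risk, n_ev = _sorted_risk_sets(times, events)
    surv = np.cumprod(1.0 - n_ev / n_risk)
    return pd.DataFrame(
        {"time": uniq, "survival": surv, "n_at_risk": n_risk, "n_events": n_ev}
    )


def nelson_aalen(times, events) -> pd.DataFrame:
    """Nelson–Aalen cumulative hazard Ĥ(t) = Σ_{t_k ≤ t} d_k/n_k."""
    uniq, n_risk, n_ev = _sorted_risk_sets(times, events)
    cumhaz = np.cumsum(n_ev / n_risk)
    return pd.DataFrame(
        {"time": uniq, "cumhaz": cumhaz, "n_at_risk": n_risk, "n_events": n_ev}
    )


def km_quantile(km: pd.DataFrame, p) -> np.ndarray:
    """Smallest observed time with Ŝ(t) ≤ 1-p; NaN where Ŝ never drops."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    out = np.full(p.shape, np.nan)
    s = km["survival"].to_numpy()
    t = km["time"].to_numpy()
    for i, pi in enumerate(p):
        hit = np.nonzero(s <= 1.0 - pi + 1e-12)[0]
        if hit.size:
            out[i] = t[hit[0]]
    return out


@dataclass
class ResidualSet:
    """Cox–Snell residuals plus their Nelson–Aalen cumulative hazard."""

    residuals: np.ndarray
    events: np.ndarray
    cumhaz: pd.DataFrame  # Nelson–Aalen over the residuals

    @property
    def origin_slope(self) -> float:
        """LS slope through the origin of Ĥ(r) against r; ≈ 1 when the
        fitted model is right (residuals unit-exponential)."""
        x = self.cumhaz["time"].to_numpy()
        y = self.cumhaz["cumhaz"].to_numpy()
        if not np.any(x > 0):
            return float("nan")
        return float(np.dot(x, y) / np.dot(x, x))


def cox_snell(fitted, ds, use_frailty: bool = True) -> ResidualSet:
    """Cox–Snell residuals of a fitted model on a dataset.

    By default the conditional residuals ẑ_i·Ĥ_c(t|x) using each cluster's
    posterior-mean frailty; ``use_frailty=False`` gives the marginal
    residuals -log S_marginal(t|x) with the frailty integrated out.
    """
    from .likelihood import _prepare  # shared design-matrix plumbing

    arr = _prepare(ds, fitted.model.covariates)
    spec = BaselineSpec(fitted.model.baseline, fitted.lam, fitted.rho)
    reg = RegressionSpec(fitted.model.formulation, np.array(list(fitted.coef.values())))
    cond = conditional_functions(spec, reg, arr.X, arr.t)
    if fitted.model.frailty is not None and use_frailty:
        zmap = dict(zip(fitted.cluster_table["cluster"], fitted.cluster_table["z_hat"]))
        z = np.array([zmap[c] for c in arr.cluster_ids])[arr.codes]
        r = z * cond["H"]
    elif fitted.model.frailty is not None:
        from .frailty import log_laplace

        r = -log_laplace(FrailtySpec(fitted.model.frailty, fitted.theta), cond["H"])
    else:
        r = cond["H"]
    na = nelson_aalen(r, arr.delta)
    return ResidualSet(residuals=r, events=arr.delta.astype(int), cumhaz=na)


def baseline_adequacy_coords(ds, family: str) -> dict:
    """Linearizing coordinates (and OLS R²) for one baseline family.

    exponential: (t, Ĥ(t)); weibull: (log t, log Ĥ(t)); loglogistic:
    (log t, log[(1-Ŝ)/Ŝ]).  Ĥ is Nelson–Aalen, Ŝ Kaplan–Meier; points where
    the transform is undefined (Ĥ = 0 or Ŝ ∈ {0,1}) are dropped and counted.
    """
    t = ds.frame["time"].to_numpy()
    d = ds.frame["event"].to_numpy()
    km = kaplan_meier(t, d)
    na = nelson_aalen(t, d)
    ev = na["n_events"].to_numpy() > 0
    if ev.sum() < 2:
        raise ValueError("need at least 2 distinct event times")
    times = na["time"].to_numpy()[ev]
    H = na["cumhaz"].to_numpy()[ev]
    S = km["survival"].to_numpy()[ev]
    dropped = 0
    if family == "exponential":
        x, y = times, H
    elif family == "weibull":
        keep = H > 0
        dropped = int((~keep).sum())
        x, y = np.log(times[keep]), np.log(H[keep])
    elif family == "loglogistic":
        keep = (S > 0) & (S < 1)
        dropped = int((~keep).sum())
        x = np.log(times[keep])
        y = np.log((1.0 - S[keep]) / S[keep])
    else:
        raise ValueError(f"unknown family {family!r}")
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate coordinates: fewer than 2 distinct x values")
    lr = linregress(x, y)
    r2 = 1.0 if len(x) == 2 else float(lr.rvalue**2)
    return {
        "family": family,
        "x": x,
        "y": y,
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "r_squared": r2,
        "n_dropped": dropped,
    }


def qq_aft(ds, covariate: str, level_a: str, level_b: str, probs=None) -> dict:
    """Paired KM quantiles of two covariate groups and the origin slope.

    Under an AFT model the quantiles of group b against group a fall on a
    line through the origin with slope equal to the acceleration factor of
    b relative to a.  Grid points where either group's quantile is
    undefined are dropped (and counted).
    """
    if probs is None:
        probs = np.arange(0.1, 0.91, 0.05)
    probs = np.asarray(probs, dtype=float)
    sub_a = ds.frame[ds.frame[covariate] == level_a]
    sub_b = ds.frame[ds.frame[covariate] == level_b]
    for lvl, sub in ((level_a, sub_a), (level_b, sub_b)):
        if sub["event"].sum() == 0:
            raise ValueError(f"group {lvl!r} contains no events")
    qa = km_quantile(kaplan_meier(sub_a["time"], sub_a["event"]), probs)
    qb = km_quantile(kaplan_meier(sub_b["time"], sub_b["event"]), probs)
    keep = np.isfinite(qa) & np.isfinite(qb)
    x, y = qa[keep], qb[keep]
    slope_origin = float(np.dot(x, y) / np.dot(x, x)) if np.any(x > 0) else float("nan")
    slope_ols = float(linregress(x, y).slope) if keep.sum() > 1 else float("nan")
    return {
        "probs": probs[keep],
        "quantiles_a": x,
        "quantiles_b": y,
        "slope_origin": slope_origin,
        "slope_ols": slope_ols,
        "n_dropped": int((~keep).sum()),
    }


def conditional_hazard_curves(
    fitted, frailty_probs=(0.25, 0.5, 0.75), t_grid=None, x=None, empirical: bool = False
) -> pd.DataFrame:
    """Conditional hazard h(t|x, z_p) = z_p h_c(t|x) at frailty quantiles.

    ``empirical=True`` takes z_p as quantiles of the fit's predicted
    cluster frailties instead of the theoretical frailty distribution.
    """
    if t_grid is None:
        t_grid = np.linspace(0.5, 63.0, 126)
    t_grid = np.asarray(t_grid, dtype=float)
    k = len(fitted.coef)
    x = np.zeros(k) if x is None else np.asarray(x, dtype=float)
    spec = BaselineSpec(fitted.model.baseline, fitted.lam, fitted.rho)
    reg = RegressionSpec(fitted.model.formulation, np.array(list(fitted.coef.values())))
    xg = np.broadcast_to(x, (t_grid.size, k))
    base_h = conditional_functions(spec, reg, xg, t_grid)["h"]
    rows = []
    for p in frailty_probs:
        if empirical:
            z = float(np.quantile(fitted.predicted_frailties, p))
        elif fitted.model.frailty is not None:
            z = float(frailty_quantile(FrailtySpec(fitted.model.frailty, fitted.theta), p))
        else:
            z = 1.0
        rows.append(pd.DataFrame({"p": p, "z": z, "t": t_grid, "hazard": z * base_h}))
    return pd.concat(rows, ignore_index=True)
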