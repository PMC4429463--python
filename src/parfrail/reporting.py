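"""Analysis-flow reporting: univariable screening, AIC model comparison,
and acceleration-factor tables.

The screening step fits one single-covariate model per candidate and keeps
a covariate when any non-reference level is Wald-significant at level α.
The comparison step fits a grid of baseline × frailty combinations on the
same data and ranks them by AIC (smallest best).  The acceleration table
turns an AFT fit into the familiar coefficient / SE / ϕ / 95% CI layout,
starring effects whose CI for ϕ excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .frailty import FrailtySpec, kendalls_tau
from .likelihood import FitError, ModelFit, ModelSpec, fit

_Z95 = 1.959963984540054

DEFAULT_GRID = tuple(
    (b, f)
    for b in ("exponential", "weibull", "loglogistic")
    for f in ("gamma", "invgauss")
)


def univariable_screen(
    ds,
    covariates,
    alpha: float = 0.05,
    baseline: str = "loglogistic",
    frailty: str | None = None,
) -> dict:
    """Fit one single-covariate model per candidate; keep the significant.

    A covariate is selected when any of its non-reference dummy levels has
    Wald p < α.  Covariates with a single observed level are skipped with a
    warning entry.  Default screening model is a no-frailty log-logistic
    AFT fit (cheap); both baseline and frailty are configurable.
    """
    if not covariates:
        raise ValueError("need at least one candidate covariate")
    selected, excluded, skipped = [], [], []
    fits: dict[str, ModelFit] = {}
    pvals: dict[str, float] = {}
    for name in covariates:
        observed = ds.frame[name].astype(str).nunique()
        if observed < 2:
            skipped.append(name)
            continue
        f = fit(ModelSpec(baseline, frailty, (name,)), ds)
        fits[name] = f
        z = np.array(
            [abs(f.coef[k]) / f.se[k] if f.se[k] > 0 else 0.0 for k in f.coef]
        )
        p = float(2.0 * norm.sf(z).min()) if z.size else 1.0
        pvals[name] = p
        (selected if p < alpha else excluded).append(name)
    return {
        "selected": selected,
        "excluded": excluded,
        "skipped": skipped,
        "fits": fits,
        "p_values": pvals,
        "alpha": alpha,
    }


@dataclass
class ComparisonTable:
    """AIC ranking of baseline × frailty combinations on shared data."""

    table: pd.DataFrame
    fits: dict[str, ModelFit]

    @property
    def best(self) -> str:
        return self.table.loc[self.table["best"], "model"].iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> str:
        return self.table.to_json(orient="records", indent=2)


def compare_models(
    ds, covariates, grid=DEFAULT_GRID, compute_se: bool = True
) -> ComparisonTable:
    """Fit every (baseline, frailty) combination and rank by AIC.

    The minimum-AIC model is flagged best; ties break toward fewer
    parameters, then lexicographic model name.  A combination whose fit
    fails is kept as a failed row so the comparison still completes.
    """
    if len(grid) < 2:
        raise ValueError("need at least two model specs to compare")
    rows, fits = [], {}
    base_fits: dict[str, ModelFit] = {}  # no-frailty warm starts per baseline
    for baseline, frailty in grid:
        spec = ModelSpec(baseline, frailty, tuple(covariates))
        row = {"baseline": baseline, "frailty": frailty or "none", "model": spec.label}
        try:
            init = None
            if frailty is not None:
                if baseline not in base_fits:
                    base_fits[baseline] = fit(
                        ModelSpec(baseline, None, tuple(covariates)), ds,
                        compute_se=False,
                    )
                bf = base_fits[baseline]
                init = {"beta": np.array(list(bf.coef.values())),
                        "lam": bf.lam, "rho": bf.rho, "theta": 0.1}
            f = fit(spec, ds, init=init, compute_se=compute_se)
        except (FitError, ValueError) as exc:
            row.update(aic=np.nan, loglik=np.nan, theta=np.nan, tau=np.nan,
                       n_params=np.nan, failed=True, error=str(exc))
            rows.append(row)
            continue
        fits[spec.label] = f
        tau = (
            kendalls_tau(FrailtySpec(frailty, f.theta)) if frailty is not None else np.nan
        )
        row.update(
            aic=f.aic, loglik=f.loglik, theta=f.theta, tau=tau,
            n_params=f.n_params, failed=False, error="",
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = ~table["failed"]
    order = table[ok].sort_values(
        ["aic", "n_params", "model"], kind="stable"
    ).index
    table["rank"] = np.nan
    table.loc[order, "rank"] = np.arange(1, ok.sum() + 1)
    table["best"] = False
    if len(order):
        table.loc[order[0], "best"] = True
    return ComparisonTable(table=table, fits=fits)


def acceleration_row(coef: float, se: float) -> dict:
    """ϕ = e^coef with the Wald 95% CI e^{coef ± 1.96·SE}; pure arithmetic."""
    phi = float(np.exp(coef))
    lo, hi = float(np.exp(coef - _Z95 * se)), float(np.exp(coef + _Z95 * se))
    return {
        "coef": coef,
        "se": se,
        "phi": phi,
        "ci_low": lo,
        "ci_high": hi,
        "significant": bool(lo > 1.0 or hi < 1.0),
    }


def acceleration_table(fitted: ModelFit) -> pd.DataFrame:
    """Acceleration-factor report of an AFT fit, reference rows included."""
    if fitted.model.formulation != "AFT":
        raise ValueError(
            "acceleration factors are defined for AFT fits; refit with "
            "formulation='AFT' (for Weibull, beta_AFT = -beta_PH/rho)"
        )
    rows = []
    for name in fitted.model.covariates:
        # non-reference levels in schema order, recovered from coefficient names
        labels = [k.split("[", 1)[1][:-1] for k in fitted.coef if k.startswith(f"{name}[")]
        rows.append(
            {"covariate": name, "level": "(ref)", "coef": 0.0, "se": np.nan,
             "phi": 1.0, "ci_low": np.nan, "ci_high": np.nan, "significant": False,
             "display": "Ref 1.000"}
        )
        for label in labels:
            key = f"{name}[{label}]"
            r = acceleration_row(fitted.coef[key], fitted.se[key])
            star = "*" if r["significant"] else ""
            rows.append(
                {"covariate": name, "level": label, **r,
                 "display": f"{r['phi']:.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f}){star}"}
            )
    return pd.DataFrame(rows)


def acceleration_markdown(fitted: ModelFit) -> str:
    """Markdown rendering of the acceleration-factor table."""
    tab = acceleration_table(fitted)
    lines = [
        "| Covariate | Level | Coef | S.E. | ϕ | 95% CI of ϕ |",
        "|---|---|---|---|---|---|",
    ]
    for _, r in tab.iterrows():
        if r["level"] == "(ref)":
            lines.append(f"| {r['covariate']} | Ref | — | — | 1.000 | — |")
        else:
            star = "*" if r["significant"] else ""
            lines.append(
                f"| {r['covariate']} | {r['level']} | {r['coef']:.3f} | "
                f"{r['se']:.3f} | {r['phi']:.3f} | "
                f"({r['ci_low']:.3f}, {r['ci_high']:.3f}){star} |"
            )
    return "\n".join(lines)
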