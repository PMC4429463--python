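"""Model-adequacy diagnostics for the best model.

Writes tidy coordinates for: the baseline-linearity plots (with OLS R² as
the linearity score), Cox–Snell residual cumulative hazards for all three
baselines, conditional hazard curves at the frailty quartiles, and q-q
acceleration-factor checks between covariate groups.  Pass --plots to also
render PNGs under scratch/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import parfrail as pf
from parfrail import diagnostics

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--plots", action="store_true", help="render PNGs to scratch/")
    args = ap.parse_args()

    ds = pf.load_dataset(RESULTS / "data" / "dataset.csv",
                         RESULTS / "data" / "schema.json")
    ds, _ = pf.filter_singleton_clusters(ds)
    comp = pd.read_csv(RESULTS / "comparison.csv")
    best = comp.loc[comp["best"], ["baseline", "frailty"]].iloc[0]
    screened = json.loads((RESULTS / "screen.json").read_text())["selected"]

    # baseline-linearity coordinates and R² scores
    rows, coords = [], []
    for fam in ("exponential", "weibull", "loglogistic"):
        co = diagnostics.baseline_adequacy_coords(ds, fam)
        rows.append({"family": fam, "r_squared": co["r_squared"],
                     "slope": co["slope"], "n_dropped": co["n_dropped"]})
        coords.append(pd.DataFrame({"family": fam, "x": co["x"], "y": co["y"]}))
    adequacy = pd.DataFrame(rows)
    adequacy.to_csv(RESULTS / "adequacy_r2.csv", index=False)
    pd.concat(coords).to_csv(RESULTS / "adequacy_coords.csv", index=False)
    ranked = adequacy.sort_values("r_squared", ascending=False)
    print("baseline linearity R²:",
          {r["family"]: round(r["r_squared"], 4) for _, r in ranked.iterrows()})

    # Cox–Snell residuals for all three baselines under the best frailty
    slopes = {}
    for fam in ("exponential", "weibull", "loglogistic"):
        f = pf.fit(pf.ModelSpec(fam, best["frailty"], tuple(screened)), ds,
                   compute_se=False)
        res = diagnostics.cox_snell(f, ds)
        res.cumhaz.assign(family=fam).to_csv(
            RESULTS / f"cox_snell_{fam}.csv", index=False)
        slopes[fam] = round(res.origin_slope, 3)
    print("Cox–Snell origin slopes (1 = adequate):", slopes)

    # conditional hazards at frailty quartiles + q-q check for co-infection
    fit = pf.fit(pf.ModelSpec(best["baseline"], best["frailty"], tuple(screened)),
                 ds, compute_se=False)
    curves = diagnostics.conditional_hazard_curves(fit)
    curves.to_csv(RESULTS / "conditional_hazards.csv", index=False)
    zq = curves.groupby("p")["z"].first()
    print("frailty quartiles (theoretical):",
          {p: round(v, 3) for p, v in zq.items()})

    qq = diagnostics.qq_aft(ds, "co_infection", "No", "Yes")
    pd.DataFrame({"p": qq["probs"], "q_no": qq["quantiles_a"],
                  "q_yes": qq["quantiles_b"]}).to_csv(
        RESULTS / "qq_co_infection.csv", index=False)
    print(f"q-q slope for co-infection (≈ acceleration factor): "
          f"{qq['slope_origin']:.3f}")

    if args.plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        scratch = ROOT / "scratch"
        scratch.mkdir(exist_ok=True)
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (fam, grp) in zip(axes, pd.concat(coords).groupby("family")):
            ax.plot(grp["x"], grp["y"], "o", ms=3)
            ax.set_title(fam)
        fig.savefig(scratch / "adequacy.png", dpi=120)
        fig, ax = plt.subplots()
        for p, grp in curves.groupby("p"):
            ax.plot(grp["t"], grp["hazard"], label=f"z at p={p}")
        ax.legend(); ax.set_xlabel("days"); ax.set_ylabel("hazard")
        fig.savefig(scratch / "conditional_hazards.png", dpi=120)
        print(f"plots under {scratch}")


if __name__ == "__main__":
    main()
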