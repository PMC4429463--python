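"""Univariable covariate screening.

Fits one single-covariate model per candidate (sex, age group,
malnutrition type, co-infection) and keeps those with any Wald-significant
non-reference level at the 5% level; only the survivors enter the
multivariable comparison.
"""

import json
from pathlib import Path

import parfrail as pf
from parfrail.reporting import univariable_screen

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = pf.load_dataset(RESULTS / "data" / "dataset.csv",
                         RESULTS / "data" / "schema.json")
    ds, _ = pf.filter_singleton_clusters(ds)
    out = univariable_screen(ds, list(ds.schema), alpha=0.05)

    payload = {k: out[k] for k in ("selected", "excluded", "skipped",
                                   "p_values", "alpha")}
    (RESULTS / "screen.json").write_text(json.dumps(payload, indent=2))

    print("univariable Wald p-values:",
          {k: round(v, 4) for k, v in out["p_values"].items()})
    print(f"selected for the multivariable model: {out['selected']}")
    print(f"excluded: {out['excluded']}")
    print(f"wrote {RESULTS / 'screen.json'}")


if __name__ == "__main__":
    main()
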