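"""Fit the crossed-random-effects multilevel model of life expectancy.

Stepwise covariate selection over the candidate set, a REML fit of the
retained model with environment-type and development-stage random
intercepts, a comparison of the estimates against the generator truth,
and grouped cross-validation against pooled linear regression.
"""

import json
from pathlib import Path

import pandas as pd

from geotree_le.mlm import cross_validate, fit_mlm, stepwise_select
from geotree_le.panel import read_panel
from geotree_le.synthetic import read_truth

OUT = Path("results")
SEED = 20301231


def main() -> None:
    panel = read_panel(OUT / "panel.csv")
    strata = pd.read_csv(OUT / "strata.csv")
    work = panel.drop(columns=["env_type", "stage"]).merge(
        strata, on=["region", "year"])
    truth = read_truth(OUT / "truth.json")

    selected, trace = stepwise_select(work, "le", criterion="bic")
    print(f"stepwise (BIC) kept {len(selected)} covariates: {sorted(selected)}")

    fit = fit_mlm(work, "le", selected)
    with open(OUT / "model.json", "w") as fh:
        json.dump(fit.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    print("fixed effects (vs truth):")
    for name, est in fit.beta.items():
        true = truth.beta.get(name if name != "intercept" else "intercept", 0.0)
        print(f"  {name:12s} {est:8.3f}   (truth {true:g})")
    print(f"variance components: "
          f"{ {k: round(v, 3) for k, v in fit.sigma2.items()} } "
          f"(truth {truth.sigma2_t}, {truth.sigma2_s}, {truth.sigma2_e})")
    print(f"type BLUPs {fit.blups['env_type'].round(3).to_dict()} "
          f"vs realized { {k: round(v, 3) for k, v in truth.u_t.items()} }")

    cv = cross_validate(work, "le", selected, n_folds=None, seed=SEED)
    cv.to_csv(OUT / "cv.csv", float_format="%.12g")
    print("leave-one-region-out cross-validation:")
    print(cv.round(3).to_string())


if __name__ == "__main__":
    main()
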