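"""Link latent class membership to MRI burden in the imaging subsample.

Reads the posterior classification from results/fit/ and the subject table
from results/cohort/, then (1) compares baseline characteristics across
modal classes and (2) fits posterior-weighted multinomial logistic
regressions of class membership on per-SD WM-SVID and AD-PS.  Writes
results/mri/associations.csv and results/mri/baseline_comparison.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from jlcmm import (baseline_comparison, standardize_exposure,
                   weighted_multinomial_fit)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "mri"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = pd.read_csv(ROOT / "cohort" / "subjects.csv")
    post = pd.read_csv(ROOT / "fit" / "posterior.csv")
    df = subjects.merge(post, on="subject_id")
    G = df["modal"].max()
    df["modal_weight"] = df[[f"p_{g}" for g in range(1, G + 1)]].max(axis=1)

    comp_rows = []
    for var, kind in [("age_at_baseline", "continuous"),
                      ("history_depression", "categorical")]:
        stat, p, method = baseline_comparison(df, "modal", var, kind)
        comp_rows.append({"variable": var, "method": method,
                          "statistic": stat, "p": p})
        print(f"{var}: {method} statistic {stat:.2f}, p = {p:.2g}")
    pd.DataFrame(comp_rows).to_csv(OUT / "baseline_comparison.csv",
                                   index=False)

    mri = df[df["wm_svid"].notna()].copy()
    print(f"\nMRI subsample: n = {len(mri)}")
    rows = []
    for exposure in ("wm_svid", "adps"):
        z, mean, sd = standardize_exposure(mri[exposure].to_numpy())
        res = weighted_multinomial_fit(
            mri["modal"].to_numpy(), mri["modal_weight"].to_numpy(),
            z[:, None], ref_class=1, exposure_names=[exposure])
        sub = res.table[res.table["term"] == exposure]
        for _, r in sub.iterrows():
            rows.append({"exposure": exposure, "class": int(r["class"]),
                         "or_per_sd": r["or_"], "ci_lo": r["ci_lo"],
                         "ci_hi": r["ci_hi"], "p": r["p"],
                         "exposure_mean": mean, "exposure_sd": sd})
            print(f"  {exposure} -> class {int(r['class'])}: "
                  f"OR/SD {r['or_']:.2f} [{r['ci_lo']:.2f}, "
                  f"{r['ci_hi']:.2f}], p = {r['p']:.3f}")
    pd.DataFrame(rows).to_csv(OUT / "associations.csv", index=False)
    print(f"\nwrote association tables to {OUT}")


if __name__ == "__main__":
    main()
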