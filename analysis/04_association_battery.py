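#!/usr/bin/env python
"""The association battery: treatment-response scores vs TRD status.

Joins the standardized scores and PCs onto each definition's
case-control roster, then runs, per definition x trait: the Welch
t-test on the mean score difference, PC-adjusted logistic regression
(OR per SD), Nagelkerke R2 with the liability conversion at K = 0.10,
and the quartile trend test.  BH-FDR is applied over the six primary
t-tests and the six primary regressions separately; sensitivity rows
rerun the models with lithium-using cases excluded.  Writes
results/association_results.csv and results/quartile_trends.csv.
"""

from pathlib import Path

import pandas as pd

from trdprs.assoc import quartile_trend, run_battery
from trdprs.phenotype import DEFINITIONS, build_comparison

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cls = pd.read_csv(ROOT / "classifications.csv", dtype={"subject_id": str})
    scores = pd.read_csv(ROOT / "scores.csv", dtype={"subject_id": str})
    pcs = pd.read_csv(ROOT / "pcs.csv", dtype={"subject_id": str}).set_index("subject_id")
    wide = scores.pivot(index="subject_id", columns="trait", values="z")
    wide.columns = [f"score_{t}" for t in wide.columns]
    lith = cls.set_index("subject_id")["lithium_user"]

    datasets = {}
    for definition in DEFINITIONS:
        roster = build_comparison(cls, definition)
        roster = roster[roster["subject_id"].isin(wide.index)]
        df = roster.set_index("subject_id").join(wide, how="inner").join(pcs, how="left")
        df["lithium_user"] = lith.loc[df.index].to_numpy()
        datasets[definition] = df.reset_index()

    results = run_battery(datasets)
    results.to_csv(ROOT / "association_results.csv", index=False, float_format="%.6g")

    trends = []
    for definition, df in datasets.items():
        for trait in ("lithium", "antidep"):
            tr = quartile_trend(df[f"score_{trait}"].to_numpy(), df["status"].to_numpy())
            trends.append({"definition": definition, "trait": trait,
                           "statistic": tr.statistic, "p_trend": tr.p,
                           **{f"case_prop_q{i+1}": v
                              for i, v in enumerate(tr.case_proportion)}})
    pd.DataFrame(trends).to_csv(ROOT / "quartile_trends.csv", index=False,
                                float_format="%.6g")

    primary = results[(results["covariate_set"] == "base")
                      & (~results["lithium_excluded"])]
    cols = ["definition", "trait", "n_cases", "n_controls", "mean_difference",
            "p_ttest", "p_ttest_fdr", "odds_ratio", "or_ci_low", "or_ci_high",
            "p_logistic", "p_logistic_fdr", "r2_nagelkerke", "r2_liability"]
    print("primary six-test battery:")
    print(primary[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print("\nquartile trend p-values (lithium):")
    li = [t for t in trends if t["trait"] == "lithium"]
    for t in li:
        print(f"  {t['definition']:>9}: p_trend = {t['p_trend']:.4g}  "
              f"case proportions "
              + ", ".join(f"Q{i+1} {t[f'case_prop_q{i+1}']:.2f}" for i in range(4)))
    print(f"\nwrote {ROOT / 'association_results.csv'}")


if __name__ == "__main__":
    main()
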