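#!/usr/bin/env python
"""Forest and quartile-proportion figures from the battery results.

Reads results/association_results.csv and results/quartile_trends.csv
and draws (A) per-SD odds ratios with 95% CIs per definition and
covariate set for the lithium-response score, and (B) TRD case
proportion per score quartile.  Figures land in results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"
FIGS = ROOT / "figures"


def forest(results: pd.DataFrame) -> None:
    li = results[(results["trait"] == "lithium") & (~results["lithium_excluded"])]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharex=True)
    for ax, definition in zip(axes, ("broad", "narrow_1", "narrow_2")):
        sub = li[li["definition"] == definition]
        y = np.arange(len(sub))
        ax.errorbar(
            sub["odds_ratio"], y,
            xerr=[sub["odds_ratio"] - sub["or_ci_low"],
                  sub["or_ci_high"] - sub["odds_ratio"]],
            fmt="o", capsize=3,
        )
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y, sub["covariate_set"])
        ax.set_title(definition)
        ax.set_xlabel("OR per SD of lithium-response PRS")
    fig.tight_layout()
    fig.savefig(FIGS / "forest_lithium.png", dpi=150)


def quartiles(trends: pd.DataFrame) -> None:
    li = trends[trends["trait"] == "lithium"]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, (_, row) in zip(axes, li.iterrows()):
        props = [row[f"case_prop_q{i + 1}"] for i in range(4)]
        ax.bar(["Q1", "Q2", "Q3", "Q4"], props)
        ax.set_title(f"{row['definition']} (p_trend = {row['p_trend']:.2g})")
        ax.set_ylabel("TRD case proportion")
    fig.tight_layout()
    fig.savefig(FIGS / "quartile_proportions.png", dpi=150)


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    forest(pd.read_csv(ROOT / "association_results.csv"))
    quartiles(pd.read_csv(ROOT / "quartile_trends.csv"))
    print(f"wrote figures under {FIGS}")


if __name__ == "__main__":
    main()
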