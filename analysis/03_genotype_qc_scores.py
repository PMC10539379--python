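#!/usr/bin/env python
"""Genotype QC, ancestry screening, PCs, and polygenic scoring.

Reads the PLINK fileset from results/study/, applies the SNP screens
(call rate, invariance, exact HWE in cases/controls, differential
missingness, MAF), the sample screens (call rate, F_HET, sex check),
relatedness pruning at pi-hat > 0.2, and an ancestry-outlier screen
against a simulated two-population reference panel.  Scores both
treatment-response weight tables on the QC-passed data and writes
scores, PCs and the QC report under results/.
"""

import json
from pathlib import Path

import pandas as pd

from trdprs import io as tio
from trdprs.genoprs import (
    ancestry_outliers,
    filter_weights,
    relatedness_prune,
    sample_qc,
    score,
    snp_qc,
)
from trdprs.pipeline import compute_pcs
from trdprs.synthdata import simulate_reference_panel

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = ROOT / "study"
    G = tio.read_plink(study / "genotypes")
    subjects = pd.read_csv(study / "subjects.csv", dtype={"subject_id": str})
    cls = pd.read_csv(ROOT / "classifications.csv", dtype={"subject_id": str})
    status = (
        cls.set_index("subject_id").loc[G.subjects, "label_broad"].eq("TRD").astype(int)
    )

    reports = {}
    rep = snp_qc(G, status.to_numpy())
    reports["snp"] = rep
    G = G.take_variants(rep.retained_mask)

    meta = subjects.set_index("subject_id").loc[G.subjects]
    rep = sample_qc(G, meta["reported_sex"].to_numpy(object),
                    meta["x_het_rate"].to_numpy(float))
    reports["sample"] = rep
    G = G.take_subjects(rep.retained_mask)

    rep = relatedness_prune(G)
    reports["relatedness"] = rep
    G = G.take_subjects(rep.retained_mask)

    ref, pops = simulate_reference_panel(G, n_per_population=200, seed=99)
    rep = ancestry_outliers(G, ref, pops, target_population="EUR", sd_threshold=6)
    reports["ancestry"] = rep
    G = G.take_subjects(rep.retained_mask)

    for name, r in reports.items():
        print(r.summary())
    with open(ROOT / "qc_report.json", "w") as fh:
        json.dump({k: r.to_dict() for k, r in reports.items()}, fh, indent=2)

    pcs = compute_pcs(G, 4)
    pcs.to_csv(ROOT / "pcs.csv", index=False, float_format="%.10g")

    frames = []
    for trait in ("lithium", "antidep"):
        weights = tio.read_weight_table(study / f"weights_{trait}.tsv")
        filtered, counts = filter_weights(weights, G)
        print(f"{trait}: scoring {len(filtered)} SNPs "
              f"(removed {sum(counts.values())}: {counts})")
        frames.append(score(G, filtered, trait=trait))
    scores = pd.concat(frames, ignore_index=True)
    scores.to_csv(ROOT / "scores.csv", index=False, float_format="%.10g")
    print(f"wrote scores for {G.n_subjects} QC-passed subjects under {ROOT}")


if __name__ == "__main__":
    main()
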