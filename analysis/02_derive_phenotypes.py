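#!/usr/bin/env python
"""Derive TRD / non-TRD labels from the register files.

Reads the prescription and ECT tables written by 01_simulate_study.py,
builds treatment episodes (120-day gap rule, 42-day adequacy), and
classifies every subject under the broad, narrow_1 and narrow_2
definitions.  Writes results/classifications.csv and prints the case
attrition from the broad to the narrow definitions.
"""

from pathlib import Path

import pandas as pd

from trdprs import io as tio
from trdprs.phenotype import DEFINITIONS, PhenotypeParams, case_counts, classify_all

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = ROOT / "study"
    subjects = pd.read_csv(study / "subjects.csv", dtype={"subject_id": str})
    prescriptions = tio.read_prescriptions(study / "prescriptions.csv")
    ect = tio.read_ect_events(study / "ect_events.csv")

    cls = classify_all(subjects, prescriptions, ect, PhenotypeParams())
    cls.to_csv(ROOT / "classifications.csv", index=False)

    counts = case_counts(cls)
    n_ect = int(cls["first_ect_date"].notna().sum())
    print(f"classified {len(cls)} subjects; {n_ect} with ECT")
    for d in DEFINITIONS:
        n_tr = counts[d]
        n_ctl = int((cls[f"label_{d}"] == "non-TRD").sum())
        n_exc = int((cls[f"label_{d}"] == "excluded").sum())
        extra = f" ({n_tr / n_ect:.1%} of ECT cases)" if d != "broad" else ""
        print(f"  {d:>9}: {n_tr} TRD / {n_ctl} non-TRD / {n_exc} excluded{extra}")
    print(f"lithium users: {int(cls['lithium_user'].sum())}")
    print(f"wrote {ROOT / 'classifications.csv'}")


if __name__ == "__main__":
    main()
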