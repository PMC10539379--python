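"""TRD / non-TRD classification from prescription and ECT histories.

Treatment-resistant depression (TRD) is operationalized from register
data under three nested definitions:

* ``broad`` — TRD iff the subject ever received electroconvulsive
  therapy (ECT); everyone without ECT is non-TRD.
* ``narrow_1`` — TRD iff ECT was preceded by >= 1 distinct
  antidepressant (ATC ``N06A``) with an adequate treatment episode
  (>= 42 days) ending strictly before the first ECT date.
* ``narrow_2`` — as narrow_1 but requiring >= 2 distinct adequate
  antidepressants.

ECT subjects failing a narrow criterion are *excluded* from that narrow
comparison — they can never serve as controls.  Non-ECT subjects are
non-TRD under the narrow definitions only if they carry at most
``max_adequate_for_control`` adequate antidepressants over their whole
record (the likely antidepressant responders); those with more are
excluded from the narrow comparisons but remain non-TRD under the broad
one.  Lithium use (ATC ``N05AN01``) anywhere in the record is flagged
for the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .episodes import (
    DEFAULT_ADEQUATE_DAYS,
    DEFAULT_GAP_DAYS,
    adequate_episodes,
    build_episodes,
    count_distinct_adequate_before,
    validate_prescriptions,
)

DEFINITIONS = ("broad", "narrow_1", "narrow_2")
TRD, NON_TRD, EXCLUDED = "TRD", "non-TRD", "excluded"

ATC_ANTIDEPRESSANT_PREFIX = "N06A"
ATC_LITHIUM = "N05AN01"


@dataclass(frozen=True)
class PhenotypeParams:
    """Classification thresholds, with register-convention defaults."""

    gap_days: int = DEFAULT_GAP_DAYS
    adequate_days: int = DEFAULT_ADEQUATE_DAYS
    antidep_prefix: str = ATC_ANTIDEPRESSANT_PREFIX
    lithium_code: str = ATC_LITHIUM
    #: non-TRD controls may carry at most this many adequate antidepressants
    max_adequate_for_control: int = 2
    #: narrow controls must have at least one antidepressant record
    #: (adequacy not required); the broad comparison never requires one
    control_requires_antidep: bool = True
    #: required distinct adequate antidepressants before first ECT
    narrow1_min_adequate: int = 1
    narrow2_min_adequate: int = 2


CLASSIFICATION_COLUMNS = [
    "subject_id",
    "first_ect_date",
    "n_adequate_antidep_before_ect",
    "n_adequate_antidep_total",
    "label_broad",
    "label_narrow_1",
    "label_narrow_2",
    "lithium_user",
    "exclusion_reason",
]


def classify(
    subject_id: str,
    prescriptions: pd.DataFrame,
    ect_events: pd.DataFrame,
    params: PhenotypeParams = PhenotypeParams(),
) -> dict:
    """Classify one subject under all three definitions.

    ``prescriptions`` and ``ect_events`` must already be restricted to
    this subject (rows for other subjects raise).  Returns a plain dict
    with the :data:`CLASSIFICATION_COLUMNS` fields.
    """
    if len(prescriptions) > 0:
        other = set(prescriptions["subject_id"].unique()) - {subject_id}
        if other:
            raise ValueError(f"prescriptions contain foreign subjects: {sorted(other)[:3]}")
        prescriptions = validate_prescriptions(prescriptions)
    if len(ect_events) > 0:
        other = set(ect_events["subject_id"].unique()) - {subject_id}
        if other:
            raise ValueError(f"ect_events contain foreign subjects: {sorted(other)[:3]}")

    has_ect = len(ect_events) > 0
    first_ect = int(ect_events["date"].min()) if has_ect else None

    antidep = (
        prescriptions.loc[
            prescriptions["atc_code"].str.startswith(params.antidep_prefix)
        ]
        if len(prescriptions)
        else prescriptions
    )
    lithium_user = bool(
        len(prescriptions) and (prescriptions["atc_code"] == params.lithium_code).any()
    )

    if len(antidep):
        total_adequate = int(
            adequate_episodes(
                build_episodes(antidep, gap_days=params.gap_days),
                params.adequate_days,
            )["atc_code"].nunique()
        )
    else:
        total_adequate = 0

    n_before = None
    if has_ect:
        n_before = count_distinct_adequate_before(
            prescriptions,
            cutoff_date=first_ect,
            atc_prefix=params.antidep_prefix,
            gap_days=params.gap_days,
            min_days=params.adequate_days,
        )

    reasons = []
    if has_ect:
        label_broad = TRD
        if n_before >= params.narrow1_min_adequate:
            label_n1 = TRD
        else:
            label_n1 = EXCLUDED
            reasons.append("ect_without_adequate_antidep_narrow_1")
        if n_before >= params.narrow2_min_adequate:
            label_n2 = TRD
        else:
            label_n2 = EXCLUDED
            if "ect_without_adequate_antidep_narrow_1" not in reasons:
                reasons.append("ect_without_adequate_antidep_narrow_2")
    else:
        label_broad = NON_TRD
        control_ok = total_adequate <= params.max_adequate_for_control
        if params.control_requires_antidep and len(antidep) == 0:
            control_ok = False
            reasons.append("no_antidepressant_record")
        if total_adequate > params.max_adequate_for_control:
            reasons.append("too_many_adequate_antidepressants")
        label_n1 = label_n2 = NON_TRD if control_ok else EXCLUDED

    return {
        "subject_id": subject_id,
        "first_ect_date": first_ect,
        "n_adequate_antidep_before_ect": n_before,
        "n_adequate_antidep_total": total_adequate,
        "label_broad": label_broad,
        "label_narrow_1": label_n1,
        "label_narrow_2": label_n2,
        "lithium_user": lithium_user,
        "exclusion_reason": ";".join(reasons),
    }


def classify_all(
    subjects: pd.DataFrame,
    prescriptions: pd.DataFrame,
    ect_events: pd.DataFrame,
    params: PhenotypeParams = PhenotypeParams(),
) -> pd.DataFrame:
    """Classify every subject in the roster; one row per subject.

    Subjects referenced by prescriptions or ECT events but absent from
    the roster raise, so silent phenotype loss cannot occur.
    """
    roster = list(subjects["subject_id"])
    roster_set = set(roster)
    for name, df, col in (
        ("prescriptions", prescriptions, "subject_id"),
        ("ect_events", ect_events, "subject_id"),
    ):
        if len(df):
            unknown = set(df[col].unique()) - roster_set
            if unknown:
                raise ValueError(
                    f"{name} reference subjects absent from roster: {sorted(unknown)[:3]}"
                )
    rx_groups = (
        dict(tuple(prescriptions.groupby("subject_id", sort=False)))
        if len(prescriptions)
        else {}
    )
    ect_groups = (
        dict(tuple(ect_events.groupby("subject_id", sort=False)))
        if len(ect_events)
        else {}
    )
    empty_rx = prescriptions.iloc[0:0]
    empty_ect = ect_events.iloc[0:0] if len(ect_events) else pd.DataFrame(
        {"subject_id": pd.Series(dtype=object), "date": pd.Series(dtype="int64")}
    )
    rows = [
        classify(
            sid,
            rx_groups.get(sid, empty_rx),
            ect_groups.get(sid, empty_ect),
            params,
        )
        for sid in roster
    ]
    out = pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)
    out["first_ect_date"] = out["first_ect_date"].astype("Int64")
    out["n_adequate_antidep_before_ect"] = out[
        "n_adequate_antidep_before_ect"
    ].astype("Int64")
    return out


def build_comparison(
    classifications: pd.DataFrame,
    definition: str,
    exclude_lithium_users: bool = False,
) -> pd.DataFrame:
    """Case/control roster for one definition.

    Returns a frame with ``subject_id`` and ``status`` (1 = TRD case,
    0 = non-TRD control); excluded subjects are dropped.  With
    ``exclude_lithium_users`` the lithium-exposed *cases* are removed
    (controls are untouched), matching the sensitivity analysis that
    asks whether the lithium-response signal is driven by lithium use
    among the treatment-resistant.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"definition must be one of {DEFINITIONS}, got {definition!r}")
    if len(classifications) == 0:
        raise ValueError("no classifications supplied")
    col = f"label_{definition}"
    labels = classifications[col]
    keep = labels != EXCLUDED
    roster = classifications.loc[keep, ["subject_id", col, "lithium_user"]].copy()
    roster["status"] = (roster[col] == TRD).astype(int)
    if exclude_lithium_users:
        roster = roster.loc[~((roster["status"] == 1) & roster["lithium_user"])]
    n_cases = int((roster["status"] == 1).sum())
    n_controls = int((roster["status"] == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"unanalyzable comparison under {definition!r}: "
            f"{n_cases} cases / {n_controls} controls"
        )
    return roster[["subject_id", "status"]].reset_index(drop=True)


def case_counts(classifications: pd.DataFrame) -> dict:
    """TRD case count per definition (nesting: broad >= narrow_1 >= narrow_2)."""
    return {
        d: int((classifications[f"label_{d}"] == TRD).sum()) for d in DEFINITIONS
    }
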