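"""Treatment-episode construction from prescription-register records.

A *treatment episode* is a maximal run of dispenses of the same drug
(full ATC code) for one subject in which consecutive dispense dates are
no more than ``gap_days`` apart.  An episode is *adequate* when it spans
at least ``min_days`` from first to last dispense — the register proxy
for a sustained treatment trial, long enough for a therapeutic effect
and distinguishable from an immediate switch due to side effects.

Records are plain pandas DataFrames with columns ``subject_id``,
``atc_code`` and ``dispense_date`` (integer day offsets from the study
epoch); calendar formatting belongs at I/O boundaries only.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

#: Default maximum within-episode gap between consecutive dispenses (days).
DEFAULT_GAP_DAYS = 120
#: Default minimum first-to-last span for an adequate episode (six weeks).
DEFAULT_ADEQUATE_DAYS = 42

PRESCRIPTION_COLUMNS = ["subject_id", "atc_code", "dispense_date"]
EPISODE_COLUMNS = [
    "subject_id",
    "atc_code",
    "start_date",
    "end_date",
    "n_dispenses",
    "duration_days",
]


def _empty_episodes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": pd.Series(dtype=object),
            "atc_code": pd.Series(dtype=object),
            "start_date": pd.Series(dtype="int64"),
            "end_date": pd.Series(dtype="int64"),
            "n_dispenses": pd.Series(dtype="int64"),
            "duration_days": pd.Series(dtype="int64"),
        }
    )


def validate_prescriptions(records: pd.DataFrame) -> pd.DataFrame:
    """Check the prescription-record contract and return a clean copy.

    Requires the three canonical columns, non-empty uppercase
    alphanumeric ATC codes and finite integer dispense dates.
    """
    missing = [c for c in PRESCRIPTION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"prescription records missing columns: {missing}")
    out = records.loc[:, PRESCRIPTION_COLUMNS].copy()
    atc = out["atc_code"].astype(str)
    bad = ~atc.str.fullmatch(r"[A-Z0-9]+")
    if bad.any():
        examples = sorted(atc[bad].unique()[:5])
        raise ValueError(f"invalid ATC codes (need uppercase alphanumeric): {examples}")
    out["atc_code"] = atc
    dates = pd.to_numeric(out["dispense_date"], errors="raise")
    if not pd.api.types.is_integer_dtype(dates) and not (dates == dates.round()).all():
        raise ValueError("dispense_date must be integer day offsets")
    out["dispense_date"] = dates.astype("int64")
    return out


def build_episodes(
    records: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS
) -> pd.DataFrame:
    """Group dispenses into treatment episodes per (subject, ATC code).

    Records are sorted by date within each subject x drug group; a new
    episode starts whenever the gap to the previous dispense of the same
    drug is strictly greater than ``gap_days`` (a gap of exactly
    ``gap_days`` stays within the episode).  Duplicate
    (subject, drug, date) rows are collapsed to a single dispense.

    Returns one row per episode with start/end dates, the number of
    dispenses and the duration in days (end minus start).
    """
    if gap_days <= 0:
        raise ValueError(f"gap_days must be positive, got {gap_days}")
    if len(records) == 0:
        return _empty_episodes()
    rec = validate_prescriptions(records)
    n_before = len(rec)
    rec = rec.drop_duplicates(PRESCRIPTION_COLUMNS)
    if len(rec) < n_before:
        logger.info("collapsed %d duplicate prescription rows", n_before - len(rec))
    rec = rec.sort_values(PRESCRIPTION_COLUMNS, kind="mergesort").reset_index(drop=True)

    grp = rec.groupby(["subject_id", "atc_code"], sort=False)
    gap = rec["dispense_date"] - grp["dispense_date"].shift(1)
    # First record of each group, or a gap beyond the limit, opens an episode.
    new_episode = gap.isna() | (gap > gap_days)
    rec["episode_idx"] = new_episode.cumsum()

    agg = rec.groupby(["subject_id", "atc_code", "episode_idx"], sort=False).agg(
        start_date=("dispense_date", "min"),
        end_date=("dispense_date", "max"),
        n_dispenses=("dispense_date", "size"),
    )
    agg = agg.reset_index().drop(columns="episode_idx")
    agg["duration_days"] = agg["end_date"] - agg["start_date"]
    return agg[EPISODE_COLUMNS]


def adequate_episodes(
    episodes: pd.DataFrame, min_days: int = DEFAULT_ADEQUATE_DAYS
) -> pd.DataFrame:
    """Keep episodes whose first-to-last span is at least ``min_days``.

    The boundary is inclusive: a 42-day episode qualifies under the
    six-week default.
    """
    if min_days < 0:
        raise ValueError(f"min_days must be >= 0, got {min_days}")
    if len(episodes) == 0:
        return _empty_episodes()
    return episodes.loc[episodes["duration_days"] >= min_days].reset_index(drop=True)


def count_distinct_adequate_before(
    records: pd.DataFrame,
    cutoff_date: int,
    atc_prefix: str = "N06A",
    gap_days: int = DEFAULT_GAP_DAYS,
    min_days: int = DEFAULT_ADEQUATE_DAYS,
) -> int:
    """Number of distinct drugs with an adequate episode before a cutoff.

    Restricts to records whose ATC code starts with ``atc_prefix`` and
    whose dispense date is strictly before ``cutoff_date`` (a dispense
    on the cutoff day does not count), rebuilds episodes on the
    truncated record set, and counts distinct full ATC codes carrying at
    least one adequate episode.  Episodes spanning the cutoff therefore
    contribute only their pre-cutoff dispenses, and adequacy is
    re-evaluated on the truncated chain.
    """
    if len(records) == 0:
        return 0
    rec = validate_prescriptions(records)
    mask = rec["atc_code"].str.startswith(atc_prefix) & (
        rec["dispense_date"] < cutoff_date
    )
    rec = rec.loc[mask]
    if len(rec) == 0:
        return 0
    adequate = adequate_episodes(build_episodes(rec, gap_days=gap_days), min_days)
    return int(adequate["atc_code"].nunique())
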