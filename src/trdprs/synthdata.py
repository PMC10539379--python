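"""Synthetic study generator: register histories, genotypes, weights.

Emulates the statistical structure of a three-cohort MDD case sample
(~4,500 subjects: an ECT-referral cohort, an internet-psychotherapy
cohort and a population-register cohort) with everything the downstream
pipeline consumes:

* per-subject genotypes at a few thousand independent post-imputation
  SNPs (0/1/2 allele counts, binomial at per-SNP frequencies);
* one effect-allele weight table per trait, already LD-rescaled in
  spirit, deliberately salted with SNPs violating each score filter
  (low MAF, low INFO, strand-ambiguous alleles, MHC positions,
  duplicate ids) so the filters are exercised;
* latent standardized trait scores and TRD status drawn from a
  logistic model — logit P(TRD) = logit(base rate)
  + log(OR_lithium) * z_lithium + log(OR_antidep) * z_antidep;
* ATC-coded prescription chains and ECT dates consistent with the
  intended phenotype labels, with configurable fractions of subjects
  whose histories fail the narrow criteria (ECT with no prior
  antidepressant; chains broken by > gap_days so no episode is
  adequate), mirroring the observed attrition from the broad to the
  narrow definitions.

Dates are integer day offsets from the study epoch.  All randomness
flows from a single seed through named child streams, so regenerating
with the same configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genoprs import GenotypeMatrix

COHORTS = ("ect_referral", "psychotherapy", "population")

#: default fractions of ECT subjects by pre-ECT antidepressant history:
#: (no antidepressant, records but none adequate, exactly one adequate);
#: the remainder has >= 2 adequate.  Chosen to reproduce the observed
#: broad -> narrow_1 -> narrow_2 attrition (94.2% / 83.6% / 60.8%).
DEFAULT_TRD_HISTORY_MIX = (0.0585, 0.1052, 0.2283)
#: fraction of non-ECT subjects given >= 3 adequate antidepressants
#: (excluded from the narrow comparisons), matching 1 - 1483/2264.
DEFAULT_CONTROL_EXCESS = 0.345

_ANTIDEPRESSANTS = (
    "N06AB03", "N06AB04", "N06AB05", "N06AB06", "N06AB08", "N06AB10",
    "N06AA04", "N06AA09", "N06AX11", "N06AX12", "N06AX16", "N06AX21",
)
ATC_LITHIUM = "N05AN01"

_NONAMBIGUOUS_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
_AMBIGUOUS_PAIRS = (("A", "T"), ("C", "G"))

_INVALID_CLASSES = ("low_maf", "low_info", "ambiguous", "mhc", "duplicate")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the study design."""

    n_subjects: int = 4500
    #: ECT-referral, psychotherapy, population cohort shares
    cohort_fractions: tuple = (0.42, 0.21, 0.37)
    n_snps: int = 2000
    maf_range: tuple = (0.15, 0.5)
    or_per_sd_lithium: float = 1.12
    or_per_sd_antidep: float = 0.98
    base_trd_rate: float = 0.44
    gap_days: int = 120
    adequate_days: int = 42
    missing_rate: float = 0.01
    seed: int = 0
    # --- structure knobs beyond the headline design ---
    traits: tuple = ("lithium", "antidep")
    #: deliberately filter-violating weight-table SNPs per class
    n_invalid_per_filter: int = 5
    #: share of valid weight rows listing the target's second allele as
    #: effect allele (exercises allele reconciliation)
    flip_fraction: float = 0.2
    trd_history_mix: tuple = DEFAULT_TRD_HISTORY_MIX
    control_excess_fraction: float = DEFAULT_CONTROL_EXCESS
    lithium_user_fraction: float = 0.30
    sex_mismatch_rate: float = 0.0
    #: subjects drawn from a frequency-shifted second population
    ancestry_outlier_fraction: float = 0.0
    ancestry_freq_shift: float = 0.2
    first_ect_day_range: tuple = (400, 1200)
    history_end_day: int = 1200

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be >= 1")
        if abs(sum(self.cohort_fractions) - 1.0) > 1e-9 or len(self.cohort_fractions) != 3:
            raise ValueError("cohort_fractions must be three proportions summing to 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5] with lo <= hi")
        for name in ("or_per_sd_lithium", "or_per_sd_antidep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "base_trd_rate", "missing_rate", "lithium_user_fraction",
            "sex_mismatch_rate", "ancestry_outlier_fraction", "flip_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gap_days <= 0 or self.adequate_days < 0:
            raise ValueError("gap_days must be > 0 and adequate_days >= 0")
        mix = self.trd_history_mix
        if len(mix) != 3 or min(mix) < 0 or sum(mix) > 1:
            raise ValueError("trd_history_mix must be 3 non-negative shares summing <= 1")
        n_invalid = self.n_invalid_per_filter * len(_INVALID_CLASSES)
        if self.n_snps < n_invalid + 10:
            raise ValueError(
                f"n_snps={self.n_snps} too small for {n_invalid} deliberately "
                "invalid SNPs plus a scoring backbone"
            )
        if self.adequate_days > self.first_ect_day_range[0] - 60:
            raise ValueError(
                "adequate_days too long to fit an episode before the earliest ECT date"
            )


@dataclass
class SyntheticStudy:
    """A complete simulated study plus the generating truth."""

    subjects: pd.DataFrame          # subject_id, cohort, reported_sex, x_het_rate
    prescriptions: pd.DataFrame     # subject_id, atc_code, dispense_date
    ect_events: pd.DataFrame        # subject_id, date
    genotypes: GenotypeMatrix       # with missingness injected
    weights: dict                   # trait -> weight table (DataFrame)
    truth: pd.DataFrame             # subject_id, z_<trait>, p_trd, trd
    config: SimulationConfig = None

    def validate(self) -> None:
        ids = set(self.subjects["subject_id"])
        for name, df in (("prescriptions", self.prescriptions), ("ect_events", self.ect_events)):
            if len(df) and not set(df["subject_id"]) <= ids:
                raise AssertionError(f"{name} reference unknown subjects")
        if set(self.truth["subject_id"]) != ids:
            raise AssertionError("truth table must cover all subjects exactly")


def _streams(seed: int, *names: str) -> dict:
    """Named, order-independent child RNGs derived from one seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# genotypes + weights


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Genotype matrix plus one weight table per trait.

    Variants are independent; dosages are Binomial(2, p) per subject
    with p drawn uniformly from ``maf_range``.  The first
    ``n_invalid_per_filter`` x 5 weight-table rows violate, one class
    each, the score filters (summary MAF < 0.1, INFO < 0.9, A/T / C/G
    alleles, chr6:28-34 Mb, duplicated ids); everything else is
    scorable.  ``missing_rate`` of calls is masked to NaN.  The weight
    table columns follow the summary-statistics convention
    (id/chrom/pos/effect_allele/other_allele/eaf/weight/info/p).
    """
    if rng is None:
        rng = _streams(config.seed, "genotypes")["genotypes"]
    m = config.n_snps
    k = config.n_invalid_per_filter
    lo, hi = config.maf_range

    chrom = rng.integers(1, 23, size=m)
    pos = rng.integers(1, 120_000_000, size=m)
    # keep ordinary SNPs out of the MHC so only the salted class sits there
    in_mhc = (chrom == 6) & (pos >= 28_000_000) & (pos <= 34_000_000)
    pos[in_mhc] += 40_000_000
    pair_idx = rng.integers(0, len(_NONAMBIGUOUS_PAIRS), size=m)
    a1 = np.array([_NONAMBIGUOUS_PAIRS[i][0] for i in pair_idx], dtype=object)
    a2 = np.array([_NONAMBIGUOUS_PAIRS[i][1] for i in pair_idx], dtype=object)
    freq = rng.uniform(lo, hi, size=m)
    info = rng.uniform(0.92, 1.0, size=m)

    # salt the first 5k variants, one deliberately invalid class each
    sl = {c: slice(i * k, (i + 1) * k) for i, c in enumerate(_INVALID_CLASSES)}
    freq[sl["low_maf"]] = rng.uniform(0.02, 0.08, size=k)
    info[sl["low_info"]] = rng.uniform(0.5, 0.89, size=k)
    amb = [_AMBIGUOUS_PAIRS[i] for i in rng.integers(0, 2, size=k)]
    a1[sl["ambiguous"]] = [p[0] for p in amb]
    a2[sl["ambiguous"]] = [p[1] for p in amb]
    chrom[sl["mhc"]] = 6
    pos[sl["mhc"]] = rng.integers(28_000_000, 34_000_001, size=k)

    ids = np.array([f"rs{100000 + i}" for i in range(m)], dtype=object)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chrom, "pos": pos, "a1": a1, "a2": a2}
    )

    dosages = rng.binomial(2, freq, size=(config.n_subjects, m)).astype(float)
    if config.ancestry_outlier_fraction > 0:
        n_out = int(round(config.ancestry_outlier_fraction * config.n_subjects))
        if n_out:
            shift = np.where(freq < 0.5, config.ancestry_freq_shift, -config.ancestry_freq_shift)
            freq_out = np.clip(freq + shift, 0.01, 0.99)
            dosages[-n_out:, :] = rng.binomial(2, freq_out, size=(n_out, m))

    weights = {}
    scorable = np.ones(m, dtype=bool)
    for c in _INVALID_CLASSES:
        scorable[sl[c]] = False
    for trait in config.traits:
        beta = rng.normal(0.0, 1.0 / np.sqrt(max(scorable.sum(), 1)), size=m)
        flip = rng.random(m) < config.flip_fraction
        tbl = pd.DataFrame(
            {
                "id": ids,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": np.where(flip, a2, a1),
                "other_allele": np.where(flip, a1, a2),
                "eaf": np.where(flip, 1.0 - freq, freq),
                # orientation-consistent effects: flipped rows carry the
                # effect of the other allele, so negate
                "weight": np.where(flip, -beta, beta),
                "info": info,
                "p": rng.uniform(0.0, 1.0, size=m),
            }
        )
        dup = tbl.iloc[sl["duplicate"]].copy()
        dup["weight"] = dup["weight"] + rng.normal(0, 0.01, size=len(dup))
        tbl = pd.concat([tbl, dup], ignore_index=True)
        weights[trait] = tbl

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    subjects = np.array(
        [f"S{i:06d}" for i in range(config.n_subjects)], dtype=object
    )
    return GenotypeMatrix(subjects, variants, dosages), weights


def _true_scores(
    G: GenotypeMatrix, weight_table: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Latent standardized score from the scorable weight rows."""
    tbl = weight_table.drop_duplicates("id", keep=False)
    scorable = (
        (tbl["eaf"].between(0.1, 0.9))
        & (tbl["info"] >= 0.9)
        & ~tbl.apply(
            lambda r: (r["effect_allele"], r["other_allele"]) in
            {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")},
            axis=1,
        )
        & ~((pd.to_numeric(tbl["chrom"]) == 6)
            & tbl["pos"].between(28_000_000, 34_000_000))
    )
    tbl = tbl.loc[scorable]
    if len(tbl) == 0:
        raise ValueError("weight table has no scorable SNPs")
    gidx = pd.Index(G.variants["id"]).get_indexer(tbl["id"])
    D = G.dosages[:, gidx]
    if np.isnan(D).any():  # latent scores use the pre-masking genotypes
        D = np.where(np.isnan(D), 2.0 * tbl["eaf"].to_numpy(), D)
    flip = (tbl["effect_allele"].to_numpy()
            == G.variants["a2"].to_numpy()[gidx])
    eff = np.where(flip, 2.0 - D, D)
    raw = eff @ tbl["weight"].to_numpy()
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate latent score (zero variance)")
    return (raw - raw.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    weights: dict,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent standardized scores and Bernoulli TRD status per subject.

    logit P(TRD) = logit(base_trd_rate) + log(OR_li) z_li
    + log(OR_ad) z_ad.  A zero base rate short-circuits to all-zero
    status.
    """
    if rng is None:
        rng = _streams(config.seed, "phenotypes")["phenotypes"]
    if not weights:
        raise ValueError("no weight tables supplied")
    z = {t: _true_scores(genotypes, weights[t], config) for t in config.traits}
    if config.base_trd_rate == 0:
        p = np.zeros(genotypes.n_subjects)
    else:
        eta = (
            np.log(config.base_trd_rate / (1 - config.base_trd_rate))
            + np.log(config.or_per_sd_lithium) * z.get("lithium", 0.0)
            + np.log(config.or_per_sd_antidep) * z.get("antidep", 0.0)
        )
        p = 1.0 / (1.0 + np.exp(-eta))
    trd = rng.random(genotypes.n_subjects) < p
    out = {"subject_id": genotypes.subjects}
    out.update({f"z_{t}": z[t] for t in config.traits})
    out["p_trd"] = p
    out["trd"] = trd.astype(int)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# treatment histories


def _adequate_chain(rng, start_lo, start_hi, end_limit, adequate_days, gap_days):
    """Dispense dates forming one adequate episode inside [start, end_limit)."""
    start = int(rng.integers(start_lo, max(start_lo + 1, start_hi)))
    dates = [start]
    step_hi = min(gap_days, 60)
    step_lo = min(21, step_hi)
    while dates[-1] - start < adequate_days:
        dates.append(dates[-1] + int(rng.integers(step_lo, step_hi + 1)))
    return [d for d in dates if d < end_limit] if dates[-1] >= end_limit else dates


def _inadequate_records(rng, lo, hi, gap_days, adequate_days):
    """1-2 episodes of one drug, none adequate: a broken chain.

    Two dispenses more than ``gap_days`` apart form two singleton
    episodes of duration 0 (< adequate_days whenever adequate_days > 0).
    """
    d0 = int(rng.integers(lo, hi))
    if rng.random() < 0.5:
        return [d0]
    return [d0, d0 + gap_days + int(rng.integers(10, 90))]


def simulate_treatment_history(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prescription and ECT tables realizing the latent TRD labels.

    TRD subjects receive a first ECT date and a pre-ECT antidepressant
    history drawn from ``trd_history_mix`` (none / inadequate-only /
    one adequate / two-plus adequate distinct N06A drugs); a
    ``lithium_user_fraction`` share of them also receives lithium
    (N05AN01) dispenses.  Non-TRD subjects get no ECT and, by default,
    at most two adequate antidepressants; a ``control_excess_fraction``
    share instead gets three (excluded under the narrow comparisons).
    Every non-TRD subject has at least one antidepressant record.
    """
    if rng is None:
        rng = _streams(config.seed, "treatment")["treatment"]
    ect_lo, ect_hi = config.first_ect_day_range
    gap, adq, end = config.gap_days, config.adequate_days, config.history_end_day
    mix = np.array(config.trd_history_mix)
    cum = np.cumsum(mix)

    rx_rows, ect_rows = [], []
    for sid, trd in zip(truth["subject_id"], truth["trd"]):
        if trd:
            ect_day = int(rng.integers(ect_lo, ect_hi + 1))
            ect_rows.append((sid, ect_day))
            n_extra_ect = int(rng.integers(0, 3))
            for _ in range(n_extra_ect):
                ect_rows.append((sid, ect_day + int(rng.integers(2, 60))))
            u = rng.random()
            drugs = list(rng.permutation(_ANTIDEPRESSANTS))
            if u < cum[0]:
                pass  # ECT with no prior antidepressant record
            elif u < cum[1]:
                for _ in range(int(rng.integers(1, 3))):
                    drug = drugs.pop()
                    for d in _inadequate_records(rng, 0, max(1, ect_day - 200), gap, adq):
                        if d < ect_day:
                            rx_rows.append((sid, drug, d))
            else:
                n_adq = 1 if u < cum[2] else int(rng.integers(2, 4))
                for _ in range(n_adq):
                    drug = drugs.pop()
                    hi_start = ect_day - adq - 80
                    for d in _adequate_chain(rng, 0, max(1, hi_start), ect_day, adq, gap):
                        rx_rows.append((sid, drug, d))
                if rng.random() < 0.4:  # plus an inadequate trial for texture
                    drug = drugs.pop()
                    for d in _inadequate_records(rng, 0, max(1, ect_day - 200), gap, adq):
                        if d < ect_day:
                            rx_rows.append((sid, drug, d))
            if rng.random() < config.lithium_user_fraction:
                day = int(rng.integers(0, end))
                for j in range(int(rng.integers(1, 4))):
                    rx_rows.append((sid, ATC_LITHIUM, day + j * 30))
        else:
            drugs = list(rng.permutation(_ANTIDEPRESSANTS))
            if rng.random() < config.control_excess_fraction:
                n_adq = 3
            else:
                n_adq = int(rng.integers(0, 3))
            for _ in range(n_adq):
                drug = drugs.pop()
                for d in _adequate_chain(rng, 0, end - adq - 80, end, adq, gap):
                    rx_rows.append((sid, drug, d))
            if n_adq == 0 or rng.random() < 0.3:
                drug = drugs.pop()
                for d in _inadequate_records(rng, 0, end - 200, gap, adq):
                    rx_rows.append((sid, drug, d))
    prescriptions = pd.DataFrame(
        rx_rows, columns=["subject_id", "atc_code", "dispense_date"]
    )
    ect = pd.DataFrame(ect_rows, columns=["subject_id", "date"])
    return prescriptions, ect


# ---------------------------------------------------------------------------
# whole-study orchestration


def simulate_subject_metadata(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Cohort labels, reported sex, and the X-heterozygosity summary.

    X-chromosome markers are not simulated; the per-subject rate of
    heterozygous X calls is emitted directly (males near zero, females
    near 0.30), with a ``sex_mismatch_rate`` share of reported sexes
    swapped to exercise the sex check.
    """
    n = config.n_subjects
    ids = [f"S{i:06d}" for i in range(n)]
    cohort = rng.choice(COHORTS, size=n, p=np.asarray(config.cohort_fractions))
    true_sex = rng.choice(["M", "F"], size=n)
    x_het = np.where(
        true_sex == "M",
        rng.uniform(0.0, 0.01, size=n),
        rng.uniform(0.25, 0.35, size=n),
    )
    reported = true_sex.copy()
    if config.sex_mismatch_rate > 0:
        swap = rng.random(n) < config.sex_mismatch_rate
        reported[swap] = np.where(reported[swap] == "M", "F", "M")
    return pd.DataFrame(
        {
            "subject_id": ids,
            "cohort": cohort,
            "reported_sex": reported,
            "x_het_rate": x_het,
        }
    )


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full study from one seed; bit-identical on rerun."""
    streams = _streams(
        config.seed, "genotypes", "phenotypes", "treatment", "subjects"
    )
    genotypes, weights = simulate_genotypes(config, streams["genotypes"])
    truth = simulate_phenotypes(genotypes, weights, config, streams["phenotypes"])
    prescriptions, ect = simulate_treatment_history(
        truth, config, streams["treatment"]
    )
    subjects = simulate_subject_metadata(config, streams["subjects"])
    study = SyntheticStudy(
        subjects=subjects,
        prescriptions=prescriptions,
        ect_events=ect,
        genotypes=genotypes,
        weights=weights,
        truth=truth,
        config=config,
    )
    study.validate()
    return study


def simulate_reference_panel(
    G: GenotypeMatrix,
    n_per_population: int = 200,
    freq_shift: float = 0.2,
    seed: int = 0,
    populations: tuple = ("EUR", "OTHER"),
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two-population reference panel on G's variants for ancestry QC.

    The first population is drawn at G's sample allele frequencies; the
    second at frequencies shifted by ``freq_shift`` (towards 0.5-away),
    a self-contained stand-in for a global reference projection.
    """
    rng = np.random.default_rng(seed)
    p = np.nan_to_num(G.allele_frequency(), nan=0.5)
    p = np.clip(p, 0.01, 0.99)
    shift = np.where(p < 0.5, freq_shift, -freq_shift)
    p2 = np.clip(p + shift, 0.01, 0.99)
    dos = np.vstack(
        [
            rng.binomial(2, p, size=(n_per_population, G.n_variants)),
            rng.binomial(2, p2, size=(n_per_population, G.n_variants)),
        ]
    ).astype(float)
    subjects = np.array(
        [f"REF{i:05d}" for i in range(2 * n_per_population)], dtype=object
    )
    labels = np.array(
        [populations[0]] * n_per_population + [populations[1]] * n_per_population,
        dtype=object,
    )
    return GenotypeMatrix(subjects, G.variants.copy(), dos), labels
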