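"""Genotype quality control and polygenic-score calculation.

The QC battery mirrors standard case-control GWAS practice: SNP screens
(call rate, invariance, Hardy-Weinberg exact test in cases and controls
separately, case-control call-rate difference, MAF), sample screens
(call rate, heterozygosity-based inbreeding coefficient F_HET, sex
check), relatedness pruning on the method-of-moments pi-hat, and
ancestry-outlier flagging by projection onto reference-panel principal
components.

Scoring consumes a table of per-variant effect-allele weights (assumed
already LD-rescaled, e.g. by SBayesR), applies the standard summary-
statistics filters (MAF, INFO, duplicates, strand ambiguity, MHC),
reconciles alleles against the target genotypes, and computes per-
subject weighted allele sums standardized within the scored sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    ``dosages`` is subjects x variants, float, values in {0, 1, 2, NaN},
    counting copies of ``a1``.  ``variants`` carries columns
    ``id, chrom, pos, a1, a2`` (1-based bp positions).
    """

    subjects: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing (NaN)")
        alleles = set(self.variants["a1"]) | set(self.variants["a2"])
        if not alleles <= {"A", "C", "G", "T"}:
            raise ValueError(f"non-ACGT alleles present: {sorted(alleles - set('ACGT'))}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.subjects,
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def take_subjects(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.subjects[idx], self.variants.copy(), self.dosages[idx, :]
        )

    def call_rate(self, axis: str = "sample") -> np.ndarray:
        called = ~np.isnan(self.dosages)
        return called.mean(axis=1 if axis == "sample" else 0)

    def allele_frequency(self) -> np.ndarray:
        """Frequency of a1 per variant over called genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class QcReport:
    """Per-filter removal counts plus the retained mask for one QC axis."""

    axis: str  # "snp" or "sample"
    n_input: int
    removed: dict = field(default_factory=dict)  # filter name -> count removed
    retained_mask: np.ndarray = None
    params: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def validate(self) -> None:
        if self.n_removed + self.n_retained != self.n_input:
            raise AssertionError("QcReport counts do not partition the input")

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": dict(self.removed),
            "params": {k: str(v) for k, v in self.params.items()},
        }

    def summary(self) -> str:
        lines = [f"{self.axis} QC: {self.n_input} in, {self.n_retained} retained"]
        lines += [f"  - {k}: removed {v}" for k, v in self.removed.items()]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton et al. 2005 style).

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts (same parity as the minor-allele count)
    whose conditional probability does not exceed the observed
    configuration's.  Monomorphic input returns p = 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # log P(het = h | n, n_minor) up to the common normalizing constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logsumexp(logp)
    obs = n_het
    logp_obs = logp[np.flatnonzero(hets == obs)[0]]
    keep = logp <= logp_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Exact HWE p per variant column; missing genotypes ignored."""
    m = dosages.shape[1]
    p = np.ones(m)
    for j in range(m):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        p[j] = hwe_exact_test(n2, n1, n0)
    return p


# ---------------------------------------------------------------------------
# SNP QC


@dataclass(frozen=True)
class SnpQcThresholds:
    coarse_call_rate: float = 0.95
    call_rate: float = 0.98
    hwe_p: float = 1e-6
    case_control_call_rate_diff: float = 0.01
    maf: float = 0.01


def snp_qc(
    G: GenotypeMatrix,
    case_status: np.ndarray,
    thresholds: SnpQcThresholds = SnpQcThresholds(),
) -> QcReport:
    """Sequential per-SNP screens; each filter counts only new removals.

    Order: coarse call-rate pass (default < 0.95), strict call rate
    (< 0.98), invariant sites, HWE exact p < 1e-6 in controls or in
    cases, case-control call-rate difference > 0.01, MAF < 0.01.
    """
    status = np.asarray(case_status)
    if status.shape[0] != G.n_subjects:
        raise ValueError("case_status must align with G.subjects")
    t = thresholds
    called = ~np.isnan(G.dosages)
    call_rate = called.mean(axis=0)
    keep = np.ones(G.n_variants, dtype=bool)
    removed: dict[str, int] = {}

    def apply(name: str, fail: np.ndarray):
        new = keep & fail
        removed[name] = int(new.sum())
        keep[new] = False

    apply("call_rate_coarse", call_rate < t.coarse_call_rate)
    apply("call_rate", call_rate < t.call_rate)

    freq = G.allele_frequency()
    apply("invariant", np.isin(freq, (0.0, 1.0)) | np.isnan(freq))

    cases, controls = status == 1, status == 0
    hwe_fail = np.zeros(G.n_variants, dtype=bool)
    for grp in (controls, cases):
        if grp.sum() > 0:
            idx = np.flatnonzero(keep)
            pvals = _hwe_pvalues(G.dosages[np.ix_(grp, idx)])
            fail = np.zeros(G.n_variants, dtype=bool)
            fail[idx] = pvals < t.hwe_p
            hwe_fail |= fail
    apply("hwe", hwe_fail)

    if cases.sum() > 0 and controls.sum() > 0:
        cr_diff = np.abs(
            called[cases].mean(axis=0) - called[controls].mean(axis=0)
        )
        apply("case_control_call_rate_diff", cr_diff > t.case_control_call_rate_diff)
    else:
        removed["case_control_call_rate_diff"] = 0

    maf = np.minimum(freq, 1 - freq)
    apply("maf", maf < t.maf)

    report = QcReport(
        axis="snp",
        n_input=G.n_variants,
        removed=removed,
        retained_mask=keep,
        params=dict(t.__dict__),
    )
    report.validate()
    if report.n_retained == 0:
        raise ValueError("SNP QC removed every variant")
    return report


# ---------------------------------------------------------------------------
# sample QC


@dataclass(frozen=True)
class SampleQcThresholds:
    call_rate: float = 0.98
    fhet: float = 0.20
    #: inferred male if X heterozygosity below this
    male_max_x_het: float = 0.02
    #: inferred female if X heterozygosity above this
    female_min_x_het: float = 0.20


def inbreeding_coefficient(G: GenotypeMatrix) -> np.ndarray:
    """Per-sample F = 1 - observed/expected heterozygosity.

    Expected heterozygosity sums 2p(1-p) over the sample's called
    variants, with p the pooled allele frequency.
    """
    freq = G.allele_frequency()
    het_exp_per_snp = 2.0 * freq * (1.0 - freq)
    called = ~np.isnan(G.dosages)
    obs_het = ((G.dosages == 1) & called).sum(axis=1)
    exp_het = called @ np.nan_to_num(het_exp_per_snp)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - obs_het / exp_het
    return np.where(exp_het > 0, f, 0.0)


def infer_sex(x_het_rate: np.ndarray, thresholds: SampleQcThresholds) -> np.ndarray:
    """'M' / 'F' / 'ambiguous' from the X-marker heterozygosity rate."""
    x = np.asarray(x_het_rate, dtype=float)
    out = np.full(x.shape, "ambiguous", dtype=object)
    out[x < thresholds.male_max_x_het] = "M"
    out[x > thresholds.female_min_x_het] = "F"
    return out


def sample_qc(
    G: GenotypeMatrix,
    reported_sex: np.ndarray,
    x_het_rate: np.ndarray,
    thresholds: SampleQcThresholds = SampleQcThresholds(),
) -> QcReport:
    """Per-sample screens: call rate, |F_HET| > 0.20, sex mismatch.

    Sex is inferred from the X heterozygosity rate; ambiguous rates are
    never treated as a mismatch.
    """
    sex = np.asarray(reported_sex, dtype=object)
    if sex.shape[0] != G.n_subjects or np.asarray(x_het_rate).shape[0] != G.n_subjects:
        raise ValueError("sample metadata must align with G.subjects")
    t = thresholds
    keep = np.ones(G.n_subjects, dtype=bool)
    removed: dict[str, int] = {}

    def apply(name, fail):
        new = keep & fail
        removed[name] = int(new.sum())
        keep[new] = False

    apply("call_rate", G.call_rate("sample") < t.call_rate)
    apply("fhet", np.abs(inbreeding_coefficient(G)) > t.fhet)
    inferred = infer_sex(x_het_rate, t)
    mismatch = (inferred != "ambiguous") & (inferred != sex)
    apply("sex_mismatch", mismatch)

    report = QcReport(
        axis="sample",
        n_input=G.n_subjects,
        removed=removed,
        retained_mask=keep,
        params=t.__dict__,
    )
    report.validate()
    if report.n_retained == 0:
        raise ValueError("sample QC removed every subject")
    return report


# ---------------------------------------------------------------------------
# relatedness


def pihat_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise pi-hat (proportion of genome shared IBD), method of moments.

    Counts identity-by-state (IBS) 0/1/2 sharing per pair over jointly
    called variants and solves the moment equations using the expected
    IBS profile per IBD state at the sample allele frequencies
    (Purcell et al. 2007, without small-sample bias corrections):
    pi-hat = P(IBD=2) + P(IBD=1)/2.  Expected-count sums over variants
    are scaled by each pair's jointly-called fraction, an approximation
    that is exact under variant-independent missingness.
    """
    X = G.dosages
    n, m = X.shape
    valid = (~np.isnan(X)).astype(np.float32)
    A0 = ((X == 0).astype(np.float32))
    A1 = ((X == 1).astype(np.float32))
    A2 = ((X == 2).astype(np.float32))
    ibs0 = A0 @ A2.T + A2 @ A0.T
    ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    n_valid = valid @ valid.T
    ibs1 = n_valid - ibs0 - ibs2

    p = G.allele_frequency()
    p = p[~np.isnan(p)]
    q = 1.0 - p
    # expected per-variant IBS probabilities conditional on the IBD state
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    with np.errstate(divide="ignore", invalid="ignore"):
        scale = n_valid / m  # pair-specific completeness
        p_ibd0 = ibs0 / (e0_ibd0 * scale)
        p_ibd1 = (ibs1 - p_ibd0 * e1_ibd0 * scale) / (e1_ibd1 * scale)
        p_ibd2 = (ibs2 - p_ibd0 * (n_valid - (e0_ibd0 + e1_ibd0) * scale)
                  - p_ibd1 * e2_ibd1 * scale) / n_valid
    p_ibd0 = np.clip(np.nan_to_num(p_ibd0), 0.0, 1.0)
    p_ibd1 = np.clip(np.nan_to_num(p_ibd1), 0.0, 1.0)
    p_ibd2 = np.clip(np.nan_to_num(p_ibd2), 0.0, 1.0)
    pihat = p_ibd2 + 0.5 * p_ibd1
    np.fill_diagonal(pihat, 1.0)
    return np.clip(pihat, 0.0, 1.0)


def relatedness_prune(
    G: GenotypeMatrix, pihat_threshold: float = 0.2
) -> QcReport:
    """Remove one member of each pair with pi-hat above the threshold.

    The member with the lower genotype call rate is dropped; ties keep
    the earlier subject in input order.
    """
    if G.n_subjects < 2:
        raise ValueError("relatedness pruning requires >= 2 samples")
    pihat = pihat_matrix(G)
    call = G.call_rate("sample")
    keep = np.ones(G.n_subjects, dtype=bool)
    ii, jj = np.nonzero(np.triu(pihat > pihat_threshold, k=1))
    for i, j in zip(ii, jj):
        if keep[i] and keep[j]:
            drop = i if call[i] < call[j] else j  # tie keeps input order (drops j)
            keep[drop] = False
    report = QcReport(
        axis="sample",
        n_input=G.n_subjects,
        removed={"relatedness": int((~keep).sum())},
        retained_mask=keep,
        params={"pihat_threshold": pihat_threshold},
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# ancestry outliers


def ancestry_outliers(
    G: GenotypeMatrix,
    reference: GenotypeMatrix,
    reference_populations: np.ndarray,
    target_population: str = "EUR",
    sd_threshold: float = 6.0,
    min_shared_snps: int = 100,
) -> QcReport:
    """Flag samples far from the reference target population in PC space.

    The top two principal components are computed on the reference
    panel (variants standardized by reference allele frequencies);
    study samples are projected through the reference SNP loadings, and
    a sample is flagged when PC1 or PC2 lies more than ``sd_threshold``
    target-population standard deviations from the target-population
    mean.
    """
    pops = np.asarray(reference_populations, dtype=object)
    if pops.shape[0] != reference.n_subjects:
        raise ValueError("population labels must align with reference subjects")
    shared = pd.Index(reference.variants["id"]).intersection(G.variants["id"])
    if len(shared) < min_shared_snps:
        raise ValueError(
            f"only {len(shared)} SNPs shared with the reference (need {min_shared_snps})"
        )
    ref_idx = pd.Index(reference.variants["id"]).get_indexer(shared)
    g_idx = pd.Index(G.variants["id"]).get_indexer(shared)

    R = reference.dosages[:, ref_idx]
    p = np.nanmean(R, axis=0) / 2.0
    informative = (p > 0) & (p < 1)
    if informative.sum() < 2:
        raise ValueError("fewer than 2 informative dimensions in the reference")
    R = R[:, informative]
    p = p[informative]
    sd = np.sqrt(2 * p * (1 - p))

    def standardize(X):
        Z = (X - 2 * p) / sd
        return np.nan_to_num(Z, nan=0.0)

    Zr = standardize(R)
    # SVD of the reference; loadings project any sample into the same space
    _, _, vt = np.linalg.svd(Zr, full_matrices=False)
    loadings = vt[:2].T  # snps x 2
    # deterministic sign convention
    for k in range(2):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
    ref_scores = Zr @ loadings
    tgt = pops == target_population
    if tgt.sum() < 2:
        raise ValueError(f"reference target population {target_population!r} too small")
    mu = ref_scores[tgt].mean(axis=0)
    sigma = ref_scores[tgt].std(axis=0, ddof=1)

    study_scores = standardize(G.dosages[:, g_idx][:, informative]) @ loadings
    with np.errstate(invalid="ignore"):
        dist = np.abs(study_scores - mu) / sigma
    flagged = (dist > sd_threshold).any(axis=1)
    report = QcReport(
        axis="sample",
        n_input=G.n_subjects,
        removed={"ancestry_outlier": int(flagged.sum())},
        retained_mask=~flagged,
        params={"sd_threshold": sd_threshold, "target_population": target_population},
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# weight-table filtering and scoring

WEIGHT_COLUMNS = [
    "id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "weight",
    "info",
]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
MHC_REGION = (6, 28_000_000, 34_000_000)  # GRCh37, inclusive


def filter_weights(
    weights: pd.DataFrame,
    G: GenotypeMatrix,
    maf_min: float = 0.1,
    info_min: float = 0.9,
    mhc_region: tuple = MHC_REGION,
    snp_whitelist=None,
) -> tuple[pd.DataFrame, dict]:
    """Score-SNP filters, then intersection with the target genotypes.

    Removes, in order: summary-statistics MAF < ``maf_min`` (effect-
    allele frequency outside [maf_min, 1 - maf_min]); INFO <
    ``info_min``; duplicated ids (all copies); strand-ambiguous A/T
    and C/G pairs; MHC-region SNPs (chr6:28-34 Mb, inclusive, GRCh37);
    optionally SNPs outside an id whitelist (the HapMap3-intersection
    hook).  The survivors are matched to ``G`` by id; when the effect
    allele equals the target's second allele the variant is marked
    ``flip`` (scored on 2 - dosage); irreconcilable allele pairs are
    dropped.

    Returns the filtered table (with a ``flip`` column) and a dict of
    per-filter removal counts.
    """
    if len(weights) == 0:
        raise ValueError("empty weight table")
    w = weights.copy()
    missing = [c for c in WEIGHT_COLUMNS if c not in w.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    counts: dict[str, int] = {}

    def drop(name, mask):
        counts[name] = int(mask.sum())
        return w.loc[~mask]

    w = drop("maf", (w["eaf"] < maf_min) | (w["eaf"] > 1 - maf_min))
    w = drop("info", w["info"] < info_min)
    w = drop("duplicate_id", w["id"].duplicated(keep=False))
    pairs = list(zip(w["effect_allele"], w["other_allele"]))
    w = drop(
        "strand_ambiguous",
        pd.Series([p in _AMBIGUOUS_PAIRS for p in pairs], index=w.index),
    )
    chrom, lo, hi = mhc_region
    w = drop(
        "mhc",
        (pd.to_numeric(w["chrom"]) == chrom) & (w["pos"] >= lo) & (w["pos"] <= hi),
    )
    if snp_whitelist is not None:
        w = drop("whitelist", ~w["id"].isin(set(snp_whitelist)))

    gvar = G.variants.set_index("id")
    present = w["id"].isin(gvar.index)
    counts["absent_from_target"] = int((~present).sum())
    w = w.loc[present].copy()
    a1 = gvar.loc[w["id"], "a1"].to_numpy()
    a2 = gvar.loc[w["id"], "a2"].to_numpy()
    ea = w["effect_allele"].to_numpy()
    oa = w["other_allele"].to_numpy()
    same = (ea == a1) & (oa == a2)
    flip = (ea == a2) & (oa == a1)
    counts["allele_mismatch"] = int((~(same | flip)).sum())
    w = w.loc[same | flip].copy()
    w["flip"] = flip[same | flip]
    if len(w) == 0:
        raise ValueError("no scorable SNPs remain after filtering/intersection")
    return w.reset_index(drop=True), counts


def score(
    G: GenotypeMatrix,
    weights: pd.DataFrame,
    trait: str = "score",
    missing_policy: str = "impute_freq",
) -> pd.DataFrame:
    """Weighted allele-count score per subject, standardized in-sample.

    raw_i = sum_j w_j * d_ij with d_ij the effect-allele dosage
    (2 - dosage for flipped variants).  Missing dosages are imputed to
    2 x effect-allele frequency (``impute_freq``, the convention of
    standard scoring tools on imputed data) or omitted with the total
    rescaled to the full SNP count (``omit_rescale``).  The z column is
    (raw - mean) / SD over the scored sample; zero variance raises.
    """
    if missing_policy not in ("impute_freq", "omit_rescale"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if "flip" not in weights.columns:
        raise ValueError("weights must come from filter_weights (no 'flip' column)")
    gidx = pd.Index(G.variants["id"]).get_indexer(weights["id"])
    if (gidx < 0).any():
        raise ValueError("weights reference SNPs absent from the genotype matrix")
    D = G.dosages[:, gidx]
    flip = weights["flip"].to_numpy()
    eff = np.where(flip, 2.0 - D, D)
    wvec = weights["weight"].to_numpy(dtype=float)
    eaf = weights["eaf"].to_numpy(dtype=float)
    missing = np.isnan(eff)
    if missing_policy == "impute_freq":
        eff = np.where(missing, 2.0 * eaf, eff)
        raw = eff @ wvec
    else:
        n_used = (~missing).sum(axis=1)
        if (n_used == 0).any():
            bad = G.subjects[n_used == 0][:3]
            raise ValueError(f"no usable SNPs for subjects {list(bad)} under omit policy")
        raw = np.where(missing, 0.0, eff) @ wvec * (len(wvec) / n_used)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("score has zero variance; standardization undefined")
    z = (raw - raw.mean()) / sd
    return pd.DataFrame(
        {"subject_id": G.subjects, "trait": trait, "raw": raw, "z": z}
    )
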