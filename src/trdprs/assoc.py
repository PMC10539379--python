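"""Case-control association battery for standardized polygenic scores.

The primary battery compares TRD cases with non-TRD controls under
three phenotype definitions and two treatment-response scores (lithium
response, antidepressant response): a Welch t-test on the mean score
difference, logistic regression of status on the score adjusting for
the first four principal components (reported as the odds ratio per SD
of score), Nagelkerke pseudo-R2 with a liability-scale conversion at a
population TRD proportion K = 0.10, a Cochran-Armitage trend test over
score quartiles, and Benjamini-Hochberg FDR over the six primary tests.
Sensitivity variants add psychiatric-disorder scores (MDD, bipolar) as
covariates and re-run the models with lithium-using cases excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

DEFAULT_POPULATION_K = 0.10


class SeparationError(ValueError):
    """Raised when the logistic MLE does not exist (perfect separation)."""


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# mean difference


@dataclass(frozen=True)
class MeanDifferenceResult:
    estimate: float  # mean(cases) - mean(controls)
    t: float
    p: float
    ci_low: float
    ci_high: float
    df: float
    n_cases: int
    n_controls: int


def mean_difference_test(
    scores_cases, scores_controls, kind: str = "welch"
) -> MeanDifferenceResult:
    """Two-sided t-test of the case-control mean score difference.

    ``kind`` selects Welch (unequal variances, default) or Student
    (pooled variance).  The 95% CI uses the same degrees of freedom as
    the test.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups; t-test undefined")
    equal_var = {"welch": False, "student": True}[kind]
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    est = x.mean() - y.mean()
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    if equal_var:
        df = len(x) + len(y) - 2
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    else:
        se = np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    tcrit = stats.t.ppf(0.975, df)
    return MeanDifferenceResult(
        estimate=float(est),
        t=float(t),
        p=float(p),
        ci_low=float(est - tcrit * se),
        ci_high=float(est + tcrit * se),
        df=float(df),
        n_cases=len(x),
        n_controls=len(y),
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticResult:
    odds_ratio: float  # per SD of the (standardized) score
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    loglik_full: float
    loglik_base: float  # covariates-only model (intercept if none)
    n: int
    n_cases: int

    @property
    def nagelkerke_r2(self) -> float:
        return nagelkerke_r2(self.loglik_full, self.loglik_base, self.n)


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        cols, bad = [], []
        for c in X.columns:
            cand = X[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(cand) == len(cols) + 1:
                cols.append(c)
            else:
                bad.append(c)
        raise CollinearityError(f"design matrix rank deficient; collinear columns: {bad}")


def _detect_separation(status: np.ndarray, score: np.ndarray) -> str:
    s1, s0 = score[status == 1], score[status == 0]
    if len(s1) and len(s0):
        if s1.min() > s0.max():
            return "score separates cases above controls"
        if s1.max() < s0.min():
            return "score separates cases below controls"
    return "perfect separation in the design"


def fit_logistic(
    status,
    score,
    covariates: pd.DataFrame | None = None,
    ci_method: str = "wald",
) -> LogisticResult:
    """Logistic regression of case status on a standardized score.

    Returns the odds ratio per SD of score with a two-sided Wald test;
    ``ci_method='profile'`` replaces the Wald interval with the
    profile-likelihood one.  The baseline (covariates-only) model is
    fitted alongside so Nagelkerke R2 can be formed by likelihood
    comparison.  Newton-Raphson is iterated to gradient norm < 1e-8.
    """
    y = np.asarray(status, dtype=float)
    z = np.asarray(score, dtype=float)
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("status must be binary with both classes present")
    X = pd.DataFrame({"const": np.ones_like(z), "score": z})
    if covariates is not None and covariates.shape[1] > 0:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    _check_design(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(method="newton", disp=0, tol=1e-8, maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as err:
        raise SeparationError(_detect_separation(y, z)) from err
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError(_detect_separation(y, z))
    Xb = X.drop(columns="score")
    base = sm.Logit(y, Xb).fit(method="newton", disp=0, tol=1e-8, maxiter=100)
    beta = float(fit.params["score"])
    se = float(fit.bse["score"])
    if ci_method == "wald":
        lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    elif ci_method == "profile":
        lo, hi = _profile_ci(y, X, fit)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    wald_z = beta / se
    return LogisticResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p=float(2 * stats.norm.sf(abs(wald_z))),
        beta=beta,
        se=se,
        loglik_full=float(fit.llf),
        loglik_base=float(base.llf),
        n=len(y),
        n_cases=int(y.sum()),
    )


def _profile_ci(y, X, fit, level: float = 0.95):
    """Profile-likelihood CI for the score coefficient via root finding."""
    from scipy.optimize import brentq

    crit = stats.chi2.ppf(level, df=1) / 2.0
    beta_hat, se = float(fit.params["score"]), float(fit.bse["score"])
    Xo = X.drop(columns="score")
    z = X["score"].to_numpy()

    def deficit(b):
        constrained = sm.Logit(y, Xo, offset=b * z).fit(
            method="newton", disp=0, tol=1e-8, maxiter=100
        )
        return (fit.llf - constrained.llf) - crit

    lo = brentq(deficit, beta_hat - 10 * se, beta_hat)
    hi = brentq(deficit, beta_hat, beta_hat + 10 * se)
    return lo, hi


# ---------------------------------------------------------------------------
# variance explained


def nagelkerke_r2(loglik_full: float, loglik_base: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from full vs baseline log-likelihoods.

    Cox-Snell R2 = 1 - exp(2(llbase - llfull)/n), rescaled by its
    attainable maximum 1 - exp(2 llbase / n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_full < loglik_base - 1e-9:
        raise ValueError("full-model log-likelihood below baseline")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_base - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_base / n)
    if max_cs <= 0:
        return 0.0
    return float(cox_snell / max_cs)


def liability_r2(
    r2_observed: float, K: float = DEFAULT_POPULATION_K, P: float | None = None
) -> float:
    """Observed-scale R2 transformed to the liability scale.

    Threshold-model conversion (Lee et al. 2012 style):
    R2_liab = R2_obs * [K(1-K)]^2 / (z^2 * P(1-P)), with K the
    population case proportion (default 0.10: the assumed share of MDD
    cases meeting the stringent TRD definition), P the sample case
    proportion (defaults to K), and z the standard-normal density at
    the liability threshold Phi^-1(1-K).
    """
    if not (0 < K < 1):
        raise ValueError("K must lie in (0, 1)")
    P = K if P is None else P
    if not (0 < P < 1):
        raise ValueError("P must lie in (0, 1)")
    if not (0 <= r2_observed <= 1):
        raise ValueError("r2_observed must lie in [0, 1]")
    thresh = stats.norm.isf(K)
    z = stats.norm.pdf(thresh)
    return float(r2_observed * (K * (1 - K)) ** 2 / (z**2 * P * (1 - P)))


# ---------------------------------------------------------------------------
# quartile trend


@dataclass(frozen=True)
class QuartileTrendResult:
    case_proportion: tuple  # Q1..Q4
    n_per_quartile: tuple
    statistic: float  # Cochran-Armitage chi-squared (1 df)
    p: float


def assign_quartiles(scores: np.ndarray) -> np.ndarray:
    """Quartile index 1-4 from pooled-sample boundaries; ties go low."""
    scores = np.asarray(scores, dtype=float)
    bounds = np.quantile(scores, [0.25, 0.5, 0.75])
    return np.searchsorted(bounds, scores, side="left") + 1


def quartile_trend(scores, status) -> QuartileTrendResult:
    """Cochran-Armitage test for trend in case proportion over quartiles.

    Subjects are binned into score quartiles (boundaries from the
    pooled sample, boundary ties assigned to the lower quartile) and
    the one-degree-of-freedom trend statistic is computed with equally
    spaced scores 1-4.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=float)
    if len(scores) < 8:
        raise ValueError("need n >= 8 for a quartile trend test")
    q = assign_quartiles(scores)
    n_k = np.array([(q == k).sum() for k in (1, 2, 3, 4)])
    if (n_k == 0).any():
        raise ValueError(f"empty quartile (counts {n_k.tolist()}); trend undefined")
    r_k = np.array([y[q == k].sum() for k in (1, 2, 3, 4)])
    return _cochran_armitage(r_k, n_k)


def _cochran_armitage(cases: np.ndarray, totals: np.ndarray) -> QuartileTrendResult:
    s = np.arange(1, len(totals) + 1, dtype=float)
    N, R = totals.sum(), cases.sum()
    pbar = R / N
    T = float(np.sum(s * (cases - totals * pbar)))
    var = pbar * (1 - pbar) * (np.sum(totals * s**2) - np.sum(totals * s) ** 2 / N)
    if var <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = T**2 / var
        p = float(stats.chi2.sf(stat, df=1))
    return QuartileTrendResult(
        case_proportion=tuple((cases / totals).tolist()),
        n_per_quartile=tuple(int(n) for n in totals),
        statistic=float(stat),
        p=p,
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d collection")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the battery

PRIMARY_TRAITS = ("lithium", "antidep")
SENSITIVITY_COVARIATE_SETS = {
    "base": (),
    "mdd_adj": ("mdd",),
    "bip_adj": ("bip",),
    "bip_mdd_adj": ("mdd", "bip"),
}


def run_battery(
    datasets: dict[str, pd.DataFrame],
    traits=PRIMARY_TRAITS,
    pc_columns=("PC1", "PC2", "PC3", "PC4"),
    covariate_sets: dict[str, tuple] | None = None,
    lithium_sensitivity: bool = True,
    population_K: float = DEFAULT_POPULATION_K,
) -> pd.DataFrame:
    """Run the full association battery over the phenotype definitions.

    ``datasets`` maps definition label -> per-subject frame with a
    binary ``status`` column, one ``score_<trait>`` column per trait
    (standardized), optional PC columns, and optionally
    ``lithium_user`` (needed for the lithium-exclusion sensitivity
    run).  For every definition x trait the primary analysis (PCs-only
    covariates) computes the Welch mean difference and the per-SD
    logistic OR with Nagelkerke and liability R2; BH-FDR is then
    applied separately to the six primary t-test p-values and the six
    primary regression p-values.  Sensitivity rows rerun the
    regressions with added disorder-score covariates and, when
    requested, with lithium-using cases removed.

    Returns a tidy frame, one row per test.
    """
    if covariate_sets is None:
        covariate_sets = {
            k: v
            for k, v in SENSITIVITY_COVARIATE_SETS.items()
            if k == "base"
            or all(
                f"score_{t}" in df.columns
                for t in v
                for df in datasets.values()
            )
        }
    rows = []
    for definition, df in datasets.items():
        if df["status"].isna().any():
            raise ValueError(f"missing status values under {definition!r}")
        pcs = [c for c in pc_columns if c in df.columns]
        variants = [(cs, False) for cs in covariate_sets]
        if lithium_sensitivity and "lithium_user" in df.columns:
            variants.append(("base", True))
        for trait in traits:
            col = f"score_{trait}"
            if df[col].isna().any():
                raise ValueError(f"missing {col} values under {definition!r}")
            for covset, drop_li in variants:
                sub = df
                if drop_li:
                    sub = df.loc[~((df["status"] == 1) & df["lithium_user"])]
                cov_cols = list(pcs) + [
                    f"score_{t}" for t in covariate_sets[covset]
                ]
                try:
                    cases = sub.loc[sub["status"] == 1, col].to_numpy()
                    controls = sub.loc[sub["status"] == 0, col].to_numpy()
                    md = mean_difference_test(cases, controls)
                    lr = fit_logistic(
                        sub["status"].to_numpy(),
                        sub[col].to_numpy(),
                        covariates=sub[cov_cols] if cov_cols else None,
                    )
                except (ValueError, KeyError) as err:
                    raise type(err)(
                        f"[{definition}/{trait}/{covset}"
                        f"{'/lithium_excluded' if drop_li else ''}] {err}"
                    ) from err
                r2_obs = lr.nagelkerke_r2
                rows.append(
                    {
                        "definition": definition,
                        "trait": trait,
                        "covariate_set": covset,
                        "lithium_excluded": drop_li,
                        "n_cases": lr.n_cases,
                        "n_controls": lr.n - lr.n_cases,
                        "mean_difference": md.estimate,
                        "mean_diff_ci_low": md.ci_low,
                        "mean_diff_ci_high": md.ci_high,
                        "p_ttest": md.p,
                        "odds_ratio": lr.odds_ratio,
                        "or_ci_low": lr.ci_low,
                        "or_ci_high": lr.ci_high,
                        "p_logistic": lr.p,
                        "r2_nagelkerke": r2_obs,
                        "r2_liability": liability_r2(
                            r2_obs, K=population_K, P=lr.n_cases / lr.n
                        ),
                    }
                )
    out = pd.DataFrame(rows)
    primary = (out["covariate_set"] == "base") & (~out["lithium_excluded"])
    n_primary = int(primary.sum())
    if n_primary != len(datasets) * len(traits):
        raise AssertionError("primary battery rows miscounted")
    out["p_ttest_fdr"] = np.nan
    out["p_logistic_fdr"] = np.nan
    out.loc[primary, "p_ttest_fdr"] = bh_fdr(out.loc[primary, "p_ttest"])
    out.loc[primary, "p_logistic_fdr"] = bh_fdr(out.loc[primary, "p_logistic"])
    return out
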