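"""Replicate simulations for parameter recovery and error calibration.

These drive the design-scale checks: simulating case-control samples at
the published group sizes under a known per-SD odds ratio or mean score
shift, refitting with the package's own estimators, and summarizing the
replicate distribution of estimates.  They are what the acceptance
script runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .assoc import fit_logistic, mean_difference_test, run_battery


@dataclass(frozen=True)
class RecoverySummary:
    estimates: np.ndarray
    rejections: np.ndarray  # p < alpha per replicate
    alpha: float

    @property
    def mean_estimate(self) -> float:
        return float(self.estimates.mean())

    @property
    def rejection_rate(self) -> float:
        return float(self.rejections.mean())


def simulate_case_control_status(
    or_per_sd: float,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One replicate: standardized score -> logistic status.

    Scores are N(0, 1) for ``n_cases + n_controls`` subjects; status is
    Bernoulli with logit p = logit(case fraction) + log(OR) * z, so the
    expected case count matches the design's.
    """
    n = n_cases + n_controls
    z = rng.standard_normal(n)
    eta = logit(n_cases / n) + np.log(or_per_sd) * z
    y = (rng.random(n) < expit(eta)).astype(float)
    return y, z


def or_recovery(
    or_per_sd: float,
    n_cases: int = 1487,
    n_controls: int = 1483,
    n_replicates: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> RecoverySummary:
    """Per-SD OR estimates over seeded logistic-regression replicates."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    est = np.empty(n_replicates)
    rej = np.empty(n_replicates, dtype=bool)
    for r in range(n_replicates):
        y, z = simulate_case_control_status(or_per_sd, n_cases, n_controls, rng)
        fit = fit_logistic(y, z)
        est[r] = fit.odds_ratio
        rej[r] = fit.p < alpha
    return RecoverySummary(estimates=est, rejections=rej, alpha=alpha)


def mean_difference_recovery(
    shift: float,
    n_cases: int = 1487,
    n_controls: int = 1483,
    n_replicates: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> RecoverySummary:
    """Welch mean-difference estimates with cases N(shift, 1) vs N(0, 1)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    est = np.empty(n_replicates)
    rej = np.empty(n_replicates, dtype=bool)
    for r in range(n_replicates):
        cases = rng.standard_normal(n_cases) + shift
        controls = rng.standard_normal(n_controls)
        res = mean_difference_test(cases, controls)
        est[r] = res.estimate
        rej[r] = res.p < alpha
    return RecoverySummary(estimates=est, rejections=rej, alpha=alpha)


def null_battery_rejection_rates(
    n_replicates: int = 2000,
    n_cases: int = 300,
    n_controls: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the battery under the global null.

    Each replicate builds three independent null comparisons (scores
    independent of status for both traits), runs the battery, and
    counts per-test rejections of the unadjusted t-test and regression
    p-values at ``alpha``.  Returns the pooled rejection rates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n = n_cases + n_controls
    status = np.r_[np.ones(n_cases), np.zeros(n_controls)]
    t_rej = lr_rej = t_tot = lr_tot = 0
    for _ in range(n_replicates):
        datasets = {
            d: pd.DataFrame(
                {
                    "status": status,
                    "score_lithium": rng.standard_normal(n),
                    "score_antidep": rng.standard_normal(n),
                }
            )
            for d in ("broad", "narrow_1", "narrow_2")
        }
        res = run_battery(datasets, lithium_sensitivity=False)
        primary = res[res["covariate_set"] == "base"]
        t_rej += int((primary["p_ttest"] < alpha).sum())
        lr_rej += int((primary["p_logistic"] < alpha).sum())
        t_tot += len(primary)
        lr_tot += len(primary)
    return {
        "ttest_rejection_rate": t_rej / t_tot,
        "logistic_rejection_rate": lr_rej / lr_tot,
        "n_tests": t_tot,
        "alpha": alpha,
    }
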