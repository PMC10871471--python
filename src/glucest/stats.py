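"""Cohort statistics: rank-sum group comparisons, age regressions and
volume-contrast correlations.

The two-sample comparison is the Wilcoxon rank-sum (Mann-Whitney) test.  Its
p-value policy mirrors the defaults of the R ``wilcox.test`` implementation
the study's statistics were produced with: an exact two-sided p by complete
enumeration of the rank-sum null distribution whenever both samples have
fewer than 50 observations and the pooled data carry no ties, and otherwise
a normal approximation with tie correction and continuity correction.  No
multiple-testing correction is applied; p-values are reported per region.

Regressions are ordinary least squares with the two-sided slope p-value from
the t statistic on n - 2 degrees of freedom; R^2 = 1 - SSE/SST, which for a
single predictor equals the squared Pearson correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import CORTICAL_REGIONS, REGIONS

__all__ = [
    "TestResult",
    "RegressionResult",
    "ResultsBundle",
    "rank_sum_null_pmf",
    "exact_two_sided_p_distribution",
    "wilcoxon_rank_sum",
    "linreg_age",
    "volume_contrast_correlation",
    "build_results_table",
    "GROUPS",
]

logger = logging.getLogger(__name__)

GROUPS: tuple[str, str] = ("non-smoker", "smoker")

#: Regions entering the per-group age regressions (tissue aggregates plus the
#: seven cortical regions; the whole-brain aggregate is reported in the group
#: comparison table only).
REGRESSION_REGIONS: tuple[str, ...] = ("GM", "WM") + CORTICAL_REGIONS


@dataclass
class TestResult:
    """Two-sample rank-sum comparison for one region."""

    statistic: float  # rank sum W of the first sample
    p_value: float
    method: str
    region: str | None = None
    group_means: tuple[float, float] | None = None
    group_sds: tuple[float, float] | None = None
    n: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class RegressionResult:
    """Single-predictor OLS fit."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    region: str | None = None
    group: str | None = None
    predictor: str = "age"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


@dataclass
class ResultsBundle:
    """Cohort-level outputs: group-comparison table, age regressions and
    volume correlations, plus the per-subject cohort table they derive from."""

    comparison: pd.DataFrame
    regressions: pd.DataFrame
    volume_correlations: pd.DataFrame
    cohort: pd.DataFrame


@lru_cache(maxsize=64)
def rank_sum_null_pmf(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the rank sum W of a size-``n`` sample drawn
    without ties against a size-``m`` sample.

    Returns ``(w_values, probabilities)`` with W ranging over
    ``[n(n+1)/2, n(n+1)/2 + n*m]``.  Computed by dynamic programming over the
    pooled ranks (counts of size-``n`` subsets of ``{1..n+m}`` by sum).
    """
    if n < 1 or m < 1:
        raise ValueError("both sample sizes must be >= 1")
    total = n + m
    w_max = sum(range(total - n + 1, total + 1))
    counts = np.zeros((n + 1, w_max + 1))
    counts[0, 0] = 1.0
    for rank in range(1, total + 1):
        for k in range(min(rank, n), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank or None]
    w_min = n * (n + 1) // 2
    pmf = counts[n, w_min : w_min + n * m + 1]
    return np.arange(w_min, w_min + n * m + 1), pmf / pmf.sum()


@lru_cache(maxsize=64)
def exact_two_sided_p_distribution(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the exact two-sided rank-sum p-value itself.

    Returns the sorted distinct p-value atoms and their null probabilities.
    Useful for calibration checks: the exact doubled two-sided p-value is
    discrete and conservative, so its null law — not the uniform — is the
    correct reference distribution at small sample sizes.
    """
    w, pmf = rank_sum_null_pmf(n, m)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    p_two = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    atoms, inverse = np.unique(p_two, return_inverse=True)
    probs = np.bincount(inverse, weights=pmf, minlength=atoms.size)
    return atoms, probs


def wilcoxon_rank_sum(
    values_a: Sequence[float], values_b: Sequence[float], exact_limit: int = 50
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Exact enumeration when both samples are smaller than ``exact_limit`` and
    the pooled values carry no ties; otherwise a normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("samples must be finite")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n < exact_limit and m < exact_limit:
        w_vals, pmf = rank_sum_null_pmf(n, m)
        idx = int(round(w)) - int(w_vals[0])
        p_le = float(pmf[: idx + 1].sum())
        p_ge = float(pmf[idx:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        total = n + m
        mu = n * m / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (total * (total - 1)))
        sigma2 = n * m / 12.0 * ((total + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = u - mu
            z -= np.sign(z) * 0.5  # continuity correction
            z /= np.sqrt(sigma2)
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal+tie-correction"
    return TestResult(statistic=w, p_value=p, method=method, n=(n, m))


def _ols(values: np.ndarray, x: np.ndarray) -> RegressionResult:
    if np.std(values) == 0.0:
        # zero response variance: slope indistinguishable from 0
        return RegressionResult(
            slope=0.0, intercept=float(values[0]), r_squared=0.0, p_value=1.0,
            n=values.size, degenerate=True,
        )
    fit = sps.linregress(x, values)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=values.size,
    )


def linreg_age(values: Sequence[float], ages: Sequence[float]) -> RegressionResult:
    """OLS of contrast on age with R^2 and the two-sided slope p-value."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValueError("values and ages must be 1-D and aligned")
    if values.size < 3:
        raise ValueError("at least 3 points are required")
    if np.std(ages) == 0.0:
        raise ValueError("ages must not all be equal")
    return _ols(values, ages)


def _require_cohort_columns(cohort: pd.DataFrame, cols: set[str]) -> None:
    missing = cols - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns {sorted(missing)}")


def volume_contrast_correlation(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per group x tissue OLS of mean contrast on normalized tissue volume.

    Uses each subject's GM (or WM) regional mean against the corresponding
    normalized volume fraction; subjects with missing fractions are dropped
    and the count is logged.
    """
    _require_cohort_columns(
        cohort, {"subject_id", "group", "region", "mean_percent", "gm_fraction", "wm_fraction"}
    )
    rows = []
    for group in GROUPS:
        for tissue, frac_col in (("GM", "gm_fraction"), ("WM", "wm_fraction")):
            sub = cohort[(cohort["group"] == group) & (cohort["region"] == tissue)]
            ok = sub[frac_col].notna() & sub["mean_percent"].notna()
            dropped = int((~ok).sum())
            if dropped:
                logger.info(
                    "volume correlation %s/%s: dropped %d subject(s) with missing data",
                    group, tissue, dropped,
                )
            sub = sub[ok]
            if len(sub) < 3 or np.std(sub[frac_col].to_numpy()) == 0:
                continue
            res = _ols(sub["mean_percent"].to_numpy(), sub[frac_col].to_numpy())
            rows.append(
                dict(group=group, tissue=tissue, slope=res.slope,
                     intercept=res.intercept, r_squared=res.r_squared,
                     p_value=res.p_value, n=res.n)
            )
    return pd.DataFrame(rows, columns=["group", "tissue", "slope", "intercept",
                                       "r_squared", "p_value", "n"])


def build_results_table(cohort: pd.DataFrame) -> ResultsBundle:
    """Cohort results in the layout of the study's summary table.

    ``comparison`` holds one row per region x group with the group mean (SD)
    of per-subject regional contrast and the rank-sum p-value of the group
    comparison; ``regressions`` holds per-group OLS of contrast on age for
    GM, WM and the seven cortical regions.  A region missing for more than
    half of the subjects is excluded with a warning.
    """
    _require_cohort_columns(
        cohort, {"subject_id", "group", "age", "region", "mean_percent"}
    )
    bad_groups = set(cohort["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}")
    dup = cohort.duplicated(["subject_id", "region"])
    if dup.any():
        raise ValueError("cohort table must have one row per subject x region")

    n_subjects = cohort["subject_id"].nunique()
    comp_rows, reg_rows = [], []
    for region in REGIONS:
        sub = cohort[(cohort["region"] == region) & cohort["mean_percent"].notna()]
        if len(sub) < 0.5 * n_subjects:
            warnings.warn(
                f"region {region} present for only {len(sub)}/{n_subjects} "
                "subjects; excluded from the results table",
                stacklevel=2,
            )
            continue
        by_group = {g: sub[sub["group"] == g] for g in GROUPS}
        if all(len(v) > 0 for v in by_group.values()):
            test = wilcoxon_rank_sum(
                by_group[GROUPS[0]]["mean_percent"], by_group[GROUPS[1]]["mean_percent"]
            )
            p = test.p_value
        else:
            p = np.nan
        for g in GROUPS:
            vals = by_group[g]["mean_percent"].to_numpy()
            comp_rows.append(
                dict(
                    region=region,
                    group=g,
                    mean=float(vals.mean()) if vals.size else np.nan,
                    sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    n=int(vals.size),
                    p_value=p,
                )
            )
        if region in REGRESSION_REGIONS:
            for g in GROUPS:
                grp = by_group[g]
                if len(grp) < 3 or np.std(grp["age"].to_numpy()) == 0:
                    continue
                res = linreg_age(grp["mean_percent"].to_numpy(), grp["age"].to_numpy())
                reg_rows.append(
                    dict(region=region, group=g, slope=res.slope,
                         intercept=res.intercept, r_squared=res.r_squared,
                         p_value=res.p_value, n=res.n)
                )
    comparison = pd.DataFrame(
        comp_rows, columns=["region", "group", "mean", "sd", "n", "p_value"]
    )
    regressions = pd.DataFrame(
        reg_rows, columns=["region", "group", "slope", "intercept", "r_squared",
                           "p_value", "n"]
    )
    if {"gm_fraction", "wm_fraction"} <= set(cohort.columns):
        volume = volume_contrast_correlation(cohort)
    else:
        volume = pd.DataFrame(
            columns=["group", "tissue", "slope", "intercept", "r_squared", "p_value", "n"]
        )
    return ResultsBundle(
        comparison=comparison, regressions=regressions,
        volume_correlations=volume, cohort=cohort.copy(),
    )
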