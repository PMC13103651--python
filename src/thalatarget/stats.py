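"""Inferential layer: independent-samples t tests and Pearson correlations.

Defaults follow common clinical-neuroimaging practice: pooled-variance
Student t (Welch available), two-tailed p values, alpha 0.05, Pearson
confidence intervals via the Fisher transform. No multiple-testing
correction is applied anywhere; report writers count the tests performed
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ArgumentError, DataError
from .fc import R_CLIP

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "two_sample_t",
    "two_sample_t_from_stats",
    "pearson_test",
    "delta_correlation",
    "chi_square_counts",
    "pearson_power",
    "pearson_sampling_band",
]


@dataclass
class GroupComparison:
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t: float
    p: float
    df: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ArgumentError("p must lie in [0, 1]")
        if not np.isfinite(self.t):
            raise ArgumentError("t must be finite")
        if min(self.n1, self.n2) < 2:
            raise ArgumentError("each group needs at least 2 observations")


@dataclass
class CorrelationResult:
    n: int
    r: float
    p: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ArgumentError("p must lie in [0, 1]")
        if not (-1.0 <= self.r <= 1.0):
            raise ArgumentError("r must lie in [-1, 1]")
        if not (self.ci_low - 1e-12 <= self.r <= self.ci_high + 1e-12):
            raise ArgumentError("confidence interval must contain r")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


def two_sample_t(a, b, method: str = "pooled") -> GroupComparison:
    """Independent two-sample t test (pooled Student by default)."""
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ArgumentError("each sample needs at least 2 observations")
    if method not in ("pooled", "welch"):
        raise ArgumentError("method must be 'pooled' or 'welch'")
    sd1, sd2 = float(np.std(a, ddof=1)), float(np.std(b, ddof=1))
    if sd1 == 0.0 and sd2 == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return GroupComparison(len(a), len(b), float(a.mean()), float(b.mean()),
                                   sd1, sd2, 0.0, 1.0, len(a) + len(b) - 2, method)
        raise DataError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=(method == "pooled"))
    return GroupComparison(len(a), len(b), float(a.mean()), float(b.mean()), sd1, sd2,
                           float(res.statistic), float(res.pvalue), float(res.df), method)


def two_sample_t_from_stats(mean1: float, sd1: float, n1: int,
                            mean2: float, sd2: float, n2: int,
                            method: str = "pooled") -> GroupComparison:
    """Same test computed from summary statistics (means, SDs, group sizes)."""
    if min(n1, n2) < 2:
        raise ArgumentError("each group needs at least 2 observations")
    if method not in ("pooled", "welch"):
        raise ArgumentError("method must be 'pooled' or 'welch'")
    if sd1 == 0.0 and sd2 == 0.0:
        if np.isclose(mean1, mean2):
            return GroupComparison(n1, n2, mean1, mean2, sd1, sd2, 0.0, 1.0,
                                   n1 + n2 - 2, method)
        raise DataError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=(method == "pooled"))
    df = n1 + n2 - 2 if method == "pooled" else _welch_df(sd1, n1, sd2, n2)
    return GroupComparison(n1, n2, mean1, mean2, sd1, sd2, float(t), float(p),
                           float(df), method)


def _welch_df(sd1: float, n1: int, sd2: float, n2: int) -> float:
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def pearson_test(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with two-tailed p and a Fisher-transform confidence interval.

    At |r| = 1 the t statistic degenerates; p is reported as 0 (below the
    machine floor) and the interval uses the same clipping as fisher_z.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    if len(x) != len(y):
        raise ArgumentError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ArgumentError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation is undefined for a constant sample")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(p):
        p = 0.0
    z = np.arctanh(np.clip(r, -(1 - R_CLIP), 1 - R_CLIP))
    if n > 3:
        half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo, hi = -1.0, 1.0
    return CorrelationResult(n, r, p, float(min(lo, r)), float(max(hi, r)))


def delta_correlation(fc_pre, fc_post, fs14_pre, fs14_post) -> CorrelationResult:
    """Pearson correlation of paired changes: (post-pre FC) vs (post-pre FS14)."""
    fc_pre = _as_sample(fc_pre, "fc_pre")
    fc_post = _as_sample(fc_post, "fc_post")
    s_pre = _as_sample(fs14_pre, "fs14_pre")
    s_post = _as_sample(fs14_post, "fs14_post")
    if not (len(fc_pre) == len(fc_post) == len(s_pre) == len(s_post)):
        raise ArgumentError("pre/post samples must be paired with equal lengths")
    d_fc = fc_post - fc_pre
    d_s = s_post - s_pre
    if np.ptp(d_fc) == 0:
        raise DataError("all FC changes are identical; the delta correlation is undefined")
    if np.ptp(d_s) == 0:
        raise DataError("all FS14 changes are identical; the delta correlation is undefined")
    return pearson_test(d_fc, d_s)


def chi_square_counts(table, correction: bool = False):
    """Chi-square test of independence on a contingency table (demographics
    utility). Returns (chi2, p, dof)."""
    chi2, p, dof, _ = sps.chi2_contingency(np.asarray(table), correction=correction)
    return float(chi2), float(p), int(dof)


def pearson_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Analytic two-tailed power of the Pearson test via the Fisher
    approximation: z ~ Normal(atanh(r), 1/(n-3))."""
    if n <= 3:
        raise ArgumentError("power approximation needs n > 3")
    lam = abs(np.arctanh(r)) * np.sqrt(n - 3)
    crit = sps.norm.ppf(1 - alpha / 2)
    return float(sps.norm.cdf(lam - crit) + sps.norm.cdf(-lam - crit))


def pearson_sampling_band(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Central ``level`` band of the sample correlation around a true r
    (Fisher approximation); used to judge recovery of a planted coupling."""
    if n <= 3:
        raise ArgumentError("band approximation needs n > 3")
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    z = np.arctanh(r)
    return float(np.tanh(z - half)), float(np.tanh(z + half))
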