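"""Two-group comparisons and summaries used throughout the pipeline.

Paired comparisons use Wilcoxon's signed-rank test, unpaired comparisons the
Wilcoxon rank-sum (Mann-Whitney) test; all tests are two-sided unless stated.
Small samples use exact null enumeration, larger ones a tie-corrected normal
approximation with continuity correction.  Summaries are mean +/- SEM
(sample sd / sqrt(n)).  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "summarize_mean_sem",
]

EXACT_N_SIGNED_RANK = 12
EXACT_N_RANK_SUM = 10


@dataclass
class StatResult:
    test: str
    statistic_z: float
    p_value: float
    n: tuple[int, ...]
    paired: bool
    exact: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _signed_rank_z(diffs: np.ndarray) -> float:
    """Normal-approximation Z with continuity and tie correction."""
    n = len(diffs)
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    d = w_plus - mu
    cc = 0.5 * np.sign(d)
    return float((d - cc) / sigma) if sigma > 0 else 0.0


def wilcoxon_signed_rank(differences: np.ndarray) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (standard convention).  Exact null
    enumeration for n <= 12 without ties in |d|; otherwise the normal
    approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    unique_abs = len(np.unique(np.abs(d))) == n
    exact = n <= EXACT_N_SIGNED_RANK and unique_abs
    method = "exact" if exact else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, correction=True, method=method)
    return StatResult(
        test="wilcoxon_signed_rank",
        statistic_z=_signed_rank_z(d),
        p_value=float(res.pvalue),
        n=(n,),
        paired=True,
        exact=exact,
    )


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    n, m = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (nm * (nm - 1))
    sigma = np.sqrt(n * m / 12.0 * (nm + 1 - tie_term))
    d = u - mu
    cc = 0.5 * np.sign(d)
    return float((d - cc) / sigma) if sigma > 0 else 0.0


def wilcoxon_rank_sum(group_a: np.ndarray, group_b: np.ndarray) -> StatResult:
    """Two-sided Wilcoxon rank-sum test for two unpaired groups.

    Exact for min(n, m) <= 10 without cross-group ties; tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = min(len(a), len(b)) <= EXACT_N_RANK_SUM and no_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        test="wilcoxon_rank_sum",
        statistic_z=_rank_sum_z(a, b),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        paired=False,
        exact=exact,
    )


def summarize_mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    """(mean, SEM, n) with SEM = sample sd / sqrt(n); n = 1 gives SEM 0."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("cannot summarize an empty vector")
    if n == 1:
        warnings.warn("single observation: SEM reported as 0", stacklevel=2)
        return float(v[0]), 0.0, 1
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n)), n
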