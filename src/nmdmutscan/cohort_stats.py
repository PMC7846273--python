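"""Cohort-level statistics: two-proportion tests, Mann–Whitney U, t-tests.

The headline cohort comparison — a reported mutation frequency of 18/23
against 0/34 in later cohorts — uses the two-sided binomial proportion
test.  Two variants are provided: the pooled two-proportion z-test without
continuity correction (default) and Fisher's exact test; the reported
discrepancy is significant at p < 1e-8 under either.  No multiple-testing
correction is applied anywhere in the package: raw thresholds are used
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CohortCounts", "two_proportion_test", "mann_whitney_u", "two_sided_t_test"]


@dataclass(frozen=True)
class CohortCounts:
    """Mutation-frequency pair: k successes of n trials per cohort."""

    k1: int
    n1: int
    k2: int
    n2: int

    def __post_init__(self):
        for k, n in ((self.k1, self.n1), (self.k2, self.n2)):
            if n < 1:
                raise ValueError("each cohort needs n >= 1")
            if not 0 <= k <= n:
                raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")


def two_proportion_test(counts: CohortCounts, method: str = "pooled_z") -> float:
    """Two-sided p-value for equality of two binomial proportions.

    ``pooled_z``: z = (p2 − p1) / sqrt(p(1−p)(1/n1 + 1/n2)) with p pooled,
    no continuity correction, p-value from the standard normal.  Degenerate
    pooled proportions (0 or 1, i.e. no variation at all) give p = 1.
    ``fisher``: exact two-sided hypergeometric test on the 2x2 table.
    """
    k1, n1, k2, n2 = counts.k1, counts.n1, counts.k2, counts.n2
    if method == "pooled_z":
        p1, p2 = k1 / n1, k2 / n2
        pooled = (k1 + k2) / (n1 + n2)
        if pooled in (0.0, 1.0):
            return 1.0
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = (p2 - p1) / se
        return float(2 * stats.norm.sf(abs(z)))
    if method == "fisher":
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown method {method!r}")


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact null distribution when the combined sample size is <= 20 and the
    data are tie-free; tie-corrected normal approximation otherwise.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method, use_continuity=False).pvalue)


def two_sided_t_test(sample_a: Sequence[float], sample_b: Sequence[float],
                     variant: str = "pooled") -> float:
    """Two-sided two-sample t-test p-value (Student pooled-variance by
    default, Welch on request).

    Degenerate conventions: when both samples have zero variance, p = 1 if
    the means agree and p = 0 otherwise.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if math.isclose(a.mean(), b.mean(), rel_tol=0, abs_tol=0) else 0.0
    import warnings
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning; the
        # fully degenerate cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=(variant == "pooled")).pvalue
    return float(p) if not math.isnan(p) else 1.0
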