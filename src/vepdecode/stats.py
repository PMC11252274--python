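"""Statistical comparisons: Wilcoxon signed-rank model contrasts and the
point-biserial correlation between classifier correctness and a score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass
class ComparisonReport:
    p_value: float
    alternative: str
    family_alpha: float
    n_comparisons: int
    n_effective: int                 # pairs remaining after dropping zeros

    @property
    def corrected_alpha(self) -> float:
        """Bonferroni-corrected per-test alpha."""
        return self.family_alpha / self.n_comparisons

    @property
    def significant(self) -> bool | None:
        if np.isnan(self.p_value):
            return None
        return self.p_value < self.corrected_alpha


def wilcoxon_compare(acc_a: np.ndarray, acc_b: np.ndarray,
                     alternative: str = "greater", n_comparisons: int = 1,
                     family_alpha: float = 0.05) -> ComparisonReport:
    """Paired signed-rank test of per-subject accuracies (a vs b).

    Uses the exact null distribution for small samples (no ties); zero
    differences are dropped (classical treatment).  All-zero differences
    yield p = 1 and no decision.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return ComparisonReport(p_value=1.0, alternative=alternative,
                                family_alpha=family_alpha,
                                n_comparisons=n_comparisons, n_effective=0)
    if len(d) < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    method = "exact" if len(d) <= 25 else "approx"
    res = sstats.wilcoxon(d, alternative=alternative, method=method,
                          zero_method="wilcox")
    return ComparisonReport(p_value=float(res.pvalue), alternative=alternative,
                            family_alpha=family_alpha,
                            n_comparisons=n_comparisons, n_effective=len(d))


def signed_rank_p_exhaustive(d: np.ndarray, alternative: str = "greater") -> float:
    """Exact one/two-sided signed-rank p by enumerating all 2^n sign patterns.

    Independent oracle for :func:`wilcoxon_compare`; practical for n <= ~16.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = 1 << n
    stats_all = np.empty(total)
    for m in range(total):
        picks = [(m >> i) & 1 for i in range(n)]
        stats_all[m] = (ranks * np.asarray(picks)).sum()
    if alternative == "greater":
        return float((stats_all >= w_obs).sum() / total)
    if alternative == "less":
        return float((stats_all <= w_obs).sum() / total)
    hi = (stats_all >= w_obs).sum() / total
    lo = (stats_all <= w_obs).sum() / total
    return float(min(1.0, 2 * min(hi, lo)))


def point_biserial(binary: np.ndarray, scores: np.ndarray) -> float:
    """Point-biserial correlation: Pearson r with one variable coded 0/1.

    Computed from the group-difference formula
    r = (M1 - M0) * sqrt(p*q) / s_n; identical to the Pearson correlation of
    the 0/1 codes with the scores.
    """
    y = np.asarray(binary, dtype=float)
    x = np.asarray(scores, dtype=float)
    if y.shape != x.shape:
        raise ValueError("inputs must have equal length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary vector must contain only 0 and 1")
    n1 = y.sum()
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty")
    s = x.std()                      # population SD, matching Pearson
    if s == 0:
        raise ValueError("scores are constant; correlation undefined")
    m1 = x[y == 1].mean()
    m0 = x[y == 0].mean()
    p = n1 / len(y)
    return float((m1 - m0) * np.sqrt(p * (1 - p)) / s)
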