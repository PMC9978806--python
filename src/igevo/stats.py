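"""Exact and large-sample rank tests shared by all analysis stages.

Both tests compute their exact null distribution by dynamic programming
(midranks doubled to integers) for small samples, and switch to a normal
approximation with tie and continuity corrections for large samples.
Two-sided p-values are 2*min(P(T<=t), P(T>=t)), capped at 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_MIN_N = 10


@dataclass(frozen=True)
class TestResult:
    method: str  # signed_rank_exact | signed_rank_normal | rank_sum_exact | rank_sum_normal
    statistic: float
    n: tuple[int, ...]
    p_two_sided: float
    n_zero_dropped: int = 0


def _two_sided_from_pmf(pmf: np.ndarray, support: np.ndarray, observed: float) -> float:
    """Two-sided p from an exact null pmf over an integer support grid."""
    # tolerate float fuzz on the observed statistic
    le = pmf[support <= observed + 1e-9].sum()
    ge = pmf[support >= observed - 1e-9].sum()
    return float(min(1.0, 2.0 * min(le, ge)))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_null_pmf(ranks2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null of W (sum of positive ranks) given doubled midranks.

    Each |difference| independently carries its rank with probability 1/2.
    Returns (pmf, support) on the doubled-rank scale.
    """
    total = int(ranks2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in ranks2:
        nxt = poly.copy()
        nxt[int(r) :] += poly[: total + 1 - int(r)]
        poly = nxt
    poly /= poly.sum()
    return poly, np.arange(total + 1)


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (count reported). Midranks are used for
    ties. Exact enumeration of the null for n <= 25 non-zero pairs; normal
    approximation with tie and continuity corrections otherwise.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one pair")
    if np.isnan(d).any():
        raise ValueError("NaN differences are not allowed")
    nonzero = d[d != 0]
    n_zero = int(d.size - nonzero.size)
    n = nonzero.size
    if n == 0:
        logger.warning("all paired differences are zero; p = 1")
        return TestResult("signed_rank_exact", 0.0, (0,), 1.0, n_zero)
    ranks = rankdata(np.abs(nonzero))
    w_pos = float(ranks[nonzero > 0].sum())
    if n <= EXACT_SIGNED_RANK_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf, support = _signed_rank_null_pmf(ranks2)
        p = _two_sided_from_pmf(pmf, support, 2 * w_pos)
        return TestResult("signed_rank_exact", w_pos, (n,), p, n_zero)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of W
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_pos - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * _norm_sf(abs(z))))
    return TestResult("signed_rank_normal", w_pos, (n,), p, n_zero)


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# Mann-Whitney / rank-sum
# ---------------------------------------------------------------------------


def _rank_sum_null_pmf(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of the Mann-Whitney U statistic (no ties)."""
    # f[j, u] = #ways to realise U=u using j items from group 1
    max_u = n1 * n2
    f = np.zeros((n1 + 1, max_u + 1))
    f[0, 0] = 1.0
    # classic recurrence over combined ranks
    for i in range(1, n1 + n2 + 1):
        g = f.copy()
        for j in range(min(i, n1), 0, -1):
            # item i assigned to group 1 contributes (i - j) wins over group 2
            u_inc = i - j
            if u_inc > max_u:
                continue
            g[j, u_inc:] += f[j - 1, : max_u + 1 - u_inc]
        f = g
    pmf = f[n1]
    pmf = pmf / pmf.sum()
    return pmf, np.arange(max_u + 1)


def rank_sum(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    Exact null (no-tie DP) when min(n) <= 10 and the data are tie-free;
    otherwise a normal approximation with midranks, tie correction and
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(n1, n2) <= EXACT_RANK_SUM_MAX_MIN_N and not has_ties:
        pmf, support = _rank_sum_null_pmf(n1, n2)
        p = _two_sided_from_pmf(pmf, support, u1)
        return TestResult("rank_sum_exact", u1, (n1, n2), p)
    mean = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    diff = u1 - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * _norm_sf(abs(z))))
    return TestResult("rank_sum_normal", u1, (n1, n2), p)
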