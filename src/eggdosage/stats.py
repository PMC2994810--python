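"""Self-contained rank tests.

The marker-selection and classifier stages use two-sided Mann-Whitney
and Wilcoxon signed-rank tests at very small sample sizes (5–10 per
arm), where normal approximations are poor.  Both tests are implemented
here with exact permutation enumeration at small n (all C(n+m, n) group
labelings, respectively all 2^n sign assignments) and a tie-corrected,
continuity-corrected normal approximation beyond, so that no external
statistics package's conventions are baked into reported p-values.

Two-sided p-values are twice the smaller tail probability of the
observed statistic under the permutation distribution, capped at 1.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np

__all__ = ["TestResult", "mann_whitney_u", "wilcoxon_signed_rank"]

#: Largest per-arm size at which Mann-Whitney enumerates exactly.
MANN_WHITNEY_EXACT_LIMIT = 8
#: Largest number of nonzero pairs at which Wilcoxon enumerates exactly.
WILCOXON_EXACT_LIMIT = 15


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    exact: bool


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned their average rank."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _two_sided_from_tails(p_low: float, p_high: float) -> float:
    return min(1.0, 2.0 * min(p_low, p_high))


def _normal_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U of the first sample.

    Exact by enumeration of all group labelings when both arms have at
    most ``MANN_WHITNEY_EXACT_LIMIT`` observations (ties handled through
    midranks); tie- and continuity-corrected normal approximation above.
    When every pooled value is identical the test is degenerate and
    p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if not np.all(np.isfinite(pooled)):
        raise ValueError("observations must be finite")
    ranks = _midranks(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if max(n, m) <= MANN_WHITNEY_EXACT_LIMIT:
        # enumerate every assignment of n pooled ranks to the first group
        total = 0
        at_most = 0
        at_least = 0
        base = n * (n + 1) / 2.0
        eps = 1e-9
        for idx in combinations(range(n + m), n):
            u = float(ranks[list(idx)].sum() - base)
            total += 1
            if u <= u_obs + eps:
                at_most += 1
            if u >= u_obs - eps:
                at_least += 1
        p = _two_sided_from_tails(at_most / total, at_least / total)
        return TestResult(u_obs, p, True)

    mean_u = n * m / 2.0
    # tie correction on the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = float(((counts**3 - counts).sum())) / (nm * (nm - 1)) if nm > 1 else 0.0
    var_u = n * m / 12.0 * ((nm + 1) - tie_term)
    if var_u <= 0:
        return TestResult(u_obs, 1.0, False)
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)
    p = min(1.0, 2.0 * _normal_sf(max(z, 0.0)))
    return TestResult(u_obs, p, False)


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    ``x`` and ``y`` are paired observations; pass ``y=None`` to test
    differences directly.  Zero differences are dropped (Wilcoxon
    convention); if none remain, p = 1.  Statistic is W+, the rank sum
    of positive differences.  Exact over all 2^n sign assignments for up
    to ``WILCOXON_EXACT_LIMIT`` nonzero pairs, normal approximation with
    tie and continuity corrections beyond.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, True)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= WILCOXON_EXACT_LIMIT:
        # distribution of W+ over all sign assignments of the observed ranks
        dist: dict[float, int] = {0.0: 1}
        for r in ranks:
            new: dict[float, int] = {}
            for w, c in dist.items():
                new[w] = new.get(w, 0) + c
                new[w + r] = new.get(w + r, 0) + c
            dist = new
        total = 2**n
        eps = 1e-9
        at_most = sum(c for w, c in dist.items() if w <= w_plus + eps)
        at_least = sum(c for w, c in dist.items() if w >= w_plus - eps)
        p = _two_sided_from_tails(at_most / total, at_least / total)
        return TestResult(w_plus, p, True)

    mean_w = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        return TestResult(w_plus, 1.0, False)
    z = (abs(w_plus - mean_w) - 0.5) / math.sqrt(var_w)
    p = min(1.0, 2.0 * _normal_sf(max(z, 0.0)))
    return TestResult(w_plus, p, False)
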