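"""Cross-cutting statistics: signed r^2 contrasts and the resampling
spatial-overlap metric.

``signed_r2`` is the squared point-biserial correlation between group
membership and value, signed by the direction of the mean difference (this
convention is recorded in output metadata; it is a declared choice).

``spatial_overlap`` compares two per-channel measures: the dot product gives
a "true" overlap, normalized by the maximum achievable overlap (both vectors
independently sorted ascending - the rearrangement-inequality maximum), and
its significance is assessed by scrambling channel labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sstats

from .errors import ParameterError


def signed_r2(a, b) -> float:
    """Signed explained-variance contrast between two samples.

    Returns the squared point-biserial correlation of group membership with
    value, multiplied by ``sign(mean(a) - mean(b))``.  Zero total variance
    returns 0 by convention.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2")
    values = np.concatenate([a, b])
    labels = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    vv = values.var()
    if vv == 0 or labels.var() == 0:
        return 0.0
    r = np.corrcoef(labels, values)[0, 1]
    return float(np.sign(a.mean() - b.mean()) * r ** 2)


def signed_r2_with_p(a, b) -> tuple[float, float]:
    """Signed r^2 plus the two-sample Welch t-test p-value."""
    r2 = signed_r2(a, b)
    p = float(sstats.ttest_ind(np.asarray(a, dtype=float),
                               np.asarray(b, dtype=float),
                               equal_var=False).pvalue)
    if math.isnan(p):  # zero variance in both groups
        p = 1.0
    return r2, p


@dataclass
class OverlapResult:
    """Normalized spatial overlap with its permutation p-value."""

    overlap: float
    n_permutations: int
    p_value: float
    seed: int | None
    exact: bool = False

    def __post_init__(self):
        if abs(self.overlap) > 1 + 1e-12:
            raise ParameterError("overlap metric cannot exceed 1 in magnitude")


def _max_overlap(a: np.ndarray, b: np.ndarray) -> float:
    # rearrangement-inequality maximum of |sum a_i b_(pi(i))| over pairings:
    # identical to the sorted-ascending pairing for non-negative inputs and
    # keeps |overlap| <= 1 for mixed-sign inputs
    return float(np.sort(np.abs(a)) @ np.sort(np.abs(b)))


def spatial_overlap(a, b, n_perm: int = 10_000,
                    seed: int | None = 0) -> OverlapResult:
    """Overlap of two per-channel measures with label-scrambling significance.

    The statistic is the dot product ``a . b`` divided by the maximum
    achievable overlap over channel pairings (both magnitude distributions
    independently re-sorted ascending); the p-value is
    the fraction of label scrambles whose overlap meets or exceeds the true
    value (meets or falls below it when the true overlap is negative).  When
    the full permutation group is smaller than ``n_perm`` the p-value is
    computed by exact enumeration; otherwise by Monte Carlo driven by a
    counter-based (Philox) generator keyed by ``seed``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ParameterError("inputs must be equal-length 1-D, n >= 2")
    if not a.any() or not b.any():
        raise ParameterError("overlap undefined for an all-zero vector")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    denom = _max_overlap(a, b)
    if denom <= 0:
        raise ParameterError("degenerate inputs: zero maximal overlap")
    true = float(a @ b) / denom

    n = len(a)
    n_total = math.factorial(n)
    if n_total <= n_perm:
        surrogates = np.array([a[list(p)] @ b for p in
                               permutations(range(n))]) / denom
        hits = (surrogates >= true) if true >= 0 else (surrogates <= true)
        return OverlapResult(true, n_total, float(hits.mean()), seed,
                             exact=True)

    rng = np.random.Generator(np.random.Philox(key=seed))
    hits = 0
    block = 100_000
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        idx = rng.permuted(np.broadcast_to(np.arange(n), (m, n)), axis=1)
        surr = (a[idx] @ b) / denom
        hits += int(((surr >= true) if true >= 0 else (surr <= true)).sum())
        done += m
    p = (hits + 1) / (n_perm + 1)
    return OverlapResult(true, n_perm, float(p), seed, exact=False)


def expected_false_positives(n_tests: int, alpha: float,
                             decimals: int = 1) -> float:
    """Expected chance count among ``n_tests`` independent tests at ``alpha``."""
    if n_tests < 0 or not 0 < alpha < 1:
        raise ParameterError("need n_tests >= 0 and alpha in (0, 1)")
    return round(n_tests * alpha, decimals)


def conditional_percentage(k: int, n: int) -> int:
    """``100 * k / n`` rounded to the nearest integer percent."""
    if not 0 <= k <= n or n == 0:
        raise ParameterError("need 0 <= k <= n, n > 0")
    return int(round(100.0 * k / n))
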