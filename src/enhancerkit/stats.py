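"""Shared statistical primitives: BH adjustment, exact Wilcoxon signed-rank,
hypergeometric and binomial tail probabilities.

The exact signed-rank p-value is computed by dynamic programming over the
distribution of the positive-rank sum under random sign flips, which is
identical to enumerating all 2^n sign assignments; midranks for tied
magnitudes are doubled so the DP runs on integers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_WILCOXON_MAX_N = 25


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN entries stay NaN and
    do not count toward the number of tests."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for positive-rank sum ``w2`` given doubled ranks."""
    total = int(ranks2.sum())
    # distribution of 2*W+ over all sign assignments, by convolution
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(w2))
    p_ge = dist[w2:].sum()
    p_le = dist[: w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_signed_rank(d: np.ndarray) -> tuple[float, float, int]:
    """Paired signed-rank test on differences ``d``.

    Zero differences are dropped. Exact (sign-enumeration) p for
    n <= EXACT_WILCOXON_MAX_N informative pairs; normal approximation with
    continuity and tie corrections beyond that. Returns (W+, two-sided p, n).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _signed_rank_exact_p(np.round(2 * ranks), 2 * w_plus)
        return w_plus, p, n
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = (counts**3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    diff = w_plus - mu
    # continuity correction pulls the statistic toward the mean
    z = (diff - 0.5 * np.sign(diff)) / sigma
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return w_plus, p, n


def hypergeom_upper_tail(overlap: int, universe: int, size_a: int, size_b: int) -> float:
    """P(X >= overlap) drawing ``size_b`` from a universe containing ``size_a``
    successes — the one-tailed Fisher enrichment p-value."""
    if size_a > universe or size_b > universe:
        raise ValueError("set sizes exceed the universe")
    return float(sps.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def binom_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    return float(sps.binom.sf(k - 1, n, p0))
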