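"""Shared statistical primitives.

All group comparisons in the pipeline funnel through the same three
primitives so that the Wilcoxon policy (exact for small tie-free samples,
tie-corrected normal approximation with continuity correction otherwise),
the Fisher exact test, and Benjamini-Hochberg correction behave identically
across modules.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "fisher_test", "bh_adjust", "EXACT_MAX_N"]

#: Largest per-group size at which the exact Mann-Whitney null is enumerated.
EXACT_MAX_N = 25


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact null distribution when both groups have at most ``EXACT_MAX_N``
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with tie correction and continuity correction.

    Raises
    ------
    ValueError
        If either group is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def fisher_test(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2x2 contingency table.

    ``alternative`` is one of ``two-sided``, ``greater``, ``less``.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    if (tab < 0).any():
        raise ValueError("contingency counts must be non-negative")
    return float(sps.fisher_exact(tab, alternative=alternative)[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR q-values) for one family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]
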