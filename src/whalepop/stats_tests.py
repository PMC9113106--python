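"""Small shared hypothesis tests: Pearson correlation and one-way ANOVA.

Thin wrappers over scipy.stats with the input validation the pipeline relies
on; re-exported from :mod:`whalepop.pipeline`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def pearson_correlation(x, y) -> tuple:
    """Sample Pearson r and two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> tuple:
    """Classic fixed-effects one-way ANOVA F statistic and p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least two members")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("degenerate zero-variance data")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
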