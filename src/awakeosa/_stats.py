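"""Small statistical helpers shared across the reduction pipeline.

The robustness stage runs on the order of 10^5 normality checks per
cohort, so the Lilliefors test statistic is computed vectorized over
feature columns; critical values come from statsmodels' own lookup
table, keeping the decision identical to
``statsmodels.stats.diagnostic.lilliefors``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats._lilliefors import get_lilliefors_table

__all__ = ["lilliefors_statistic", "lilliefors_critical_value", "lilliefors_normal"]

_TABLE = get_lilliefors_table("norm")


def lilliefors_statistic(x: np.ndarray) -> np.ndarray:
    """Kolmogorov-Smirnov D with mean and sd estimated per column.

    Parameters
    ----------
    x : array of shape (n,) or (n, k)

    Returns
    -------
    D : scalar or array of shape (k,)
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    if scalar:
        x = x[:, None]
    n = x.shape[0]
    if n < 4:
        raise ValueError("Lilliefors test needs at least 4 observations")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = np.sort((x - mu) / sd, axis=0)
    cdf = stats.norm.cdf(z)
    i = np.arange(1.0, n + 1.0)[:, None]
    d_plus = (i / n - cdf).max(axis=0)
    d_minus = (cdf - (i - 1.0) / n).max(axis=0)
    d = np.maximum(d_plus, d_minus)
    return d[0] if scalar else d


@lru_cache(maxsize=None)
def lilliefors_critical_value(n: int, alpha: float = 0.05) -> float:
    """Critical D at level ``alpha`` for sample size ``n`` (statsmodels table)."""
    return float(_TABLE.crit(alpha, n))


def lilliefors_normal(x: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """True where normality is *not* rejected at level ``alpha`` (per column)."""
    x = np.asarray(x, dtype=float)
    d = lilliefors_statistic(x)
    crit = lilliefors_critical_value(x.shape[0], alpha)
    return d < crit
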