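"""Shared helpers: significance stars, Spearman matrices with p-values."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def significance_stars(p: float) -> str:
    """Conventional stars: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(
    a: pd.DataFrame, b: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations (midrank ties) with two-sided p-values.

    With one argument, returns the square r and p matrices over its
    columns; with two, the rectangular a-columns × b-columns block.
    Constant columns yield NaN entries.
    """
    if b is None:
        b = a
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    p = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            xa = a[ca].to_numpy(dtype=float)
            xb = b[cb].to_numpy(dtype=float)
            mask = ~(np.isnan(xa) | np.isnan(xb))
            def _constant(x):
                return np.ptp(x) <= 1e-10 * max(1.0, float(np.max(np.abs(x))))

            if mask.sum() < 3 or _constant(xa[mask]) or _constant(xb[mask]):
                r.loc[ca, cb] = np.nan
                p.loc[ca, cb] = np.nan
                continue
            res = stats.spearmanr(xa[mask], xb[mask])
            r.loc[ca, cb] = float(res.statistic)
            p.loc[ca, cb] = float(res.pvalue)
    return r, p


def star_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """Elementwise significance stars for a p-value matrix."""
    return p.map(significance_stars)
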