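"""Alpha diversity (Chao1, Shannon, Faith's PD) and zone comparisons.

Operates on a sites × ASVs count table. Faith's phylogenetic diversity
follows the rooted convention: the branch path connecting a site's ASVs
to the root is included, so a single-leaf sample has PD equal to its
root-to-leaf path length.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import faith_pd
from skbio.tree import TreeNode

from .utils import significance_stars

logger = logging.getLogger(__name__)


def chao1(counts: np.ndarray) -> float:
    """Classical Chao1 richness estimate.

    S_obs + F1²/(2·F2) when doubletons exist, with the bias-corrected
    fallback S_obs + F1·(F1−1)/2 when F2 = 0 (F1 singletons, F2
    doubletons).
    """
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def shannon(counts: np.ndarray, base: float = math.e) -> float:
    """Shannon diversity −Σ pᵢ log pᵢ over nonzero proportions (nats by default)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def alpha_diversity(
    table: pd.DataFrame,
    tree: TreeNode | None = None,
    shannon_base: float = math.e,
) -> pd.DataFrame:
    """Per-site Chao1, Shannon and (when a tree is given) Faith's PD.

    Parameters
    ----------
    table:
        sites × ASVs count table (non-negative integers).
    tree:
        Rooted tree whose tip names cover the table's ASV columns;
        required for the ``pd`` column.

    Empty sites (total count 0) yield NaN rows with a warning.
    """
    asv_ids = list(table.columns)
    records = []
    for site, row in table.iterrows():
        counts = row.to_numpy(dtype=float)
        if counts.sum() <= 0:
            logger.warning("site %s has zero total count; diversity undefined", site)
            rec = {"site": site, "chao1": np.nan, "shannon": np.nan}
            if tree is not None:
                rec["pd"] = np.nan
            records.append(rec)
            continue
        rec = {
            "site": site,
            "chao1": chao1(counts),
            "shannon": shannon(counts, base=shannon_base),
        }
        if tree is not None:
            rec["pd"] = float(faith_pd(counts, taxa=asv_ids, tree=tree))
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("site")


def zone_anova(
    values: pd.Series, zones: pd.Series, use_kruskal: bool = False
) -> dict:
    """One-way ANOVA of a per-site metric across zones, plus pairwise tests.

    Returns a dict with the overall ``F`` (or Kruskal–Wallis ``H``), its
    ``p``, per-zone means, and a ``pairwise`` table of two-sample
    comparisons with significance stars (* p<0.05, ** p<0.01,
    *** p<0.001).
    """
    values = values.astype(float)
    groups: dict[str, np.ndarray] = {}
    for zone in pd.unique(zones):
        g = values[zones == zone].dropna().to_numpy()
        if len(g) < 2:
            raise ValueError(f"zone '{zone}' has fewer than 2 sites")
        groups[zone] = g
    if len(groups) < 2:
        raise ValueError("need at least 2 zones")
    if use_kruskal:
        stat, p = stats.kruskal(*groups.values())
    else:
        stat, p = stats.f_oneway(*groups.values())
    labels = list(groups)
    pairs = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            t, tp = stats.ttest_ind(groups[a], groups[b])
            pairs.append(
                {"zone_a": a, "zone_b": b, "stat": float(t), "p": float(tp),
                 "stars": significance_stars(tp)}
            )
    return {
        "F": float(stat),
        "p": float(p),
        "means": {z: float(g.mean()) for z, g in groups.items()},
        "pairwise": pd.DataFrame.from_records(pairs),
    }
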