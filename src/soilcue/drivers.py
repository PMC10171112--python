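"""Drivers of metabolic efficiency: RF importance, PCA composites, path model.

Three complementary screens link metabolic efficiency to its candidate
drivers (soil physicochemistry, microbial alpha diversity, enzyme
activities):

* a permutation random forest that ranks predictors by %IncMSE — the
  percent increase in out-of-bag MSE when a predictor is permuted — with
  significance from response-permutation refits;
* pairwise Spearman correlation screens;
* a recursive path model over PCA composite variables (one PC1 score per
  variable group), estimated by per-equation least squares on z-scored
  composites — the maximum-likelihood estimator for recursive, fully
  observed path models — with χ² and RMSEA computed from the
  maximum-likelihood discrepancy between implied and observed
  covariances.

The hypothesized structure: soil properties → {diversity, enzymes,
efficiency}; diversity → {enzymes, efficiency}; enzymes → efficiency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .utils import significance_stars, spearman_matrix

logger = logging.getLogger(__name__)

#: Directed edges of the default hypothesized path structure.
DEFAULT_STRUCTURE: tuple[tuple[str, str], ...] = (
    ("soil", "diversity"),
    ("soil", "enzymes"),
    ("soil", "efficiency"),
    ("diversity", "enzymes"),
    ("diversity", "efficiency"),
    ("enzymes", "efficiency"),
)


# ---------------------------------------------------------------------------
# Random forest permutation importance
# ---------------------------------------------------------------------------

def _forest_incmse(
    X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int, rng: np.random.Generator
) -> np.ndarray:
    """%IncMSE per predictor for one bagged forest.

    Each tree is fit on a bootstrap sample; its out-of-bag rows are
    predicted once intact and once per predictor with that column
    permuted (single batched predict per tree). The importance is the
    mean over trees of the percent increase in OOB MSE.
    """
    n, p = X.shape
    increases = np.full((n_trees, p), np.nan)
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        X_oob = X[oob]
        stacked = [X_oob]
        for j in range(p):
            Xp = X_oob.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            stacked.append(Xp)
        preds = tree.predict(np.vstack(stacked)).reshape(p + 1, len(oob))
        mse = ((preds - y[oob]) ** 2).mean(axis=1)
        if mse[0] == 0:
            # perfect OOB fit: report absolute MSE increase scaled by y variance
            increases[t] = mse[1:] / max(y[oob].var(), 1e-12) * 100.0
        else:
            increases[t] = (mse[1:] - mse[0]) / mse[0] * 100.0
    return np.nanmean(increases, axis=0)


def rf_importance(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    n_perm: int = 999,
    seed: int = 0,
    mtry: int | None = None,
) -> pd.DataFrame:
    """Permutation random-forest importance (%IncMSE) with permutation p-values.

    Parameters
    ----------
    X, y:
        Predictor matrix (≥10 sites) and numeric response.
    n_trees:
        Trees per forest (default 500).
    n_perm:
        Response permutations for the null distribution (default 999);
        each permutation refits the full forest, so reduce for large
        problems.
    mtry:
        Features tried per split; default ⌈p/3⌉ (regression-forest
        convention).

    Returns a DataFrame indexed by predictor with columns ``inc_mse``
    (percent) and ``p`` (upper-tail rank probability of the observed
    importance within the null refits).
    """
    if len(X) < 10:
        raise ValueError("random forest importance needs at least 10 sites")
    yv = y.to_numpy(dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("constant response")
    Xv = X.to_numpy(dtype=float)
    p = Xv.shape[1]
    mtry = mtry or math.ceil(p / 3)
    rng = np.random.default_rng(seed)
    observed = _forest_incmse(Xv, yv, n_trees, mtry, rng)
    null = np.empty((n_perm, p))
    for b in range(n_perm):
        null[b] = _forest_incmse(Xv, rng.permutation(yv), n_trees, mtry, rng)
    pvals = (1 + (null >= observed).sum(axis=0)) / (n_perm + 1)
    return pd.DataFrame(
        {"inc_mse": observed, "p": pvals}, index=X.columns
    ).sort_values("inc_mse", ascending=False)


# ---------------------------------------------------------------------------
# PCA composites
# ---------------------------------------------------------------------------

@dataclass
class CompositeVariable:
    """PC1 summary of a variable group, sign-anchored."""

    scores: pd.Series
    variance_explained: float
    loadings: pd.Series
    anchor: str


def pca_composite(matrix: pd.DataFrame, anchor: str) -> CompositeVariable:
    """First principal component of a variable group as a composite score.

    Variables are z-scored internally (correlation-matrix PCA);
    zero-variance variables are dropped with a warning. The score sign is
    oriented so that its correlation with the ``anchor`` column is ≥ 0,
    making the composite's direction interpretable.
    """
    if matrix.shape[1] < 2:
        raise ValueError("composite needs at least 2 variables")
    if len(matrix) < 3:
        raise ValueError("composite needs at least 3 sites")
    sd = matrix.std(ddof=1)
    dead = sd[sd == 0].index
    if len(dead):
        logger.warning("dropping zero-variance variables: %s", list(dead))
        matrix = matrix.drop(columns=dead)
        if matrix.shape[1] < 2:
            raise ValueError("fewer than 2 variables left after dropping constants")
    if anchor not in matrix.columns:
        raise ValueError(f"anchor '{anchor}' not among composite variables")
    Z = (matrix - matrix.mean()) / matrix.std(ddof=1)
    corr = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v1 = eigvecs[:, -1]
    scores = Z.to_numpy() @ v1
    if np.corrcoef(scores, Z[anchor].to_numpy())[0, 1] < 0:
        v1 = -v1
        scores = -scores
    return CompositeVariable(
        scores=pd.Series(scores, index=matrix.index),
        variance_explained=float(eigvals[-1] / eigvals.sum() * 100.0),
        loadings=pd.Series(v1, index=matrix.columns),
        anchor=anchor,
    )


# ---------------------------------------------------------------------------
# Recursive path model
# ---------------------------------------------------------------------------

@dataclass
class PathModel:
    """Fitted recursive path model over composite variables."""

    structure: tuple[tuple[str, str], ...]
    coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    chi_square: float
    df: int
    rmsea: float
    n: int
    residual_variances: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "structure": [list(e) for e in self.structure],
            "coefficients": {f"{a}->{b}": v for (a, b), v in self.coefficients.items()},
            "r_squared": self.r_squared,
            "chi_square": self.chi_square,
            "df": self.df,
            "rmsea": self.rmsea,
            "n": self.n,
        }


def _check_acyclic(names: list[str], structure) -> list[str]:
    """Topological order of the structure; raises on cycles."""
    parents = {v: [a for a, b in structure if b == v] for v in names}
    order, seen, onstack = [], set(), set()

    def visit(v):
        if v in seen:
            return
        if v in onstack:
            raise ValueError("path structure contains a cycle")
        onstack.add(v)
        for u in parents[v]:
            visit(u)
        onstack.discard(v)
        seen.add(v)
        order.append(v)

    for v in names:
        visit(v)
    return order


def fit_path_model(
    composites: pd.DataFrame,
    structure: tuple[tuple[str, str], ...] = DEFAULT_STRUCTURE,
) -> PathModel:
    """Fit the recursive path model and its ML fit statistics.

    Parameters
    ----------
    composites:
        sites × variables table (typically the four composite scores:
        soil, diversity, enzymes, efficiency). Variables are z-scored
        internally, so path coefficients are standardized.
    structure:
        Directed acyclic edges (parent, child).

    Each endogenous variable is regressed on its structural parents by
    OLS (the ML estimator for recursive models with independent errors).
    χ² = (n−1)·F_ML from the implied vs observed covariance;
    df = p(p+1)/2 − free parameters; RMSEA = √(max(χ²−df, 0)/(df·(n−1))),
    reported as 0 for a saturated (df = 0) model.
    """
    names = list(composites.columns)
    for a, b in structure:
        if a not in names or b not in names:
            raise ValueError(f"structure variable '{a}'->'{b}' not in composites")
    _check_acyclic(names, structure)
    n = len(composites)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    Z = (composites - composites.mean()) / composites.std(ddof=1)
    S = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    corr = S - np.eye(len(names))
    if np.any(np.abs(corr) > 0.999):
        raise ValueError(
            "collinear composites (|r| > 0.999); merge or drop a group"
        )
    idx = {v: i for i, v in enumerate(names)}
    endogenous = sorted({b for _, b in structure}, key=idx.get)
    exogenous = [v for v in names if v not in endogenous]

    B = np.zeros((len(names), len(names)))  # B[child, parent]
    coefficients: dict[tuple[str, str], float] = {}
    r_squared: dict[str, float] = {}
    resid_var: dict[str, float] = {}
    Zv = Z.to_numpy()
    for child in endogenous:
        parents = [a for a, b in structure if b == child]
        Xp = Zv[:, [idx[a] for a in parents]]
        yv = Zv[:, idx[child]]
        beta, *_ = np.linalg.lstsq(Xp, yv, rcond=None)
        fitted = Xp @ beta
        ss_res = float(((yv - fitted) ** 2).sum())
        ss_tot = float((yv**2).sum())
        r_squared[child] = 1.0 - ss_res / ss_tot
        resid_var[child] = ss_res / (n - 1)
        for a, bcoef in zip(parents, beta):
            coefficients[(a, child)] = float(bcoef)
            B[idx[child], idx[a]] = bcoef

    # implied covariance: (I-B)^-1 Psi (I-B)^-T with Psi holding the
    # exogenous (co)variances and the endogenous residual variances
    psi = np.zeros_like(S)
    ex_idx = [idx[v] for v in exogenous]
    psi[np.ix_(ex_idx, ex_idx)] = S[np.ix_(ex_idx, ex_idx)]
    for v in endogenous:
        psi[idx[v], idx[v]] = resid_var[v]
    inv = np.linalg.inv(np.eye(len(names)) - B)
    sigma = inv @ psi @ inv.T

    p = len(names)
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("singular covariance matrix in path model")
    f_ml = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
    chi_square = max((n - 1) * f_ml, 0.0)
    n_free = (
        len(structure)
        + len(endogenous)
        + len(exogenous) * (len(exogenous) + 1) // 2
    )
    df = p * (p + 1) // 2 - n_free
    if df > 0:
        rmsea = math.sqrt(max(chi_square - df, 0.0) / (df * (n - 1)))
    else:
        chi_square = 0.0 if chi_square < 1e-8 else chi_square
        rmsea = 0.0
    return PathModel(
        structure=tuple(structure),
        coefficients=coefficients,
        r_squared=r_squared,
        chi_square=float(chi_square),
        df=int(df),
        rmsea=float(rmsea),
        n=n,
        residual_variances=resid_var,
    )


def correlation_screen(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Long-form Spearman screen between two variable blocks.

    Returns (variable_a, variable_b, r, p, stars) for every pair, with
    pairwise-complete handling of missing values and NaN for constant
    columns.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 4:
        raise ValueError("blocks share fewer than 4 sites")
    r, p = spearman_matrix(a.loc[shared], b.loc[shared])
    records = []
    for ca in r.index:
        for cb in r.columns:
            pv = p.loc[ca, cb]
            records.append({"variable_a": ca, "variable_b": cb,
                            "r": r.loc[ca, cb], "p": pv,
                            "stars": significance_stars(pv)})
    return pd.DataFrame.from_records(records)
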