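"""Feature normalisation, selection, and radiomic-genomic association.

Implements the association side of the pipeline: z-score
standardisation, inter-feature redundancy filtering (|r| > 0.8 drops
one member of the pair), consensus feature selection across four
algorithms (L1-penalised linear model, recursive feature elimination,
gradient-boosted trees, random forest - a feature is retained when at
least two algorithms rank it in their top k), histology-correlated
cytoband selection (|r| > 0.1), and the full radiomic x genomic
Pearson correlation map with thresholded pair lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LassoCV, LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "standardize",
    "redundancy_filter",
    "consensus_select",
    "select_cytobands",
    "cross_correlate",
    "AssociationMap",
]


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores (population SD). Constant columns carry no
    information and are dropped with a log record."""
    if len(table) < 2:
        raise ValueError("standardization requires at least 2 rows")
    sd = table.std(ddof=0)
    # constant within float precision: spread negligible vs magnitude
    scale = table.abs().mean().clip(lower=1.0)
    constant = sd[sd <= 1e-12 * scale].index.tolist()
    if constant:
        logger.info("dropping %d constant columns: %s", len(constant), constant[:10])
        table = table.drop(columns=constant)
        sd = sd.drop(constant)
    return (table - table.mean()) / sd


def redundancy_filter(table: pd.DataFrame, r_max: float = 0.8) -> pd.DataFrame:
    """Drop one member of every feature pair with |r| strictly above
    r_max; the member with the higher mean absolute correlation to all
    other features is dropped (tie: the lexicographically later name).
    """
    corr = table.corr().abs().fillna(0.0)
    np.fill_diagonal(corr.values, 0.0)
    dropped: set[str] = set()
    while True:
        sub = corr.drop(index=dropped, columns=dropped, errors="ignore")
        if sub.empty:
            break
        max_r = sub.values.max()
        if max_r <= r_max:
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = sub.index[i], sub.columns[j]
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = max(a, b)
        dropped.add(victim)
    return table.drop(columns=sorted(dropped))


def consensus_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    k: int = 14,
    min_votes: int = 2,
    seed: int = 0,
) -> tuple[list[str], dict[str, list[str]]]:
    """Consensus feature selection across four algorithms.

    Each selector ranks features and contributes its top k; the final
    set keeps every feature named by at least ``min_votes`` selectors.
    Returns (selected feature names, per-selector top-k lists).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    if k > table.shape[1]:
        raise ValueError("k exceeds the number of features")
    X = table.to_numpy(float)
    names = np.array(table.columns)

    rankings: dict[str, list[str]] = {}

    lasso = LassoCV(cv=5, random_state=seed, max_iter=5000).fit(X, labels)
    rankings["lasso"] = _topk(names, np.abs(lasso.coef_), k)

    rfe = RFE(
        LogisticRegression(max_iter=2000, random_state=seed),
        n_features_to_select=k,
    ).fit(X, labels)
    rankings["rfe"] = list(names[rfe.support_])

    import xgboost as xgb

    booster = xgb.XGBClassifier(
        n_estimators=200,
        max_depth=3,
        random_state=seed,
        verbosity=0,
        eval_metric="logloss",
    ).fit(X, labels)
    rankings["xgboost"] = _topk(names, booster.feature_importances_, k)

    rf = RandomForestClassifier(n_estimators=500, random_state=seed).fit(X, labels)
    rankings["random_forest"] = _topk(names, rf.feature_importances_, k)

    votes: dict[str, int] = {}
    for sel in rankings.values():
        for name in sel:
            votes[name] = votes.get(name, 0) + 1
    selected = sorted([n for n, v in votes.items() if v >= min_votes])
    return selected, rankings


def _topk(names: np.ndarray, scores: np.ndarray, k: int) -> list[str]:
    order = np.argsort(-scores, kind="stable")
    return list(names[order[:k]])


def select_cytobands(
    matrix: pd.DataFrame, labels: np.ndarray, r_min: float = 0.1
) -> list[tuple[str, float]]:
    """Cytoband columns whose Pearson correlation with the binary class
    labels exceeds r_min in magnitude, ranked by descending |r|.
    Constant columns (correlation undefined) are excluded."""
    labels = np.asarray(labels, dtype=float)
    if len(labels) != len(matrix):
        raise ValueError("matrix rows must match labels")
    results = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(float)
        if np.std(x) == 0:
            logger.info("cytoband %s constant across cohort; excluded", col)
            continue
        r = float(np.corrcoef(x, labels)[0, 1])
        if abs(r) > r_min:
            results.append((col, r))
    results.sort(key=lambda t: -abs(t[1]))
    return results


@dataclass
class AssociationMap:
    """Radiomic x genomic Pearson correlation matrix with thresholded
    pair lists per cut-off."""

    matrix: pd.DataFrame
    pairs: dict[float, list[tuple[str, str, float]]] = field(default_factory=dict)


def cross_correlate(
    radiomic: pd.DataFrame,
    genomic: pd.DataFrame,
    cutoffs: tuple[float, ...] = (0.4, 0.55),
) -> AssociationMap:
    """Full Pearson correlation matrix between radiomic features (rows)
    and genomic cytoband features (columns), plus the feature pairs
    whose |r| exceeds each cut-off."""
    if len(radiomic) != len(genomic) or not (radiomic.index == genomic.index).all():
        raise ValueError("radiomic and genomic tables must share patients in order")
    r_arr = radiomic.to_numpy(float)
    g_arr = genomic.to_numpy(float)
    n = len(radiomic)
    r_c = r_arr - r_arr.mean(axis=0)
    g_c = g_arr - g_arr.mean(axis=0)
    r_sd = r_c.std(axis=0)
    g_sd = g_c.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (r_c.T @ g_c) / n / np.outer(r_sd, g_sd)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    matrix = pd.DataFrame(corr, index=radiomic.columns, columns=genomic.columns)
    amap = AssociationMap(matrix=matrix)
    for cut in cutoffs:
        pairs = [
            (rf, gf, float(matrix.loc[rf, gf]))
            for rf in matrix.index
            for gf in matrix.columns
            if abs(matrix.loc[rf, gf]) > cut
        ]
        pairs.sort(key=lambda t: -abs(t[2]))
        amap.pairs[cut] = pairs
    return amap
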