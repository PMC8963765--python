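"""Cluster validation: internal quality, partition agreement, stability,
and cross-algorithm state matching.

Internal quality uses the average silhouette coefficient and the Dunn index
under the cosine distance; agreement between partitions uses the Adjusted
Rand Index and the Variation of Information (natural log); stability uses a
10-fold protocol in which a nearest-prototype classifier transfers the
training partition onto held-out eigenvectors and is compared with a fresh
clustering of the same held-out set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import entropy
from sklearn.metrics import adjusted_rand_score, mutual_info_score, silhouette_samples
from sklearn.metrics.cluster import contingency_matrix
from sklearn.metrics.pairwise import cosine_distances
from sklearn.model_selection import KFold

from .clustering import cluster
from .datatypes import StateRepertoire

__all__ = [
    "silhouette_avg",
    "dunn_index",
    "ari",
    "vi",
    "kfold_stability",
    "match_states",
    "validation_report",
]


def _check_labels(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels must have one entry per pooled eigenvector")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 non-empty clusters")
    return labels


def silhouette_avg(pool: np.ndarray, repertoire: StateRepertoire | np.ndarray) -> float:
    """Average silhouette coefficient under the cosine distance.

    Points in singleton clusters contribute a silhouette of 0 (the standard
    convention for clusters whose intra distance is undefined).
    """
    x = np.asarray(pool, dtype=float)
    labels = repertoire.assignments if isinstance(repertoire, StateRepertoire) else repertoire
    labels = _check_labels(x, labels)
    s = silhouette_samples(x, labels, metric="cosine")
    _, counts = np.unique(labels, return_counts=True)
    singleton_labels = np.unique(labels)[counts == 1]
    if singleton_labels.size:
        s = s.copy()
        s[np.isin(labels, singleton_labels)] = 0.0
    return float(np.clip(s, -1.0, 1.0).mean())


def dunn_index(pool: np.ndarray, repertoire: StateRepertoire | np.ndarray) -> float:
    """Dunn index: minimum between-cluster distance (single linkage) over
    maximum within-cluster diameter, under the cosine distance.

    Returns ``inf`` when every cluster has zero diameter (all members
    identical) but the clusters are separated.
    """
    x = np.asarray(pool, dtype=float)
    labels = repertoire.assignments if isinstance(repertoire, StateRepertoire) else repertoire
    labels = _check_labels(x, labels)
    d = cosine_distances(x)
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(x.shape[0], dtype=bool)
    max_diam = float(d[same & off_diag].max()) if np.any(same & off_diag) else 0.0
    min_inter = float(d[~same].min())
    if max_diam == 0.0:
        return np.inf if min_inter > 0 else 0.0
    return min_inter / max_diam


def ari(p1, p2) -> float:
    """Adjusted Rand Index between two partitions of the same item set."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must cover the same item set")
    return float(adjusted_rand_score(p1, p2))


def vi(p1, p2) -> float:
    """Variation of Information, ``H(p1) + H(p2) - 2 I(p1, p2)``, in nats."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must cover the same item set")
    c = contingency_matrix(p1, p2)
    h1 = entropy(c.sum(axis=1))
    h2 = entropy(c.sum(axis=0))
    mi = mutual_info_score(None, None, contingency=c)
    return float(max(h1 + h2 - 2.0 * mi, 0.0))


def _agreement(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Fraction of items on which two labelings agree after optimal
    one-to-one label matching (Hungarian on the contingency table)."""
    c = contingency_matrix(p_a, p_b)
    r, cc = linear_sum_assignment(-c)
    return float(c[r, cc].sum() / p_a.size)


def kfold_stability(
    pool: np.ndarray,
    K: int,
    algorithm: str = "kmeans",
    folds: int = 10,
    n_restarts: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """K-fold clustering stability.

    Per fold: cluster the training sample (partition P1); assign each test
    eigenvector to the nearest P1 prototype under the cosine distance
    (class set P2); cluster the test sample independently (partition P3);
    report percent agreement (after optimal label matching), ARI and VI
    between P2 and P3.  A fold whose test sample has fewer than K distinct
    rows is marked failed.
    """
    x = np.asarray(pool, dtype=float)
    if x.shape[0] < 2 * folds:
        raise ValueError("pool too small for the requested number of folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(kf.split(x), start=1):
        x_tr, x_te = x[train_idx], x[test_idx]
        n_distinct = np.unique(x_te, axis=0).shape[0]
        if n_distinct < K:
            rows.append(
                {
                    "fold": fold,
                    "n_test": len(test_idx),
                    "agreement": np.nan,
                    "ari": np.nan,
                    "vi": np.nan,
                    "failed": True,
                }
            )
            continue
        rep1 = cluster(x_tr, K, algorithm=algorithm, n_restarts=n_restarts, seed=seed + fold)
        p2 = np.argmin(cosine_distances(x_te, rep1.prototypes), axis=1) + 1
        rep3 = cluster(x_te, K, algorithm=algorithm, n_restarts=n_restarts, seed=seed + fold)
        p3 = rep3.assignments
        rows.append(
            {
                "fold": fold,
                "n_test": len(test_idx),
                "agreement": _agreement(p2, p3),
                "ari": ari(p2, p3),
                "vi": vi(p2, p3),
                "failed": False,
            }
        )
    return pd.DataFrame(rows)


def match_states(
    r1: StateRepertoire, r2: StateRepertoire
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Pearson correlation between all prototype pairs plus the optimal
    one-to-one matching maximizing total correlation.

    Returns the ``(K1, K2)`` correlation matrix and matched 1-based state
    pairs ``(state in r1, state in r2)``.
    """
    if r1.n_regions != r2.n_regions:
        raise ValueError("repertoires have different region counts")
    k1 = r1.K
    corr = np.corrcoef(r1.prototypes, r2.prototypes)[:k1, k1:]
    rows, cols = linear_sum_assignment(-corr)
    pairs = [(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)]
    return corr, pairs


def validation_report(
    pool: np.ndarray, solutions: dict[int, StateRepertoire]
) -> pd.DataFrame:
    """Per-K silhouette and Dunn table for a sweep of clustering solutions."""
    rows = [
        {
            "K": k,
            "silhouette": silhouette_avg(pool, rep),
            "dunn": dunn_index(pool, rep),
        }
        for k, rep in sorted(solutions.items())
    ]
    return pd.DataFrame(rows)
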