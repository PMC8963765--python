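"""Cosine-distance K-means and K-medoids over pooled leading eigenvectors.

Recurrent phase-coherence states are the prototypes of a best-of-restarts
partition of the pooled eigenvectors under the cosine distance
``d(x, y) = 1 - x.y / (||x|| ||y||)``.  K-means updates each centroid as
the arithmetic mean of its members (the convention of the LEiDA
literature); K-medoids restricts prototypes to observed eigenvectors and
updates them by Voronoi iteration, with an optional PAM-style swap
refinement.  States are relabeled by decreasing occurrence, so state 1 is
always the most frequent pattern.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import cosine_distances

from .datatypes import StateRepertoire

__all__ = ["cluster", "sweep_K"]

_MAX_ITER = 300


def _distinct_row_indices(x: np.ndarray) -> np.ndarray:
    """Index of the first occurrence of each distinct row."""
    _, idx = np.unique(x, axis=0, return_index=True)
    return np.sort(idx)


def _fix_empty(labels, d_to_proto, prototypes, x, empty_clusters):
    """Re-seat each empty prototype at the point farthest from its current
    prototype; deterministic given the assignment."""
    for k in empty_clusters:
        dist_to_own = d_to_proto[np.arange(x.shape[0]), labels]
        far = int(np.argmax(dist_to_own))
        prototypes[k] = x[far]
        labels[far] = k
    return labels, prototypes


def _kmeans_once(x, k, init_idx):
    c = x[init_idx].copy()
    labels = np.full(x.shape[0], -1)
    for _ in range(_MAX_ITER):
        d = cosine_distances(x, c)
        new_labels = np.argmin(d, axis=1)
        empty = [j for j in range(k) if not np.any(new_labels == j)]
        if empty:
            new_labels, c = _fix_empty(new_labels, d, c, x, empty)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            c[j] = x[labels == j].mean(axis=0)
    d = cosine_distances(x, c)
    labels = np.argmin(d, axis=1)
    if len(np.unique(labels)) < k:
        return None
    obj = float(d[np.arange(x.shape[0]), labels].sum())
    return labels, c, obj


def _kmedoids_once(x, k, init_idx, pam_refine=False):
    med_idx = np.array(init_idx)
    labels = np.full(x.shape[0], -1)
    for _ in range(_MAX_ITER):
        d = cosine_distances(x, x[med_idx])
        new_labels = np.argmin(d, axis=1)
        empty = [j for j in range(k) if not np.any(new_labels == j)]
        for j in empty:
            dist_to_own = d[np.arange(x.shape[0]), new_labels]
            far = int(np.argmax(dist_to_own))
            med_idx[j] = far
            new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = np.flatnonzero(labels == j)
            dm = cosine_distances(x[members], x[members])
            med_idx[j] = members[int(np.argmin(dm.sum(axis=1)))]
    d = cosine_distances(x, x[med_idx])
    labels = np.argmin(d, axis=1)
    obj = float(d[np.arange(x.shape[0]), labels].sum())
    if pam_refine:
        labels, med_idx, obj = _pam_swap(x, med_idx, labels, obj)
    if len(np.unique(labels)) < k:
        return None
    return labels, x[med_idx].copy(), obj


def _pam_swap(x, med_idx, labels, obj):
    """Greedy best-swap refinement: repeatedly replace one medoid by the
    non-medoid that most reduces the total cosine distance."""
    n = x.shape[0]
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for j in range(med_idx.size):
            candidates = np.flatnonzero(labels == j)
            for o in candidates:
                if o in med_idx:
                    continue
                trial = med_idx.copy()
                trial[j] = o
                d = cosine_distances(x, x[trial])
                trial_obj = float(d.min(axis=1).sum())
                gain = obj - trial_obj
                if gain > best[0] + 1e-12:
                    best = (gain, j, o)
        if best[1] is not None:
            _, j, o = best
            med_idx[j] = o
            d = cosine_distances(x, x[med_idx])
            labels = np.argmin(d, axis=1)
            obj = float(d[np.arange(n), labels].sum())
            improved = True
    return labels, med_idx, obj


def _rank_states(labels0, prototypes, k):
    """Relabel clusters by decreasing occurrence (stable on ties)."""
    counts = np.bincount(labels0, minlength=k)
    order = np.argsort(-counts, kind="stable")
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    assignments = rank_of[labels0] + 1  # 1-based state labels
    return assignments, prototypes[order], counts[order]


def cluster(
    pool: np.ndarray,
    K: int,
    algorithm: str = "kmeans",
    n_restarts: int = 1000,
    seed: int = 0,
    pam_refine: bool = False,
) -> StateRepertoire:
    """Best-of-restarts partition of pooled eigenvectors into K states.

    Each restart initializes prototypes at K distinct pooled rows drawn from
    a seeded substream; the solution with the smallest total cosine distance
    wins (ties broken by restart order, so a fixed seed fixes the output).
    Restarts that converge with an empty cluster are discarded; an error is
    raised only if every restart degenerates.
    """
    x = np.asarray(pool, dtype=float)
    if x.ndim != 2:
        raise ValueError("pool must be 2-D (eigenvectors x regions)")
    if K < 2:
        raise ValueError("K must be >= 2")
    if algorithm not in ("kmeans", "kmedoids"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    distinct = _distinct_row_indices(x)
    if K > distinct.size:
        raise ValueError(
            f"K={K} exceeds the {distinct.size} distinct rows in the pool"
        )
    ss = np.random.SeedSequence(seed)
    best = None
    for r, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        init_idx = rng.choice(distinct, size=K, replace=False)
        if algorithm == "kmeans":
            res = _kmeans_once(x, K, init_idx)
        else:
            res = _kmedoids_once(x, K, init_idx, pam_refine=pam_refine)
        if res is None:
            continue
        labels, protos, obj = res
        if best is None or obj < best[2] - 1e-12:
            best = (labels, protos, obj)
    if best is None:
        raise RuntimeError("all restarts converged to degenerate partitions")
    labels, protos, obj = best
    assignments, prototypes, counts = _rank_states(labels, protos, K)
    return StateRepertoire(
        K=K,
        prototypes=prototypes,
        assignments=assignments,
        counts=counts,
        algorithm=algorithm,
        distance="cosine",
        n_restarts=n_restarts,
        seed=seed,
        objective=obj,
    )


def sweep_K(
    pool: np.ndarray,
    K_range=range(2, 21),
    algorithm: str = "kmeans",
    n_restarts: int = 1000,
    seed: int = 0,
    **kwargs,
) -> dict[int, StateRepertoire]:
    """One ranked clustering solution per K (default K = 2..20)."""
    solutions: dict[int, StateRepertoire] = {}
    for k in K_range:
        solutions[k] = cluster(
            pool, k, algorithm=algorithm, n_restarts=n_restarts, seed=seed, **kwargs
        )
    return solutions
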