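"""Instantaneous phase extraction and the leading-eigenvector reduction.

Each regional time course is demeaned and converted to its analytic
representation by the Hilbert transform; the phase difference between every
pair of regions at a retained volume defines the cosine phase-coherence
matrix ``dFC(n, p, t) = cos(theta(n, t) - theta(p, t))``.  That matrix
equals ``cos(theta) cos(theta)^T + sin(theta) sin(theta)^T`` and is hence
positive semidefinite of rank <= 2 with trace N, which forces its leading
eigenvalue to capture at least half of the total variance.  The first and
last volume of each scan are dropped because the discrete Hilbert transform
distorts the signal at the edges.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert

from .datatypes import EigenSeries, ParcellatedScan

__all__ = [
    "compute_phases",
    "coherence_at",
    "leading_eigenvector",
    "eigenseries",
    "pool_eigenvectors",
]

#: eigenvalue gap below which the leading eigenvector is considered degenerate
DEGENERACY_TOL = 1e-12


def compute_phases(scan: ParcellatedScan) -> np.ndarray:
    """Instantaneous phase (radians) of each region's analytic signal.

    The regional time course is demeaned before the Hilbert transform (the
    analytic-signal phase is only meaningful for zero-mean signals).  All T
    columns are returned; edge trimming happens in :func:`eigenseries`.

    Raises
    ------
    ValueError
        If a region has a constant (zero-variance) time course, for which
        no phase is defined.
    """
    x = scan.signal - scan.signal.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"region(s) {bad.tolist()} have constant signal; phase undefined"
        )
    analytic = hilbert(x, axis=1)
    return np.angle(analytic)


def coherence_at(theta: np.ndarray, t: int) -> np.ndarray:
    """Cosine phase-coherence matrix at retained volume ``t`` (0-based).

    ``t`` must lie in the retained range ``1 .. T-2``; the first and last
    volumes are excluded because of Hilbert edge distortion.
    """
    theta = np.asarray(theta, dtype=float)
    n, T = theta.shape
    if not 1 <= t <= T - 2:
        raise IndexError(
            f"volume {t} outside the retained range 1..{T - 2} (0-based)"
        )
    col = theta[:, t]
    return np.cos(col[:, None] - col[None, :])


def _orient(v: np.ndarray) -> np.ndarray:
    """Apply the sign convention: at most N/2 strictly positive elements.

    Zeros count as non-positive (assigned to the global community).  At an
    exact N/2 tie the vector is oriented so its largest-magnitude element
    (first occurrence on further ties) is non-positive.
    """
    n = v.size
    npos = int(np.count_nonzero(v > 0))
    if 2 * npos > n:
        return -v
    if 2 * npos == n:
        i = int(np.argmax(np.abs(v)))
        if v[i] > 0:
            return -v
    return v


def leading_eigenvector(m: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector and variance explained of a coherence matrix.

    Returns a unit-norm eigenvector of the largest eigenvalue, oriented by
    the sign convention of :func:`_orient`, and
    ``variance_explained = lambda_1 / trace(m)``.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("coherence matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("coherence matrix must be symmetric")
    w, v = np.linalg.eigh(m)
    lam1 = w[-1]
    if m.shape[0] > 1 and lam1 - w[-2] < DEGENERACY_TOL:
        warnings.warn(
            "degenerate leading eigenvalue; orientation chosen by sign convention",
            RuntimeWarning,
            stacklevel=2,
        )
    vec = _orient(v[:, -1])
    trace = np.trace(m)
    return vec, float(lam1 / trace)


def eigenseries(scan: ParcellatedScan) -> EigenSeries:
    """LEiDA reduction of one scan: one oriented leading eigenvector (and
    its variance explained) per retained volume, in temporal order.

    ``T' = T - 2`` vectors are produced (first/last volume dropped).
    """
    theta = compute_phases(scan)
    T = scan.n_volumes
    retained = np.arange(1, T - 1)
    vectors = np.empty((retained.size, scan.n_regions))
    varexp = np.empty(retained.size)
    for i, t in enumerate(retained):
        vec, ve = leading_eigenvector(coherence_at(theta, t))
        vectors[i] = vec
        varexp[i] = ve
    return EigenSeries(
        vectors=vectors,
        variance_explained=varexp,
        retained_volumes=retained,
        subject_id=scan.subject_id,
        group=scan.group,
        tr=scan.tr,
    )


def pool_eigenvectors(
    series: list[EigenSeries],
) -> tuple[np.ndarray, "pd.DataFrame"]:
    """Stack per-scan eigenvectors into one pooled matrix.

    Returns the ``(sum T'_s, N)`` pooled matrix and a metadata table with
    one row per pooled eigenvector (``subject_id, group, volume``).
    """
    import pandas as pd

    if not series:
        raise ValueError("no eigen-series to pool")
    n = series[0].vectors.shape[1]
    for es in series:
        if es.vectors.shape[1] != n:
            raise ValueError("inconsistent region count across scans")
    x = np.vstack([es.vectors for es in series])
    meta = pd.DataFrame(
        {
            "subject_id": np.concatenate(
                [[es.subject_id] * es.n_retained for es in series]
            ),
            "group": np.concatenate([[es.group] * es.n_retained for es in series]),
            "volume": np.concatenate([es.retained_volumes for es in series]),
        }
    )
    return x, meta
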