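"""Core containers shared across the pipeline.

All state labels are 1-based (state 1 is the most frequently occupied state
after ranking), matching the convention of the dynamic functional
connectivity literature.  Volume indices are 0-based Python indices into the
scan; the retained range after edge trimming is ``1 .. T-2`` inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcellatedScan",
    "EigenSeries",
    "StateRepertoire",
    "StateTrajectory",
    "DynamicsSummary",
    "TransitionModel",
    "GroupComparison",
]


@dataclass
class ParcellatedScan:
    """One subject's regions-by-volumes BOLD signal matrix.

    Parameters
    ----------
    signal
        ``(N, T)`` array, region ``n`` by volume ``t``.
    tr
        Repetition time in seconds (sampling interval between volumes).
    subject_id, group
        Cohort bookkeeping labels.
    """

    signal: np.ndarray
    tr: float
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D regions x volumes matrix")
        n, t = self.signal.shape
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if t < 3:
            raise ValueError(f"need at least 3 volumes, got {t}")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains missing/non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_regions(self) -> int:
        return self.signal.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]


@dataclass
class EigenSeries:
    """Per-scan sequence of leading eigenvectors of phase-coherence matrices.

    ``vectors`` is ``(T', N)`` with ``T' = T - 2`` (first and last volume
    dropped); each row is unit-norm and oriented so that at most ``N/2``
    elements are strictly positive.  ``variance_explained`` is
    ``lambda_1 / trace`` per retained volume and is analytically >= 1/2 for
    cosine phase-coherence matrices (rank-2 positive semidefinite).
    """

    vectors: np.ndarray
    variance_explained: np.ndarray
    retained_volumes: np.ndarray
    subject_id: str
    group: str
    tr: float

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        self.retained_volumes = np.asarray(self.retained_volumes, dtype=int)
        tprime = self.vectors.shape[0]
        if self.variance_explained.shape != (tprime,):
            raise ValueError("variance_explained length mismatch")
        if self.retained_volumes.shape != (tprime,):
            raise ValueError("retained_volumes length mismatch")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("eigenvectors must be unit-norm")
        if np.any(self.variance_explained < 0.5 - 1e-9):
            raise ValueError("variance explained below the rank-2 bound of 1/2")

    @property
    def n_retained(self) -> int:
        return self.vectors.shape[0]


@dataclass
class StateRepertoire:
    """A clustering solution over pooled leading eigenvectors.

    States are ranked by decreasing occurrence: state 1 holds the largest
    number of assigned eigenvectors.  ``prototypes[k - 1]`` is the centroid
    (K-means) or medoid (K-medoids) of state ``k``; ``assignments`` holds a
    1-based state label per pooled eigenvector.
    """

    K: int
    prototypes: np.ndarray
    assignments: np.ndarray
    counts: np.ndarray
    algorithm: str
    distance: str
    n_restarts: int
    seed: int
    objective: float

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.prototypes.shape[0] != self.K:
            raise ValueError("prototype count must equal K")
        if self.counts.shape != (self.K,):
            raise ValueError("counts must have length K")
        if self.assignments.min(initial=1) < 1 or self.assignments.max(initial=1) > self.K:
            raise ValueError("assignments must lie in 1..K")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("states must be ranked by non-increasing occurrence")

    @property
    def n_regions(self) -> int:
        return self.prototypes.shape[1]


@dataclass
class StateTrajectory:
    """Per-scan categorical sequence over states ``1..K``; the discrete-time
    Markov-chain realization all dynamics measures are computed from."""

    states: np.ndarray
    subject_id: str
    group: str
    tr: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("states must be a non-empty 1-D sequence")
        if self.states.min() < 1:
            raise ValueError("state labels are 1-based")

    def __len__(self) -> int:
        return self.states.size


@dataclass
class DynamicsSummary:
    """Per-scan occupancy and dwell-time summary.

    Dwell times are NaN for states never visited during the scan.
    """

    subject_id: str
    group: str
    K: int
    fractional_occupancy: np.ndarray
    dwell_time_trs: np.ndarray
    dwell_time_seconds: np.ndarray
    n_runs: np.ndarray


@dataclass
class TransitionModel:
    """Transition structure of one scan's state trajectory.

    ``joint[a-1, b-1]`` is the probability of observing the ordered pair
    ``(a, b)`` among the ``T'-1`` consecutive pairs; ``conditional`` is the
    row-stochastic transition probability matrix (rows NaN for states never
    observed as a transition source).  ``limiting`` is the stationary
    distribution, present only when the chain restricted to visited states is
    irreducible and aperiodic and covers all K states; otherwise
    ``exclusion_reason`` says why.
    """

    K: int
    counts: np.ndarray
    joint: np.ndarray
    conditional: np.ndarray
    irreducible: bool
    aperiodic: bool
    limiting: np.ndarray | None
    exclusion_reason: str | None
    subject_id: str = ""
    group: str = ""

    @property
    def included_in_limiting(self) -> bool:
        return self.limiting is not None


@dataclass
class GroupComparison:
    """Result of one two-group permutation comparison."""

    statistic: float
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    pooled_sd: float
    n1: int
    n2: int
    levene_p: float
    variance_assumption: str
    p_value: float
    hedges_g: float
    alternative: str
    B: int
    flags: dict = field(default_factory=dict)
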