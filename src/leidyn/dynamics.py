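"""Markov-chain characterization of per-scan state trajectories.

A scan's sequence of leading eigenvectors, mapped to its nearest state
prototypes, defines a realization of a finite discrete-time Markov chain
over states 1..K.  This module computes the occupancy and dwell-time
statistics of that realization, estimates its transition structure, screens
the chain for irreducibility and aperiodicity, and computes the stationary
(limiting) distribution where the screen passes.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from sklearn.metrics.pairwise import cosine_distances

from .datatypes import (
    DynamicsSummary,
    EigenSeries,
    StateRepertoire,
    StateTrajectory,
    TransitionModel,
)

__all__ = [
    "assign_trajectory",
    "fractional_occupancy",
    "dwell_time",
    "transition_model",
    "chain_class",
    "limiting_distribution",
    "dynamics_summary",
    "measures_table",
    "transitions_table",
    "chain_diagnostics_table",
]

STATIONARITY_TOL = 1e-10
ROW_SUM_TOL = 1e-12


def assign_trajectory(es: EigenSeries, repertoire: StateRepertoire) -> StateTrajectory:
    """Map each eigenvector to the nearest prototype under the clustering
    distance; equidistant ties go to the lowest-ranked (most frequent)
    state."""
    if es.vectors.shape[1] != repertoire.n_regions:
        raise ValueError("region count mismatch between eigen-series and repertoire")
    d = cosine_distances(es.vectors, repertoire.prototypes)
    states = np.argmin(d, axis=1) + 1  # argmin takes the first minimum: lowest rank
    return StateTrajectory(states, es.subject_id, es.group, es.tr)


def fractional_occupancy(tr: StateTrajectory, K: int) -> np.ndarray:
    """Fraction of retained volumes spent in each state (sums to 1)."""
    counts = np.bincount(tr.states, minlength=K + 1)[1:]
    return counts / len(tr)


def _runs(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encoding: (state of each maximal run, its length)."""
    change = np.flatnonzero(np.diff(states) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [states.size - 1]))
    return states[starts], ends - starts + 1


def dwell_time(tr: StateTrajectory, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean maximal-run length per state, in TRs and in seconds.

    Runs truncated by the scan boundaries count fully.  States never
    visited get NaN dwell time and a run count of 0.  Returns
    ``(dwell_trs, dwell_seconds, n_runs)``.
    """
    run_states, run_lengths = _runs(tr.states)
    dt = np.full(K, np.nan)
    n_runs = np.zeros(K, dtype=int)
    for a in range(1, K + 1):
        sel = run_states == a
        n_runs[a - 1] = sel.sum()
        if n_runs[a - 1]:
            dt[a - 1] = run_lengths[sel].mean()
    return dt, dt * tr.tr, n_runs


def dynamics_summary(tr: StateTrajectory, K: int) -> DynamicsSummary:
    """Fractional occupancy, dwell times and run counts of one scan."""
    fo = fractional_occupancy(tr, K)
    dt_trs, dt_s, n_runs = dwell_time(tr, K)
    return DynamicsSummary(
        subject_id=tr.subject_id,
        group=tr.group,
        K=K,
        fractional_occupancy=fo,
        dwell_time_trs=dt_trs,
        dwell_time_seconds=dt_s,
        n_runs=n_runs,
    )


def chain_class(
    conditional: np.ndarray, visited: np.ndarray | None = None
) -> tuple[bool, bool]:
    """Irreducibility and aperiodicity of the chain restricted to visited
    states.

    Irreducible iff the directed graph of strictly positive transitions
    among visited states is strongly connected.  Aperiodic iff every
    recurrent class (strongly connected component without outgoing edges)
    has period 1.
    """
    p = np.asarray(conditional, dtype=float)
    k = p.shape[0]
    if visited is None:
        visited = np.flatnonzero(~np.all(np.isnan(p), axis=1))
    else:
        visited = np.asarray(visited, dtype=int)
    if visited.size == 0:
        raise ValueError("chain has no defined transition rows")
    g = nx.DiGraph()
    g.add_nodes_from(visited.tolist())
    sub = p[np.ix_(visited, visited)]
    src, dst = np.nonzero(np.nan_to_num(sub) > 0)
    g.add_edges_from(zip(visited[src].tolist(), visited[dst].tolist()))
    irreducible = visited.size == 1 and g.has_edge(visited[0], visited[0]) or (
        visited.size > 1 and nx.is_strongly_connected(g)
    )
    cond = nx.condensation(g)
    aperiodic = True
    for scc_id in cond.nodes:
        if cond.out_degree(scc_id) > 0:
            continue  # transient class
        members = cond.nodes[scc_id]["members"]
        sg = g.subgraph(members)
        if sg.number_of_edges() == 0 or not nx.is_aperiodic(sg):
            aperiodic = False
    return bool(irreducible), bool(aperiodic)


def limiting_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible aperiodic row-stochastic
    matrix, via ``pi = 1 (I - P + ONE)^-1``.

    The result is validated to be strictly positive, sum to 1, and satisfy
    ``pi P = pi`` within 1e-10.
    """
    p = np.asarray(p, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k):
        raise ValueError("TPM must be square")
    if np.any(np.isnan(p)):
        raise ValueError("TPM has undefined rows; chain does not cover the state space")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("TPM rows must sum to 1")
    a = np.eye(k) - p + np.ones((k, k))
    pi = np.linalg.solve(a.T, np.ones(k))
    if np.any(pi <= 0):
        raise ValueError("stationary distribution not strictly positive (chain not ergodic?)")
    if abs(pi.sum() - 1.0) > 1e-8 or np.max(np.abs(pi @ p - pi)) > STATIONARITY_TOL:
        raise ValueError("stationary solve failed its consistency checks")
    return pi


def transition_model(
    tr: StateTrajectory, K: int, conditional_mode: str = "counts"
) -> TransitionModel:
    """Estimate the transition structure of one trajectory.

    ``counts[a-1, b-1]`` tallies the ordered pairs ``(a, b)`` among the
    ``T'-1`` consecutive pairs; ``joint = counts / (T'-1)``.  The
    row-stochastic conditional matrix is, by default, the row-normalized
    count matrix (rows NaN for states never observed as a source).
    ``conditional_mode="quotient"`` instead forms the literal quotient of
    the joint probability by the fractional occupancy of the source state;
    its rows do not sum exactly to 1 because the joint and the occupancy
    are normalized by T'-1 and T' respectively, so it is provided for
    comparison only.

    The stationary distribution is attached only when all K states occur as
    transition sources and the chain is irreducible and aperiodic;
    otherwise ``exclusion_reason`` records why.
    """
    if len(tr) < 2:
        raise ValueError("need at least 2 retained volumes to estimate transitions")
    s = tr.states
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
    n_pairs = len(tr) - 1
    joint = counts / n_pairs

    row_sums = counts.sum(axis=1)
    conditional = np.full((K, K), np.nan)
    defined = row_sums > 0
    if conditional_mode == "counts":
        conditional[defined] = counts[defined] / row_sums[defined, None]
    elif conditional_mode == "quotient":
        fo = fractional_occupancy(tr, K)
        conditional[defined] = joint[defined] / fo[defined, None]
    else:
        raise ValueError(f"unknown conditional_mode {conditional_mode!r}")

    irreducible, aperiodic = chain_class(conditional, visited=np.flatnonzero(defined))
    limiting = None
    reason = None
    if not defined.all():
        reason = "trajectory does not span the state space"
    elif not irreducible:
        reason = "chain not irreducible"
    elif not aperiodic:
        reason = "chain not aperiodic"
    else:
        row_norm = counts / row_sums[:, None]
        limiting = limiting_distribution(row_norm)
    return TransitionModel(
        K=K,
        counts=counts,
        joint=joint,
        conditional=conditional,
        irreducible=irreducible,
        aperiodic=aperiodic,
        limiting=limiting,
        exclusion_reason=reason,
        subject_id=tr.subject_id,
        group=tr.group,
    )


def measures_table(trajectories: list[StateTrajectory], K: int) -> pd.DataFrame:
    """Tidy per-scan, per-state measures table.

    Columns: ``subject_id, group, state, fo, dt_trs, dt_s, n_runs``.
    """
    rows = []
    for tr in trajectories:
        summ = dynamics_summary(tr, K)
        for a in range(1, K + 1):
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "group": tr.group,
                    "state": a,
                    "fo": summ.fractional_occupancy[a - 1],
                    "dt_trs": summ.dwell_time_trs[a - 1],
                    "dt_s": summ.dwell_time_seconds[a - 1],
                    "n_runs": summ.n_runs[a - 1],
                }
            )
    return pd.DataFrame(rows)


def transitions_table(
    models: list[TransitionModel],
) -> pd.DataFrame:
    """Tidy per-scan conditional transition probabilities.

    One row per (scan, ordered state pair); probability is NaN for scans in
    which the source state never occurs.
    """
    rows = []
    for tm in models:
        for a in range(1, tm.K + 1):
            for b in range(1, tm.K + 1):
                rows.append(
                    {
                        "subject_id": tm.subject_id,
                        "group": tm.group,
                        "from_state": a,
                        "to_state": b,
                        "prob": tm.conditional[a - 1, b - 1],
                    }
                )
    return pd.DataFrame(rows)


def chain_diagnostics_table(models: list[TransitionModel]) -> pd.DataFrame:
    """Per-scan chain screening: irreducibility, aperiodicity, inclusion in
    the limiting-probability analysis, plus limiting probabilities where
    defined."""
    rows = []
    for tm in models:
        row = {
            "subject_id": tm.subject_id,
            "group": tm.group,
            "irreducible": tm.irreducible,
            "aperiodic": tm.aperiodic,
            "included_in_limiting": tm.included_in_limiting,
            "exclusion_reason": tm.exclusion_reason or "",
        }
        for a in range(1, tm.K + 1):
            row[f"pi_{a}"] = tm.limiting[a - 1] if tm.limiting is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
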