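"""State trajectories and their Markov-chain statistics."""

import numpy as np
import pytest

import leidyn as ld
from leidyn.datatypes import StateTrajectory


def traj(states, tr=2.0, group="A"):
    return StateTrajectory(np.asarray(states), "sub-x", group, tr)


# --------------------------------------------------------- assignment

def test_prototype_maps_to_its_own_state(small_eigenseries):
    pool, _ = ld.pool_eigenvectors(small_eigenseries)
    rep = ld.cluster(pool, 3, n_restarts=5, seed=0)
    for a in (1, 2, 3):
        es = small_eigenseries[0]
        es_proto = ld.EigenSeries(
            vectors=np.tile(rep.prototypes[a - 1] / np.linalg.norm(rep.prototypes[a - 1]), (3, 1)),
            variance_explained=np.full(3, 0.9),
            retained_volumes=np.arange(1, 4),
            subject_id="p", group="A", tr=2.0,
        )
        assert set(ld.assign_trajectory(es_proto, rep).states) == {a}


def test_trajectories_reproduce_pooled_assignments(small_eigenseries):
    pool, meta = ld.pool_eigenvectors(small_eigenseries)
    rep = ld.cluster(pool, 4, n_restarts=5, seed=1)
    got = np.concatenate(
        [ld.assign_trajectory(es, rep).states for es in small_eigenseries]
    )
    np.testing.assert_array_equal(got, rep.assignments)


def test_equidistant_tie_goes_to_lowest_ranked_state():
    rep = ld.StateRepertoire(
        K=2,
        prototypes=np.array([[1.0, 0.0], [0.0, 1.0]]),
        assignments=np.array([1, 1, 2]),
        counts=np.array([2, 1]),
        algorithm="kmeans", distance="cosine", n_restarts=1, seed=0,
        objective=0.0,
    )
    v = np.array([1.0, 1.0]) / np.sqrt(2)  # equidistant from both prototypes
    es = ld.EigenSeries(
        vectors=v[None, :], variance_explained=[0.9], retained_volumes=[1],
        subject_id="t", group="A", tr=2.0,
    )
    assert ld.assign_trajectory(es, rep).states[0] == 1


# ------------------------------------------------- occupancy and dwell

def test_fractional_occupancy_hand_example():
    np.testing.assert_allclose(
        ld.fractional_occupancy(traj([1, 1, 2, 2, 2, 1]), 2), [0.5, 0.5]
    )


def test_fractional_occupancy_constant_and_sum(rng):
    assert ld.fractional_occupancy(traj([2] * 7), 3).tolist() == [0, 1, 0]
    s = rng.integers(1, 5, size=40)
    assert ld.fractional_occupancy(traj(s), 4).sum() == pytest.approx(1.0)


def test_dwell_time_hand_example():
    dt_trs, dt_s, n_runs = ld.dwell_time(traj([1, 1, 2, 2, 2, 1]), 2)
    np.testing.assert_allclose(dt_trs, [1.5, 3.0])
    np.testing.assert_allclose(dt_s, [3.0, 6.0])  # TR = 2 s
    assert n_runs.tolist() == [2, 1]


def test_dwell_time_constant_trajectory():
    dt_trs, _, n_runs = ld.dwell_time(traj([1] * 9), 2)
    assert dt_trs[0] == 9
    assert np.isnan(dt_trs[1]) and n_runs[1] == 0


def test_time_conservation(rng):
    """sum over states of (number of runs x mean dwell) equals T'."""
    s = rng.integers(1, 4, size=57)
    dt_trs, _, n_runs = ld.dwell_time(traj(s), 3)
    total = np.nansum(np.where(n_runs > 0, n_runs * dt_trs, 0.0))
    assert total == pytest.approx(57)


# ------------------------------------------------------- transitions

def test_transition_model_hand_example():
    tm = ld.transition_model(traj([1, 1, 2, 2, 2, 1]), 2)
    np.testing.assert_array_equal(tm.counts, [[1, 1], [1, 2]])
    np.testing.assert_allclose(tm.joint, [[0.2, 0.2], [0.2, 0.4]])
    np.testing.assert_allclose(tm.conditional, [[0.5, 0.5], [1 / 3, 2 / 3]])
    assert tm.irreducible and tm.aperiodic
    assert tm.joint.sum() == pytest.approx(1.0)


def test_constant_trajectory_has_one_defined_row():
    tm = ld.transition_model(traj([2, 2, 2, 2]), 3)
    assert np.isnan(tm.conditional[0]).all() and np.isnan(tm.conditional[2]).all()
    np.testing.assert_allclose(tm.conditional[1], [0, 1, 0])
    assert tm.exclusion_reason == "trajectory does not span the state space"


def test_quotient_mode_rows_do_not_sum_to_one():
    tm = ld.transition_model(traj([1, 1, 2, 2, 2, 1]), 2,
                             conditional_mode="quotient")
    sums = np.nansum(tm.conditional, axis=1)
    # state 2 never ends the scan: its row inflates by T'/(T'-1)
    assert sums[1] == pytest.approx(6 / 5)
    # state 1 occupies the final volume: (T'/(T'-1)) * (n-1)/n deflation
    assert sums[0] == pytest.approx(0.8)
    assert not np.allclose(sums, 1.0)


def test_chain_class_examples():
    assert ld.chain_class(np.array([[0.5, 0.5], [1 / 3, 2 / 3]])) == (True, True)
    assert ld.chain_class(np.array([[0.0, 1.0], [1.0, 0.0]])) == (True, False)
    tm = ld.transition_model(traj([1, 1, 2, 2]), 2)
    assert not tm.irreducible  # state 2 absorbing within the observed window


def test_limiting_two_state_closed_form():
    pi = ld.limiting_distribution(np.array([[0.9, 0.1], [0.2, 0.8]]))
    np.testing.assert_allclose(pi, [2 / 3, 1 / 3], atol=1e-12)


def test_limiting_doubly_stochastic_uniform(rng):
    # random doubly stochastic matrix by symmetrizing a stochastic one
    p = np.array([[0.5, 0.3, 0.2], [0.3, 0.4, 0.3], [0.2, 0.3, 0.5]])
    np.testing.assert_allclose(ld.limiting_distribution(p), np.ones(3) / 3,
                               atol=1e-12)


def test_limiting_matches_power_iteration(rng):
    for _ in range(5):
        p = rng.dirichlet(np.ones(5) * 2, size=5) + 1e-3
        p /= p.sum(axis=1, keepdims=True)
        pi = ld.limiting_distribution(p)
        pk = np.linalg.matrix_power(p, 200)
        np.testing.assert_allclose(pi, pk[0], atol=1e-8)
        np.testing.assert_allclose(pi @ p, pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)


def test_limiting_rejects_undefined_rows():
    with pytest.raises(ValueError, match="undefined"):
        ld.limiting_distribution(np.array([[0.5, 0.5], [np.nan, np.nan]]))


def test_per_scan_tpm_recovers_generating_chain():
    """Mean of per-scan hidden-trajectory TPMs approaches the generating
    group TPM within 3 standard errors for long scans."""
    spec = ld.two_state_cohort_spec(n_per_group=(25, 0), T=1000, N=4,
                                    community_size=2, seed=42)
    _, truth, _ = ld.generate_cohort(spec)
    true_tpm = spec.group_tpms["A"]
    conds = []
    for st in truth.scans:
        tm = ld.transition_model(traj(st.hidden_states), 2)
        conds.append(tm.conditional)
    conds = np.array(conds)
    mean = conds.mean(axis=0)
    se = conds.std(axis=0, ddof=1) / np.sqrt(len(conds))
    assert np.all(np.abs(mean - true_tpm) < 3 * se + 1e-9)


def test_measures_and_diagnostics_tables(small_eigenseries):
    pool, _ = ld.pool_eigenvectors(small_eigenseries)
    rep = ld.cluster(pool, 3, n_restarts=5, seed=0)
    trajs = [ld.assign_trajectory(es, rep) for es in small_eigenseries]
    mt = ld.measures_table(trajs, 3)
    assert len(mt) == 3 * len(trajs)
    fo_sums = mt.groupby("subject_id")["fo"].sum()
    np.testing.assert_allclose(fo_sums, 1.0)
    models = [ld.transition_model(t, 3) for t in trajs]
    tt = ld.transitions_table(models)
    assert len(tt) == 9 * len(trajs)
    diag = ld.chain_diagnostics_table(models)
    assert len(diag) == len(trajs)
    included = diag["included_in_limiting"]
    pis = diag.loc[included, [f"pi_{a}" for a in (1, 2, 3)]].to_numpy()
    if pis.size:
        np.testing.assert_allclose(pis.sum(axis=1), 1.0)
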