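"""Markov-chain statistics of one scan's state trajectory.

Assigns a scan's eigenvectors to the nearest state prototypes and
summarizes the resulting trajectory: fractional occupancy, dwell times,
the transition probability matrix, and the chain's limiting distribution
when it is irreducible and aperiodic.
"""

import numpy as np

import leidyn as ld

spec = ld.default_cohort_spec(n_per_group=(6, 6), seed=3)
scans, _, _ = ld.generate_cohort(spec)
series = [ld.eigenseries(s) for s in scans]
pool, _ = ld.pool_eigenvectors(series)
rep = ld.cluster(pool, K=3, n_restarts=50, seed=0)

traj = ld.assign_trajectory(series[0], rep)
K = rep.K
print(f"trajectory of {traj.subject_id}: first 20 states {traj.states[:20].tolist()}")
print(f"fractional occupancy: {np.round(ld.fractional_occupancy(traj, K), 3)}")
dt_trs, dt_s, n_runs = ld.dwell_time(traj, K)
print(f"dwell time (s): {np.round(dt_s, 2)}  over {n_runs.tolist()} visits")

tm = ld.transition_model(traj, K)
print(f"transition matrix:\n{np.round(tm.conditional, 3)}")
if tm.limiting is not None:
    print(f"chain irreducible and aperiodic; limiting distribution "
          f"{np.round(tm.limiting, 3)}")
else:
    print(f"limiting distribution excluded: {tm.exclusion_reason}")
# The limiting distribution is the long-run fraction of time the chain
# spends in each state; it is only defined for ergodic trajectories, and
# short scans often fail the screen by never visiting some state.
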