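"""Recurrent coherence states by cosine-distance clustering.

Pools the eigenvectors of a small cohort, clusters them with K-means and
K-medoids, checks partition quality (silhouette, Dunn) and shows that the
two algorithms find essentially the same states.
"""

import leidyn as ld

spec = ld.default_cohort_spec(n_per_group=(6, 6), seed=3)
scans, _, _ = ld.generate_cohort(spec)
pool, meta = ld.pool_eigenvectors([ld.eigenseries(s) for s in scans])
print(f"pooled {pool.shape[0]} eigenvectors of dimension {pool.shape[1]}")

km = ld.cluster(pool, K=3, algorithm="kmeans", n_restarts=50, seed=0)
kmed = ld.cluster(pool, K=3, algorithm="kmedoids", n_restarts=50, seed=0)
print(f"K-means state sizes:   {km.counts.tolist()} (state 1 is the most frequent)")
print(f"K-medoids state sizes: {kmed.counts.tolist()}")

print(f"silhouette {ld.silhouette_avg(pool, km):.3f}, "
      f"Dunn {ld.dunn_index(pool, km):.3f}, "
      f"ARI between algorithms {ld.ari(km.assignments, kmed.assignments):.3f}")

corr, pairs = ld.match_states(km, kmed)
for i, j in pairs:
    print(f"K-means state {i} ~ K-medoids state {j}: r = {corr[i-1, j-1]:.3f}")
# Matched prototypes correlate near 1: centroids and medoids describe the
# same recurrent patterns even though the partitions differ in detail.
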