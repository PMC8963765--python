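"""From BOLD signals to leading eigenvectors of phase coherence.

Takes one synthetic scan, extracts instantaneous phases with the Hilbert
transform, forms the cosine phase-coherence matrix at one volume, and
reduces the whole scan to its eigenvector series.
"""

import numpy as np

import leidyn as ld

spec = ld.default_cohort_spec(n_per_group=(1, 0), seed=7)
scans, _, _ = ld.generate_cohort(spec)
scan = scans[0]

theta = ld.compute_phases(scan)
m = ld.coherence_at(theta, t=75)
vec, varexp = ld.leading_eigenvector(m)
print(f"coherence matrix at volume 75: trace {np.trace(m):.1f} "
      f"(= N = {scan.n_regions}), entries in [{m.min():.2f}, {m.max():.2f}]")
print(f"leading eigenvector: {np.count_nonzero(vec > 0)} of {vec.size} "
      f"regions split from the global mode; variance explained {varexp:.3f}")

es = ld.eigenseries(scan)
print(f"eigen-series: {es.n_retained} vectors (T - 2), "
      f"variance explained in [{es.variance_explained.min():.3f}, "
      f"{es.variance_explained.max():.3f}]")
# The leading eigenvalue always explains at least half of the coherence
# variance: the matrix is positive semidefinite with rank at most two.
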