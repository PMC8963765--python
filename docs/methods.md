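# Methods

This note records the models, conventions and numerical choices behind
`leidyn`, including the points where the procedure is genuinely open and a
choice had to be made.

## Phase extraction and the leading-eigenvector reduction

Regional time courses are demeaned before the Hilbert transform.  The
analytic-signal phase is only meaningful for zero-mean signals and the
convention in the field is silent on this step; demeaning is the assumption
made here and it is the only preprocessing applied — no band-pass
filtering, detrending or nuisance regression (the analysis deliberately
uses the whole spectrum).  The discrete Hilbert transform is the standard
FFT analytic-signal construction (`scipy.signal.hilbert`) over all `T`
volumes; the first and last volume are then dropped because the transform
distorts the signal at the window edges, leaving `T' = T − 2` retained
volumes per scan.  A region with a constant time course has no phase and
is rejected with an error naming the region.

The cosine phase-coherence matrix at volume `t` is
`dFC(n, p, t) = cos(θ(n, t) − θ(p, t))`, identically equal to
`ccᵀ + ssᵀ` with `c = cos θ(·, t)`, `s = sin θ(·, t)`.  It is therefore
positive semidefinite of rank at most two with trace `N`, which forces the
leading eigenvalue to satisfy `λ₁ ≥ trace/2`: the variance explained
`λ₁ / trace` is bounded below by 1/2 analytically, and the
`EigenSeries` container enforces this invariant at construction.

Eigenvector orientation.  Since `−V₁` is also a leading eigenvector, each
vector is oriented so that at most `N/2` elements are strictly positive
(zero elements count as non-positive and belong to the global community).
At an exact `N/2` tie the vector is flipped, if needed, so that its
largest-magnitude element — first occurrence on further magnitude ties —
is non-positive.  A degenerate leading eigenvalue (gap below 1e-12) is a
measure-zero event; it is resolved by the same rule and reported as a
`RuntimeWarning` rather than an error.

## Synthetic cohorts

The generator emulates a two-group resting-state cohort in which scans
visit a small repertoire of planted coherence states.  Per scan, a hidden
Markov chain over the planted states (one chain per group, row-stochastic
within 1e-9, started from its stationary distribution) selects the active
state at each volume; the state is piecewise-constant within a volume,
matching the one-state-per-TR assumption of the analysis.  The phase of
region `n` is a shared slow carrier `2π f · TR · t` (default
`f = 0.05 Hz`, the center of the slow BOLD fluctuation band), plus an
independent per-region Wiener walk, plus a `π` offset whenever the region
belongs to the active state's community.  The observed signal is the
cosine of that phase plus i.i.d. Gaussian noise.  Because the community
offset is exactly `π`, the noiseless phase-coherence matrix is the rank-1
outer product of the ±1 community contrast, so the planted leading
eigenvector is known analytically — the oriented indicator contrast of
the mask — and the community is restricted to at most `N/2` regions so
that the orientation convention maps the community to the positive
elements.

Noise defaults.  The phase-noise default is a 0.05 rad per-volume Wiener
step: over a 150-volume scan the accumulated drift stays well under a
radian, so planted states remain identifiable while single-volume
eigenvectors are visibly noisy.  (A Wiener step of ~0.2 rad/volume lets
regional phases drift apart by more than `π` within a scan and dissolves
the planted structure — useful as a stress case but not as a default
condition.)  Observation noise defaults to 0.2 signal units against a
unit-amplitude carrier.

Planted group effect.  `two_state_cohort_spec` plants a global state and
one community state with group chains `[[1−a, a], [b, 1−b]]`,
`a = s·π_g`, `b = s·(1−π_g)`: `s` is the switching rate and `π_g` the
community-state stationary mass.  The asymptotic variance of the
occupancy fraction over `T` volumes is `π(1−π)(2−s)/(s·T)`; with the
defaults `s = 0.6`, `π_A = 0.425`, `π_B = 0.375`, `T = 150` this puts the
between-scan effect of the planted occupancy difference at Hedges'
g ≈ 0.8 (verified empirically at ≈ 0.83).  Setting both occupancies equal
gives an exchangeable null cohort.

What the generator does *not* emulate: hemodynamic response convolution,
realistic BOLD spectra, spatial autocorrelation, physiological noise and
head motion.  Passing tests therefore demonstrate the correctness and
statistical calibration of the machinery under a known ground truth, not
robustness to the artifacts of real fMRI.

RNG discipline: one cohort seed spawns one `SeedSequence` child per scan,
so outputs are bit-reproducible and independent of generation order.

## Clustering

Distance is the cosine distance `1 − x·y/(‖x‖‖y‖)` throughout.  K-means
updates each centroid as the arithmetic mean of its members — the
convention of the leading-eigenvector literature — rather than a
spherical-mean variant; K-medoids uses alternating Voronoi iteration with
prototypes restricted to observed eigenvectors, plus an optional greedy
PAM-style swap refinement (`pam_refine=True`) intended for small pools.
Each restart initializes at K distinct pooled rows; an empty cluster is
re-seated at the point farthest from its current prototype, and a restart
that still degenerates is discarded (an error is raised only if all
restarts degenerate).  The best-of-restarts winner under the total
cosine-distance objective is relabeled by decreasing cluster size, so
state 1 is always the most frequent pattern.  The full-scale default is
1,000 restarts; tests and examples use 5–50, which is ample at their pool
sizes.

Validation: silhouette (cosine metric; points in singleton clusters score
0), Dunn index (single-linkage separation over maximum diameter; infinite
when all clusters have zero diameter but are separated), ARI, and
variation of information in nats.  The stability protocol clusters each
training fold, transfers the partition to the held-out fold by
nearest-prototype classification, clusters the held-out fold
independently, and compares the two labelings; because labels of
independent clusterings are arbitrary, percent agreement is computed
after optimal one-to-one label matching (Hungarian algorithm on the
contingency table).  The fold split is at the eigenvector level, as the
protocol is usually described; note this allows volumes of one subject to
appear on both sides of a split (a subject-level split would be the
stricter variant).

## Trajectory dynamics

Dwell time averages maximal run lengths, including runs truncated by the
scan boundaries (no censoring rule is standard; inclusion matches the
plain definition), and is reported in TRs and seconds.  States never
visited get occupancy 0, undefined (NaN) dwell time, and are excluded
from group means with the per-test `n` reported.

The conditional transition matrix is estimated by row-normalizing
transition counts.  The textbook quotient of the joint pair probability
(normalized by `T'−1`) by the occupancy (normalized by `T'`) is *not*
row-stochastic — rows inflate by `T'/(T'−1)` except the row of the state
occupying the final volume — so the count-normalized estimator is the
default and the literal quotient is available as
`conditional_mode="quotient"` for comparison.

Chain screening: irreducibility is strong connectivity of the positive
transition digraph restricted to visited states; aperiodicity requires
every recurrent class (condensation sink) to have period 1.  The
stationary distribution `π = 1 (I − P + ONE)⁻¹` is computed only for
chains that visit all K states as transition sources and pass both
screens; excluded scans carry an explicit reason.  Tolerances: row sums
1e-12, stationarity `‖πP − π‖∞` ≤ 1e-10.

## Group statistics

The test statistic is a studentized mean difference whose variance form
is chosen once per comparison by a mean-centered Levene test on the
observed samples: Welch form below p = 0.05, pooled form otherwise.  The
"bootstrap SE" convention is interpreted as: the denominator of the
observed and of every permuted statistic is the bootstrap standard
deviation (default 500 resamples; smaller in desk-scale suites) of the
group-mean difference computed within that labeling, which decouples the
scale estimate from the observed difference; a plug-in formula SE
(`se_mode="plugin"`) is the simpler fallback and is the form the
exhaustive-enumeration oracle uses in the tests.  p-values use the
add-one estimator `(1 + #extreme)/(B + 1)` and can never be exactly
zero.  Hedges' g always uses the pooled SD (with
`J = 1 − 3/(4(n₁+n₂) − 9)`) even when the Welch branch tested the
difference, since g is defined on the pooled scale.  One-tailed tests, in
`compare_all`, take the direction of the observed difference — mirroring
how directional confirmations are usually reported; the default is
two-sided.  All permutation and nested bootstrap streams derive from one
test seed (per-family tests get independent child seeds).

## Network overlap

Prototypes are rectified (negative elements zeroed) before Pearson
correlation with each reference network's parcel-composition vector, so
only the regions that split from the global mode count.  A rectified
prototype with zero variance — always the case for the globally
synchronized state — has no defined correlation and is reported as
overlapping with no network.  No significance convention for "overlap" is
standard; the tidy output reports the two-sided Pearson p per network and
flags the best match, leaving multiplicity control (e.g., Bonferroni over
the 7 networks) to the caller.  The real atlas-derived composition table
requires volumetric atlases and is consumed as an input file;
`synthetic_rsn_table` ships a clearly-synthetic stand-in with the same
format and invariants for tests and examples.

## Problem sizes in the shipped suites

The test and acceptance suites run the full study geometry where it is
what is being checked (145 scans × 150 volumes × 90 regions for the
eigenvector bookkeeping and the variance bound) and compact sizes
elsewhere: clustering and pipeline tests use cohorts of 10–20 scans with
21–30 regions, permutation suites use B = 199–5,000 with 10–200 bootstrap
resamples, and the calibration studies use 50 replicate cohorts for power
(n = 30/group, planted g ≈ 0.8, one-tailed at α₂ = 0.025) and 200 for the
null rejection rate.  These sizes are the package's own desk-scale
choices; the full-scale defaults (1,000 restarts, B = 10,000, 500
bootstrap resamples) remain the constructor defaults.

## Known limitations

- Eigenvector-level cross-validation folds ignore subject identity.
- The permutation test assumes exchangeability under the null; covariate
  adjustment (age, sex, motion) is out of scope.
- K selection is reported (validation surfaces), not automated.
- The generator's stationarity (time-homogeneous hidden chains) cannot
  probe drifting or non-Markovian state dynamics.
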