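"""Two-group Monte-Carlo permutation tests with bootstrap standard errors.

Group means of any per-scan measure (occupancy, dwell time, transition or
limiting probability) are compared with a studentized mean-difference
statistic whose form is gated by a Levene test of variance homogeneity:
Welch-style when the variances differ (Levene p < 0.05), pooled otherwise.
The standard error in the denominator is, by default, the bootstrap
standard deviation of the mean difference estimated inside each (permuted)
labeling, which decouples the scale estimate from the observed mean
difference; a plug-in formula SE is available as a fallback.  The p-value
uses the add-one Monte-Carlo estimator (1 + #extreme) / (B + 1), so it is
never exactly zero.  Effect sizes are Hedges' g (pooled SD with the
small-sample correction J = 1 - 3 / (4 n - 9)).

Bonferroni thresholds: alpha1 = 0.05 (per test), alpha2 = 0.05 / family
size (per clustering solution), alpha3 = 0.05 / 209 (across the K = 2..20
sweep, since sum of K over 2..20 is 209).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import GroupComparison

__all__ = [
    "TestSpec",
    "levene_test",
    "hedges_g",
    "permutation_test",
    "compare_all",
    "ALPHA3_FAMILY",
]

#: total number of hypotheses across the K = 2..20 sweep: sum(K) = 209
ALPHA3_FAMILY = sum(range(2, 21))


@dataclass
class TestSpec:
    """Parameters of the permutation-test procedure."""

    B: int = 10_000
    n_boot: int = 500
    tails: str = "two"
    alpha1: float = 0.05
    seed: int = 0
    se_mode: str = "bootstrap"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")
        if self.se_mode not in ("bootstrap", "plugin"):
            raise ValueError("se_mode must be 'bootstrap' or 'plugin'")


def levene_test(x, y) -> float:
    """p-value of the classic mean-centered Levene test of equal variances
    (one-way F on absolute deviations from the group means)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    dev = np.concatenate([np.abs(x - x.mean()), np.abs(y - y.mean())])
    if np.allclose(dev, 0):
        return 1.0
    with np.errstate(invalid="ignore"):
        stat, p = scipy.stats.levene(x, y, center="mean")
    if not np.isfinite(p):
        return 1.0
    return float(p)


def hedges_g(x, y) -> float:
    """Hedges' g: pooled-SD standardized mean difference with the
    small-sample correction ``J = 1 - 3 / (4 (n1 + n2) - 9)``."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    s1, s2 = x.std(ddof=1), y.std(ddof=1)
    sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    diff = x.mean() - y.mean()
    if sp == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * diff / sp)


def _plugin_se(x: np.ndarray, y: np.ndarray, branch: str) -> float:
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if branch == "welch":
        return math.sqrt(v1 / n1 + v2 / n2)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def _bootstrap_se_batch(
    xs: np.ndarray, ys: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap SD of the mean difference for a batch of labelings.

    ``xs`` is ``(m, n1)``, ``ys`` is ``(m, n2)``; returns ``(m,)``.
    """
    m, n1 = xs.shape
    n2 = ys.shape[1]
    i1 = rng.integers(0, n1, size=(m, n_boot, n1))
    i2 = rng.integers(0, n2, size=(m, n_boot, n2))
    m1 = np.take_along_axis(xs[:, None, :], i1, axis=2).mean(axis=2)
    m2 = np.take_along_axis(ys[:, None, :], i2, axis=2).mean(axis=2)
    return (m1 - m2).std(axis=1, ddof=1)


def _statistics(nums: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """Studentize mean differences, mapping 0/0 to 0 and x/0 to +-inf."""
    out = np.zeros_like(nums)
    nonzero = ses > 0
    out[nonzero] = nums[nonzero] / ses[nonzero]
    out[~nonzero & (nums > 0)] = np.inf
    out[~nonzero & (nums < 0)] = -np.inf
    return out


def permutation_test(
    x,
    y,
    spec: TestSpec | None = None,
    alternative: str = "two-sided",
) -> GroupComparison:
    """Monte-Carlo permutation test of equal group means.

    The observed statistic and every permuted statistic are studentized
    mean differences (x mean minus y mean); the variance branch (Welch or
    pooled) is chosen once from a Levene test on the observed samples.
    ``alternative`` is ``"two-sided"``, ``"greater"`` (x mean exceeds y
    mean) or ``"less"``.
    """
    spec = spec or TestSpec()
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(spec.seed)

    lev_p = levene_test(x, y)
    branch = "welch" if lev_p < 0.05 else "pooled"
    pooled = np.concatenate([x, y])

    if spec.se_mode == "bootstrap":
        obs_se = float(
            _bootstrap_se_batch(x[None, :], y[None, :], spec.n_boot, rng)[0]
        )
    else:
        obs_se = _plugin_se(x, y, branch)
    obs_num = x.mean() - y.mean()
    t0 = float(_statistics(np.array([obs_num]), np.array([obs_se]))[0])

    # permuted statistics, chunked to bound memory at ~2e7 resamples
    stats = np.empty(spec.B)
    chunk = max(1, int(2e7 // max(1, spec.n_boot * max(n1, n2))))
    done = 0
    while done < spec.B:
        m = min(chunk, spec.B - done)
        perm = np.empty((m, n1 + n2))
        for i in range(m):
            perm[i] = pooled[rng.permutation(n1 + n2)]
        xs, ys = perm[:, :n1], perm[:, n1:]
        nums = xs.mean(axis=1) - ys.mean(axis=1)
        if spec.se_mode == "bootstrap":
            ses = _bootstrap_se_batch(xs, ys, spec.n_boot, rng)
        else:
            v1 = xs.var(axis=1, ddof=1)
            v2 = ys.var(axis=1, ddof=1)
            if branch == "welch":
                ses = np.sqrt(v1 / n1 + v2 / n2)
            else:
                sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
                ses = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        stats[done : done + m] = _statistics(nums, ses)
        done += m

    eps = 1e-12
    if alternative == "two-sided":
        extreme = np.abs(stats) >= abs(t0) - eps
    elif alternative == "greater":
        extreme = stats >= t0 - eps
    else:
        extreme = stats <= t0 + eps
    p = (1.0 + int(extreme.sum())) / (spec.B + 1.0)

    s1, s2 = x.std(ddof=1), y.std(ddof=1)
    sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    g = hedges_g(x, y) if (sp > 0 or obs_num == 0) else float("nan")
    return GroupComparison(
        statistic=t0,
        mean1=float(x.mean()),
        mean2=float(y.mean()),
        sd1=float(s1),
        sd2=float(s2),
        pooled_sd=float(sp),
        n1=n1,
        n2=n2,
        levene_p=lev_p,
        variance_assumption=branch,
        p_value=float(p),
        hedges_g=g,
        alternative=alternative,
        B=spec.B,
    )


def compare_all(
    table: pd.DataFrame,
    measure: str,
    K: int,
    spec: TestSpec | None = None,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """One permutation test per state (or per ordered state pair).

    ``measure`` selects the family: ``"fo"``, ``"dt"`` (columns of the
    tidy measures table), ``"transition"`` (tidy transitions table with
    ``from_state``/``to_state``/``prob``) or ``"limiting"`` (chain
    diagnostics table with ``pi_<state>`` columns, excluded scans NaN).
    Family sizes are K for per-state measures and K*K for transitions;
    significance flags are reported at alpha1 = 0.05, alpha2 = 0.05 /
    family size and alpha3 = 0.05 / 209.  Tests with fewer than 2 defined
    values in either group are skipped and reported as such.
    """
    spec = spec or TestSpec()
    if groups is None:
        found = list(pd.unique(table["group"]))
        if len(found) != 2:
            raise ValueError(f"expected exactly 2 groups, found {found}")
        groups = (found[0], found[1])
    g1, g2 = groups

    if measure in ("fo", "dt"):
        col = {"fo": "fo", "dt": "dt_s"}[measure]
        keys = [("state", a) for a in range(1, K + 1)]
        family = K

        def values(key, grp):
            sel = (table["state"] == key[1]) & (table["group"] == grp)
            return table.loc[sel, col].dropna().to_numpy()

    elif measure == "transition":
        keys = [
            (("from_state", a), ("to_state", b))
            for a in range(1, K + 1)
            for b in range(1, K + 1)
        ]
        family = K * K

        def values(key, grp):
            (fc, a), (tc, b) = key
            sel = (table[fc] == a) & (table[tc] == b) & (table["group"] == grp)
            return table.loc[sel, "prob"].dropna().to_numpy()

    elif measure == "limiting":
        keys = [("state", a) for a in range(1, K + 1)]
        family = K

        def values(key, grp):
            sel = table["group"] == grp
            return table.loc[sel, f"pi_{key[1]}"].dropna().to_numpy()

    else:
        raise ValueError(f"unknown measure {measure!r}")

    alpha2 = spec.alpha1 / family
    alpha3 = spec.alpha1 / ALPHA3_FAMILY
    alternative = "two-sided" if spec.tails == "two" else None
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(keys))]

    rows = []
    for key, child_seed in zip(keys, seeds):
        if measure == "transition":
            ident = {"from_state": key[0][1], "to_state": key[1][1]}
        else:
            ident = {"state": key[1]}
        xv, yv = values(key, g1), values(key, g2)
        if xv.size < 2 or yv.size < 2:
            rows.append(
                {
                    **ident,
                    "measure": measure,
                    "n1": xv.size,
                    "n2": yv.size,
                    "skipped": True,
                    "p": np.nan,
                    "g": np.nan,
                }
            )
            continue
        sub = TestSpec(
            B=spec.B,
            n_boot=spec.n_boot,
            tails=spec.tails,
            alpha1=spec.alpha1,
            seed=child_seed,
            se_mode=spec.se_mode,
        )
        alt = alternative
        if alt is None:
            # one-tailed in the direction of the observed difference
            alt = "greater" if xv.mean() >= yv.mean() else "less"
        res = permutation_test(xv, yv, sub, alternative=alt)
        rows.append(
            {
                **ident,
                "measure": measure,
                "n1": res.n1,
                "n2": res.n2,
                "mean1": res.mean1,
                "mean2": res.mean2,
                "levene_p": res.levene_p,
                "branch": res.variance_assumption,
                "statistic": res.statistic,
                "p": res.p_value,
                "g": res.hedges_g,
                "sig_alpha1": res.p_value < spec.alpha1,
                "sig_alpha2": res.p_value < alpha2,
                "sig_alpha3": res.p_value < alpha3,
                "skipped": False,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha1"] = spec.alpha1
    out.attrs["alpha2"] = alpha2
    out.attrs["alpha3"] = alpha3
    out.attrs["groups"] = groups
    return out
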