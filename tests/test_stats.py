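"""Permutation tests, Levene gate, Hedges' g and family-wise comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import leidyn as ld



# ------------------------------------------------------------- Levene

def levene_oracle(x, y):
    """One-way F on absolute deviations from the group means."""
    from scipy.stats import f as fdist

    dev = [np.abs(np.asarray(s) - np.mean(s)) for s in (x, y)]
    n = sum(len(d) for d in dev)
    grand = np.concatenate(dev).mean()
    between = sum(len(d) * (d.mean() - grand) ** 2 for d in dev) / (2 - 1)
    within = sum(((d - d.mean()) ** 2).sum() for d in dev) / (n - 2)
    stat = between / within
    return 1 - fdist.cdf(stat, 1, n - 2)


def test_levene_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    assert ld.levene_test(x, x) == pytest.approx(1.0)


def test_levene_matches_hand_formula():
    x = [2.1, 3.4, 1.9, 2.8, 3.0]
    y = [10.0, 2.0, 7.5, 0.3, 5.2]
    assert ld.levene_test(x, y) == pytest.approx(levene_oracle(x, y), abs=1e-10)


def test_levene_detects_variance_difference(rng):
    x = np.zeros(60) + rng.normal(0, 1e-6, 60)
    y = rng.normal(0, 5.0, 60)
    assert ld.levene_test(x, y) < 1e-6


def test_levene_all_constant():
    assert ld.levene_test([1.0, 1.0, 1.0], [2.0, 2.0]) == 1.0


# ----------------------------------------------------------- Hedges g

def test_hedges_hand_example():
    assert ld.hedges_g([1, 2, 3], [3, 4, 5]) == pytest.approx(-1.6)


def test_hedges_null_and_antisymmetry(rng):
    x = rng.normal(size=10)
    y = rng.normal(size=12)
    assert ld.hedges_g(x, x) == 0.0
    assert ld.hedges_g(x, y) == pytest.approx(-ld.hedges_g(y, x))


def test_hedges_zero_pooled_sd_unequal_means():
    with pytest.raises(ValueError, match="undefined"):
        ld.hedges_g([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------- permutation test

def exhaustive_p(x, y, alternative="two-sided"):
    """Exhaustive permutation p using the pooled plug-in statistic."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def stat(ix):
        a = pooled[list(ix)]
        b = pooled[[i for i in range(len(pooled)) if i not in ix]]
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((n1 - 1) * v1 + (len(b) - 1) * v2) / (len(pooled) - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / len(b)))
        d = a.mean() - b.mean()
        return d / se if se > 0 else math.copysign(math.inf, d) if d else 0.0

    t0 = stat(range(n1))
    stats = [stat(ix) for ix in itertools.combinations(range(len(pooled)), n1)]
    if alternative == "two-sided":
        hits = sum(abs(t) >= abs(t0) - 1e-12 for t in stats)
    else:
        hits = sum(t >= t0 - 1e-12 for t in stats)
    return hits / len(stats), t0


def test_identical_constant_samples_give_p_one():
    res = ld.permutation_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0],
                              ld.TestSpec(B=99, n_boot=20, seed=0))
    assert res.p_value == pytest.approx(1.0)
    assert res.statistic == 0.0
    assert res.hedges_g == 0.0


def test_monte_carlo_p_matches_exhaustive_enumeration():
    x = np.array([1.0, 4.0, 2.0])
    y = np.array([6.0, 3.0, 8.0])
    p_exact, _ = exhaustive_p(x, y)
    spec = ld.TestSpec(B=4000, n_boot=50, seed=7, se_mode="plugin")
    res = ld.permutation_test(x, y, spec)
    mc_se = math.sqrt(p_exact * (1 - p_exact) / spec.B)
    assert abs(res.p_value - p_exact) < 2 * mc_se + 2 / spec.B


def test_p_value_never_zero(rng):
    x = rng.normal(0, 1, 20)
    y = rng.normal(30, 1, 20)
    res = ld.permutation_test(x, y, ld.TestSpec(B=199, n_boot=20, seed=0))
    assert res.p_value == pytest.approx(1 / 200)
    assert res.p_value > 0


def test_one_tailed_not_larger_than_two_tailed(rng):
    x = rng.normal(0.7, 1, 15)
    y = rng.normal(0.0, 1, 15)
    spec = ld.TestSpec(B=999, n_boot=30, seed=3)
    p2 = ld.permutation_test(x, y, spec, alternative="two-sided").p_value
    p1 = ld.permutation_test(x, y, spec, alternative="greater").p_value
    assert p1 <= p2 + 1e-12


def test_bootstrap_and_plugin_agree_on_clear_effect(rng):
    x = rng.normal(2.0, 1.0, 25)
    y = rng.normal(0.0, 1.0, 25)
    for mode in ("bootstrap", "plugin"):
        res = ld.permutation_test(
            x, y, ld.TestSpec(B=499, n_boot=100, seed=1, se_mode=mode)
        )
        assert res.p_value < 0.01
        assert res.hedges_g > 1.0


def test_levene_gate_selects_welch_branch(rng):
    x = rng.normal(0, 0.01, 30)
    y = rng.normal(0, 5.0, 30)
    res = ld.permutation_test(x, y, ld.TestSpec(B=99, n_boot=20, seed=0))
    assert res.variance_assumption == "welch"
    z = rng.normal(0, 1, 30)
    w = rng.normal(0, 1, 30)
    res2 = ld.permutation_test(z, w, ld.TestSpec(B=99, n_boot=20, seed=0))
    assert res2.variance_assumption == "pooled"


# ----------------------------------------------------------- families

def make_measures(rng, n=12, K=3, shift_state=None, shift=0.0):
    rows = []
    for g in ("A", "B"):
        for i in range(n):
            raw = rng.dirichlet(np.ones(K) * 5)
            if g == "A" and shift_state is not None:
                raw[shift_state - 1] += shift
                raw /= raw.sum()
            for a in range(1, K + 1):
                rows.append(
                    {"subject_id": f"{g}{i}", "group": g, "state": a,
                     "fo": raw[a - 1], "dt_s": raw[a - 1] * 10}
                )
    return pd.DataFrame(rows)


def test_compare_all_fo_family_size_and_flags(rng):
    table = make_measures(rng, n=15, K=3, shift_state=1, shift=0.4)
    res = ld.compare_all(table, "fo", 3, ld.TestSpec(B=199, n_boot=20, seed=0))
    assert len(res) == 3
    assert res.attrs["alpha2"] == pytest.approx(0.05 / 3)
    assert res.attrs["alpha3"] == pytest.approx(0.05 / 209)
    top = res[res["state"] == 1].iloc[0]
    assert top["p"] < 0.05 / 3 and top["g"] > 0


def test_compare_all_transition_family_has_k_squared_tests(rng):
    rows = []
    for g in ("A", "B"):
        for i in range(4):
            for a in range(1, 12):
                for b in range(1, 12):
                    rows.append(
                        {"subject_id": f"{g}{i}", "group": g,
                         "from_state": a, "to_state": b,
                         "prob": rng.random()}
                    )
    table = pd.DataFrame(rows)
    res = ld.compare_all(table, "transition", 11,
                         ld.TestSpec(B=19, n_boot=5, seed=0))
    assert len(res) == 121
    assert res.attrs["alpha2"] == pytest.approx(0.05 / 121)


def test_compare_all_skips_underpopulated_tests(rng):
    table = make_measures(rng, n=6, K=2)
    # state 2 defined for fewer than 2 scans in group A
    table.loc[(table["group"] == "A") & (table["state"] == 2), "fo"] = np.nan
    res = ld.compare_all(table, "fo", 2, ld.TestSpec(B=19, n_boot=5, seed=0))
    skipped = res[res["state"] == 2].iloc[0]
    assert bool(skipped["skipped"]) and np.isnan(skipped["p"])
    assert not res[res["state"] == 1].iloc[0]["skipped"]


def test_compare_all_deterministic(rng):
    table = make_measures(rng, n=8, K=2)
    spec = ld.TestSpec(B=99, n_boot=10, seed=5)
    r1 = ld.compare_all(table, "fo", 2, spec)
    r2 = ld.compare_all(table, "fo", 2, spec)
    pd.testing.assert_frame_equal(r1, r2)
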