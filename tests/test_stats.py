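"""Nonparametric battery vs hand-rolled oracle implementations.

The oracles below deliberately avoid the code paths of serosim.stats (and
its scipy backends where feasible): ranks are computed by explicit sorting,
exact Mann-Whitney p-values by enumeration over label assignments, and the
two-group Dunn z is checked against the algebraic identity z^2 = H.
"""

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pytest
from scipy import stats as sps

from serosim import (
    cohens_d,
    compare_groups,
    dunn_bonferroni,
    kruskal_wallis,
    mann_whitney_u,
    posthoc_power,
)


# ---------------------------------------------------------------- oracles
def oracle_ranks(values):
    """Midranks by explicit sorting (no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def oracle_u(x, y):
    """U of x by direct pair counting (ties count half)."""
    return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)


def oracle_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumeration of label assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = oracle_u(x, y)
    mu = len(x) * len(y) / 2
    us = [
        oracle_u([pooled[i] for i in idx], [pooled[i] for i in range(len(pooled)) if i not in idx])
        for idx in combinations(range(len(pooled)), n)
    ]
    dev = abs(u_obs - mu)
    return sum(1 for u in us if abs(u - mu) >= dev - 1e-12) / comb(len(pooled), n)


def oracle_h(groups):
    """Kruskal-Wallis H with tie correction, from first principles."""
    pooled = [v for g in groups for v in g]
    ranks = oracle_ranks(pooled)
    n = len(pooled)
    start, rsums = 0, []
    for g in groups:
        rsums.append(sum(ranks[start : start + len(g)]))
        start += len(g)
    h = 12 / (n * (n + 1)) * sum(r * r / len(g) for r, g in zip(rsums, groups)) - 3 * (n + 1)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    correction = 1 - tie / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def oracle_normal_p_two_sided(z):
    return 2 * (1 - 0.5 * (1 + erf(abs(z) / sqrt(2))))


# ------------------------------------------------------------ Mann-Whitney
class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, u_expected, p_expected",
        [
            ([1, 2, 3], [4, 5, 6], 0.0, 0.1),  # 2/C(6,3)
            ([1, 2], [3], 0.0, 2 / 3),  # enumeration over 3 assignments
        ],
    )
    def test_exact_small_sample(self, x, y, u_expected, p_expected):
        u, p = mann_whitney_u(x, y)
        assert u == u_expected
        assert p == pytest.approx(p_expected, abs=1e-12)
        assert p == pytest.approx(oracle_exact_p(x, y), abs=1e-12)

    def test_identical_samples_give_symmetric_null(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_path_agrees_with_enumeration_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 1000, size=int(rng.integers(2, 7))) / 7.0
            y = rng.integers(1000, 2000, size=int(rng.integers(2, 7))) / 7.0
            y = np.concatenate([y, rng.integers(0, 1000, size=2) / 7.0])
            if len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
                continue  # oracle enumeration assumes no ties here
            u, p = mann_whitney_u(x, y)
            assert u == pytest.approx(oracle_u(x, y), abs=1e-12)
            assert p == pytest.approx(oracle_exact_p(x, y), abs=1e-10)

    def test_asymptotic_path_agrees_with_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 12, size=40).astype(float)  # heavy ties
            y = rng.integers(3, 15, size=55).astype(float)
            u, p = mann_whitney_u(x, y)
            n1, n2 = len(x), len(y)
            n = n1 + n2
            assert u == pytest.approx(oracle_u(x, y), abs=1e-9)
            counts = {}
            for v in np.concatenate([x, y]):
                counts[v] = counts.get(v, 0) + 1
            tie = sum(c**3 - c for c in counts.values())
            sd = sqrt(n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1))))
            z = (u - n1 * n2 / 2) / sd
            assert p == pytest.approx(oracle_normal_p_two_sided(z), abs=1e-10)

    def test_shift_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=25)
        assert mann_whitney_u(x, y) == pytest.approx(mann_whitney_u(x + 100, y + 100))


# ---------------------------------------------------------- Kruskal-Wallis
class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_hand_ranked_example(self):
        # three cleanly separated pairs, no ties: the hand-rank formula gives
        # 12/(6*7) * (2*1.5^2 + 2*3.5^2 + 2*5.5^2) - 3*7 = 32/7
        h, _ = kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert h == pytest.approx(32 / 7, abs=1e-12)
        assert h == pytest.approx(oracle_h([[1, 2], [3, 4], [5, 6]]), abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0])

    def test_agrees_with_first_principles_oracle(self, rng):
        for _ in range(20):
            groups = [rng.integers(0, 20, size=int(rng.integers(5, 30))).astype(float)
                      for _ in range(int(rng.integers(2, 5)))]
            h, p = kruskal_wallis(*groups)
            assert h == pytest.approx(oracle_h(groups), abs=1e-10)
            assert p == pytest.approx(float(sps.chi2.sf(h, len(groups) - 1)), abs=1e-12)

    def test_two_group_case_matches_mann_whitney_asymptotics(self, rng):
        """On tie-free data KW and the MWU normal approximation agree closely."""
        x, y = rng.normal(0.0, 1.0, 200), rng.normal(0.3, 1.0, 200)
        _, p_kw = kruskal_wallis(x, y)
        _, p_mwu = mann_whitney_u(x, y)
        assert abs(p_kw - p_mwu) < 0.01


# --------------------------------------------------------------- Dunn test
class TestDunn:
    def test_identical_groups_adjusted_p_is_one(self):
        res = dunn_bonferroni({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert all(padj == 1.0 for _, _, padj in res.values())

    def test_bonferroni_is_capped_triple_of_raw(self, rng):
        groups = {k: rng.normal(loc, 1.0, 20) for k, loc in [("a", 0), ("b", 0.5), ("c", 1)]}
        for z, praw, padj in dunn_bonferroni(groups).values():
            assert padj == pytest.approx(min(1.0, 3 * praw), abs=1e-15)

    def test_two_group_z_squared_equals_kruskal_h(self, rng):
        """Algebraic identity linking Dunn's z to the (tie-corrected) H."""
        for _ in range(10):
            groups = {
                "a": rng.integers(0, 15, size=int(rng.integers(5, 40))).astype(float),
                "b": rng.integers(5, 20, size=int(rng.integers(5, 40))).astype(float),
            }
            ((z, _, _),) = dunn_bonferroni(groups).values()
            h, _ = kruskal_wallis(groups["a"], groups["b"])
            assert z**2 == pytest.approx(h, abs=1e-10)

    def test_agrees_with_independent_reimplementation(self, rng):
        """Formula-level oracle via explicit midranks, ties included."""
        groups = {k: rng.integers(0, 10, size=n).astype(float)
                  for k, n in [("a", 18), ("b", 25), ("c", 12)]}
        pooled = np.concatenate(list(groups.values()))
        ranks = oracle_ranks(list(pooled))
        n = len(pooled)
        sizes = {k: len(v) for k, v in groups.items()}
        start, rbar = 0, {}
        for k, v in groups.items():
            rbar[k] = sum(ranks[start : start + len(v)]) / len(v)
            start += len(v)
        counts = {}
        for v in pooled:
            counts[v] = counts.get(v, 0) + 1
        tie = sum(c**3 - c for c in counts.values())
        var = n * (n + 1) / 12 - tie / (12 * (n - 1))
        res = dunn_bonferroni(groups)
        for (a, b), (z, praw, _) in res.items():
            se = sqrt(var * (1 / sizes[a] + 1 / sizes[b]))
            assert z == pytest.approx((rbar[a] - rbar[b]) / se, abs=1e-10)
            assert praw == pytest.approx(oracle_normal_p_two_sided(z), abs=1e-10)

    def test_unknown_pair_rejected(self):
        with pytest.raises(KeyError):
            dunn_bonferroni({"a": [1, 2], "b": [3, 4]}, pair=("a", "zzz"))


# ------------------------------------------------------- effect size/power
class TestEffectSizeAndPower:
    def test_equal_samples_give_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        # means 0.5 vs 1.5, pooled SD sqrt(1/2) -> d = -sqrt(2)
        assert cohens_d([0, 1], [1, 2]) == pytest.approx(-sqrt(2), abs=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(0.4, 1.0, 25)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x), abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([2.0, 2.0], [2.0, 2.0])

    def test_null_effect_power_equals_alpha(self):
        assert posthoc_power(0.0, 50, 50, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_effect_and_n(self):
        powers_d = [posthoc_power(d, 40, 40) for d in (0.1, 0.3, 0.5, 0.8)]
        powers_n = [posthoc_power(0.4, n, n) for n in (10, 30, 100)]
        assert sorted(powers_d) == powers_d and sorted(powers_n) == powers_n

    def test_published_study_size_power(self):
        """d=0.35 with groups of 46 and 55 gives power ~0.41."""
        assert posthoc_power(0.35, 46, 55, alpha=0.05) == pytest.approx(0.41, abs=0.015)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power(0.3, 20, 20, alpha=1.5)


class TestCompareGroups:
    def test_two_and_three_group_layouts(self, rng):
        import pandas as pd

        rows = []
        for g, loc, n in [("u", 0.0, 30), ("a", 0.4, 25), ("n", 0.1, 28)]:
            for i in range(n):
                rows.append({"sample_id": f"{g}{i}", "group": g,
                             "fc5ht_mean": rng.normal(loc, 1.0)})
        df = pd.DataFrame(rows)
        res3 = compare_groups(df)
        assert set(res3["test"]) == {"kruskal_wallis", "dunn"}
        assert len(res3[res3["test"] == "dunn"]) == 3
        res2 = compare_groups(df[df["group"] != "n"])
        assert set(res2["test"]) == {"mann_whitney"}
        assert res2["power"].notna().all()
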