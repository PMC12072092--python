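"""Nonparametric group comparisons for model-derived species means.

Two-group comparisons use the Mann-Whitney U test; three or more groups use
Kruskal-Wallis followed by Dunn's post hoc pairwise z tests with Bonferroni
correction.  Effect sizes are pooled-SD Cohen's d, and post hoc power uses
the noncentral-t two-sample approximation.  All tests are two-sided with
tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_bonferroni",
    "cohens_d",
    "posthoc_power",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupComparison:
    """One test result on one species."""

    species: str
    groups: tuple[str, ...]
    group_n: tuple[int, ...]
    test: str  # 'mann_whitney' | 'kruskal_wallis' | 'dunn'
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    effect_size_d: float | None = None
    power: float | None = None


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    return arr


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U of the first sample, p).

    Uses the exact null distribution when both samples have n <= 8 and no
    ties across the pooled data, the normal approximation with tie
    correction otherwise.
    """
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(x) <= 8 and len(y) <= 8
    if small and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        # tie-corrected normal approximation, no continuity correction
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*samples) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square (k-1 df) p-value."""
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [_check_sample(s, f"group {i}") for i, s in enumerate(samples)]
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H = 0 by convention, p = 1
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def _ranks_and_tie_term(samples: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float]:
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    out, start = [], 0
    for s in samples:
        out.append(ranks[start : start + len(s)])
        start += len(s)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    return out, tie_sum


def dunn_bonferroni(
    samples: Mapping[str, Sequence[float]], pair: tuple[str, str] | None = None
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Dunn's post hoc z tests on pooled ranks, Bonferroni-adjusted.

    ``samples`` maps group label to observations.  Returns, for the
    requested ``pair`` (or all pairs when None), ``(z, raw p, adjusted p)``
    where the adjusted p is min(1, m * p) with m the number of pairs.  The
    z denominator carries the standard tie correction
    sum(t^3 - t) / (12 (N - 1)).
    """
    labels = list(samples)
    if pair is not None:
        for g in pair:
            if g not in samples:
                raise KeyError(f"group {g!r} not among samples")
    arrays = [_check_sample(samples[g], g) for g in labels]
    group_ranks, tie_sum = _ranks_and_tie_term(arrays)
    n_tot = sum(len(a) for a in arrays)
    mean_rank = {g: float(r.mean()) for g, r in zip(labels, group_ranks)}
    sizes = {g: len(samples[g]) for g in labels}
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    results: dict[tuple[str, str], tuple[float, float, float]] = {}
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        results[(a, b)] = (float(z), p, min(1.0, m * p))
    if pair is not None:
        key = pair if pair in results else (pair[1], pair[0])
        return {pair: results[key]}
    return results


def cohens_d(x, y) -> float:
    """Pooled-SD Cohen's d, (n-1)-weighted pooling; antisymmetric in (x, y)."""
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Cohen's d needs at least two values per group")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def posthoc_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample comparison at effect size ``d``.

    Noncentral-t approximation (as for an independent-samples t test with
    unequal group sizes).  At d = 0 the power equals ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    power = TTestIndPower().power(
        effect_size=abs(d), nobs1=n1, ratio=n2 / n1, alpha=alpha, alternative="two-sided"
    )
    return float(power)


def compare_groups(
    summaries: pd.DataFrame,
    species_cols: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full battery on a per-individual species-means table.

    Expects the layout of :func:`serosim.simulate.simulate_cohort`
    (``sample_id``, ``group``, ``<species>_mean`` columns).  With two
    groups: Mann-Whitney plus Cohen's d and post hoc power.  With three or
    more: Kruskal-Wallis plus Dunn-Bonferroni pairwise rows.  Returns one
    row per (species, test, pair).
    """
    if species_cols is None:
        species_cols = [c for c in summaries.columns if c.endswith("_mean")]
    groups = list(dict.fromkeys(summaries["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for col in species_cols:
        by_group = {g: summaries.loc[summaries["group"] == g, col].to_numpy() for g in groups}
        if len(groups) == 2:
            a, b = groups
            u, p = mann_whitney_u(by_group[a], by_group[b])
            d = cohens_d(by_group[a], by_group[b])
            rows.append(
                {
                    "species": col, "test": "mann_whitney", "pair": f"{a}|{b}",
                    "statistic": u, "p_value": p, "adjusted_p": np.nan,
                    "effect_size_d": d,
                    "power": posthoc_power(d, len(by_group[a]), len(by_group[b]), alpha),
                }
            )
        else:
            h, p = kruskal_wallis(*[by_group[g] for g in groups])
            rows.append(
                {
                    "species": col, "test": "kruskal_wallis", "pair": "|".join(groups),
                    "statistic": h, "p_value": p, "adjusted_p": np.nan,
                    "effect_size_d": np.nan, "power": np.nan,
                }
            )
            for (a, b), (z, praw, padj) in dunn_bonferroni(by_group).items():
                d = cohens_d(by_group[a], by_group[b])
                rows.append(
                    {
                        "species": col, "test": "dunn", "pair": f"{a}|{b}",
                        "statistic": z, "p_value": praw, "adjusted_p": padj,
                        "effect_size_d": d,
                        "power": posthoc_power(d, len(by_group[a]), len(by_group[b]), alpha),
                    }
                )
    return pd.DataFrame(rows)
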