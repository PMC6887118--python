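"""Group-comparison reporting: normality-routed test selection.

The routing mirrors the analysis convention of the source experiments:
normality is assessed per group with the Lilliefors-corrected
Kolmogorov-Smirnov test; two normal groups are compared with Welch's
t-test and otherwise with the Mann-Whitney test; more than two groups use
one-way ANOVA with Bonferroni-corrected pairwise post-hocs when all are
normal, and Kruskal-Wallis with Dunn's post-hoc test otherwise;
categorical counts use Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr
from statsmodels.stats.diagnostic import lilliefors

ALPHA_NORMALITY = 0.05


def normality_pvalue(x: Sequence[float]) -> float:
    """Lilliefors (KS with estimated parameters) p-value for normality."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        return 1.0          # too small to reject; route parametric
    if np.ptp(x) == 0:
        return 0.0          # degenerate; route non-parametric
    return float(lilliefors(x, dist="norm")[1])


def is_normal(x: Sequence[float], alpha: float = ALPHA_NORMALITY) -> bool:
    return normality_pvalue(x) > alpha


def dunns_test(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test with tie correction.

    Pairwise z statistics on mean pooled ranks, two-sided p-values from
    the normal distribution, Bonferroni-adjusted over all pairs.
    """
    names = list(samples)
    data = [np.asarray(samples[k], dtype=float) for k in names]
    pooled = np.concatenate(data)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for name, x in zip(names, data):
        mean_ranks[name] = ranks[i:i + len(x)].mean()
        i += len(x)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        na, nb = len(samples[a]), len(samples[b])
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = abs(mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * (1.0 - ndtr(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "p_raw": float(p),
                     "p_adj": float(min(1.0, p * len(pairs)))})
    return pd.DataFrame(rows)


def _bonferroni_welch(samples: Mapping[str, Sequence[float]],
                      ) -> pd.DataFrame:
    pairs = list(combinations(samples, 2))
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(samples[a], samples[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t),
                     "p_raw": float(p),
                     "p_adj": float(min(1.0, p * len(pairs)))})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    groups: list[str]
    n: dict[str, int]
    normal: dict[str, bool]
    test: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None
    alternative: str = "two-sided"


def compare_groups(samples: Mapping[str, Sequence[float]],
                   alternative: str = "two-sided") -> GroupComparison:
    """Route a multi-group comparison by normality and group count.

    ``alternative`` applies to the two-group tests only (one-tailed p
    values are reported when the hypothesis dictates a direction).
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for k in names:
        if len(samples[k]) < 3:
            raise ValueError(f"group {k!r} has n < 3")
    normal = {k: is_normal(samples[k]) for k in names}
    posthoc = None
    if len(names) == 2:
        a, b = (np.asarray(samples[k], dtype=float) for k in names)
        if all(normal.values()):
            test = "welch_t"
            stat, p = sps.ttest_ind(a, b, equal_var=False,
                                    alternative=alternative)
        else:
            test = "mann_whitney"
            stat, p = sps.mannwhitneyu(a, b, alternative=alternative)
    else:
        arrays = [np.asarray(samples[k], dtype=float) for k in names]
        if all(normal.values()):
            test = "anova_bonferroni"
            stat, p = sps.f_oneway(*arrays)
            posthoc = _bonferroni_welch(samples)
        else:
            test = "kruskal_dunn"
            stat, p = sps.kruskal(*arrays)
            posthoc = dunns_test(samples)
    return GroupComparison(groups=names,
                           n={k: len(samples[k]) for k in names},
                           normal=normal, test=test,
                           statistic=float(stat), pvalue=float(p),
                           posthoc=posthoc, alternative=alternative)


def fisher_exact_counts(k1: int, n1: int, k2: int, n2: int,
                        alternative: str = "two-sided",
                        ) -> tuple[float, float]:
    """Fisher's exact test on two success/total counts."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    odds, p = sps.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference
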