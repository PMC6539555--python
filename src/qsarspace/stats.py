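"""Cross-representation comparison with the Friedman rank test.

Representations (treatments) are ranked within each dataset (block) by their
independent-validation PVE, rank 1 going to the best (highest-PVE) model and
ties receiving averaged ranks.  The tie-corrected Friedman chi-square
statistic on k-1 degrees of freedom tests whether the treatments differ; a
Conover rank-sum least-significant-difference procedure then groups
statistically indistinct treatments under shared letters (a treatment can
belong to several groups).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RankTable", "FriedmanResult", "rank_table", "friedman",
           "chi2_sf", "posthoc_groups"]


@dataclass
class RankTable:
    """Datasets x treatments performance matrix and its within-block ranks."""

    performance: pd.DataFrame
    ranks: pd.DataFrame

    @property
    def n_blocks(self) -> int:
        return self.performance.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.performance.shape[1]


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    rank_sums: pd.Series
    groups: dict[str, str] | None = None  # treatment -> letter string


def rank_table(performance: pd.DataFrame) -> RankTable:
    """Within-dataset ranks of a datasets x treatments PVE table.

    Rank 1 is the best (highest) performance; ties get averaged ranks.
    """
    if performance.isna().any().any():
        raise ValueError("performance table has missing cells; cannot rank")
    ranks = performance.rank(axis=1, ascending=False, method="average")
    return RankTable(performance=performance.copy(), ranks=ranks)


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return float(sps.chi2.sf(x, df))


def friedman(perf: RankTable | pd.DataFrame) -> FriedmanResult:
    """Tie-corrected Friedman chi-square test over a rank table.

    With rank sums R_j, the uncorrected statistic is
    ``12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)``; ties divide it by the standard
    correction factor (equivalently: (k-1) * sum (R_j - n(k+1)/2)^2 / (A - C)
    with A the sum of squared ranks and C = n k (k+1)^2 / 4).
    """
    table = perf if isinstance(perf, RankTable) else rank_table(perf)
    n, k = table.n_blocks, table.n_treatments
    if n < 2 or k < 2:
        raise ValueError("need at least 2 datasets and 2 treatments")
    R = table.ranks.to_numpy()
    rank_sums = R.sum(axis=0)
    A = float((R ** 2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    centered = float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum())
    if A - C <= 0:  # all performances equal within every block
        statistic = 0.0
    else:
        statistic = (k - 1) * centered / (A - C)
    df = k - 1
    return FriedmanResult(statistic=statistic, df=df,
                          p_value=chi2_sf(statistic, df),
                          rank_sums=pd.Series(rank_sums,
                                              index=table.ranks.columns))


def _letters(n_groups: int) -> list[str]:
    letters = list(string.ascii_lowercase)
    while len(letters) < n_groups:
        letters += [a + b for a in string.ascii_lowercase
                    for b in string.ascii_lowercase]
    return letters[:n_groups]


def conover_lsd(result: FriedmanResult, table: RankTable, alpha: float) -> float:
    """Conover least significant difference between two rank sums."""
    n, k = table.n_blocks, table.n_treatments
    R = table.ranks.to_numpy()
    A = float((R ** 2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    if A - C <= 0:
        return np.inf  # everything tied: no difference can be significant
    t1 = result.statistic
    shrink = max(0.0, 1.0 - t1 / (n * (k - 1)))
    dfe = (n - 1) * (k - 1)
    tcrit = sps.t.ppf(1 - alpha / 2, dfe)
    return float(tcrit * np.sqrt(2.0 * n * (A - C) * shrink / dfe))


def posthoc_groups(result: FriedmanResult, table: RankTable,
                   alpha: float = 0.05) -> dict[str, str]:
    """Letter groups of statistically indistinct treatments (Conover LSD).

    Two treatments differ significantly iff their rank sums differ by more
    than the LSD; since that criterion depends only on the rank-sum gap,
    groups are maximal runs of treatments (sorted by rank sum) whose extremes
    do not differ.  Treatments share a letter iff they are non-significant.
    """
    if table.n_treatments < 2:
        raise ValueError("post hoc grouping needs at least 2 treatments")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lsd = conover_lsd(result, table, alpha)
    sums = result.rank_sums.sort_values(kind="stable")
    names = list(sums.index)
    vals = sums.to_numpy()
    k = len(names)
    # maximal intervals [i, j] with vals[j] - vals[i] <= lsd; the right end
    # j(i) is non-decreasing in i, so keeping the first i per distinct j(i)
    # yields exactly the maximal intervals
    maximal: list[tuple[int, int]] = []
    j = 0
    for i in range(k):
        j = max(j, i)
        while j + 1 < k and vals[j + 1] - vals[i] <= lsd:
            j += 1
        if not maximal or maximal[-1][1] < j:
            maximal.append((i, j))
    letters = _letters(len(maximal))
    groups = {name: "" for name in names}
    for letter, (i, j) in zip(letters, maximal):
        for idx in range(i, j + 1):
            groups[names[idx]] += letter
    result.groups = groups
    return groups
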