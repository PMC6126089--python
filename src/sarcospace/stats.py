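"""Group-comparison statistics for spacing data.

Two tests cover the two reporting situations:

* **Welch's t-test** for two groups, from raw distances or directly
  from printed ``mean ± SD, n`` summaries — the published comparisons
  are recomputable from figure legends alone.
  t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite degrees of
  freedom; two-sided p from Student's t.

* **Steel–Dwass** all-pairs nonparametric comparison for k ≥ 3 groups
  (the rank analogue of Tukey's HSD): each pair is jointly ranked with
  average ranks for ties, the rank sum is standardized with the
  tie-corrected variance, and q = |z|·√2 is referred to the
  studentized-range distribution with k groups and infinite df.  For
  k = 2 this reduces exactly to the two-sided normal-approximation
  Wilcoxon rank-sum test.  An exact per-pair permutation mode is
  provided for small groups (n ≤ 8).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError

__all__ = [
    "SummaryStats",
    "TestResult",
    "SteelDwassResult",
    "summarize",
    "welch_t",
    "steel_dwass",
]

EXACT_MAX_N = 8


@dataclass(frozen=True)
class SummaryStats:
    """mean ± sample SD with group size, the printed reporting unit."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"summary requires n >= 2, got n={self.n}")
        if self.sd < 0:
            raise InvalidInputError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    groups: tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
            "groups": list(self.groups),
        }


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample (n−1) SD and n of raw distances."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError(f"summarize requires n >= 2, got n={arr.size}")
    return SummaryStats(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def _as_summary(group) -> SummaryStats:
    if isinstance(group, SummaryStats):
        return group
    return summarize(group)


def welch_t(
    group1,
    group2,
    labels: tuple[str, str] = ("group1", "group2"),
) -> TestResult:
    """Welch's two-sample t-test, from raw values or summary statistics.

    Raw inputs are reduced to their summaries first, so raw and
    summarized calls agree exactly.  Both groups having zero variance
    and equal means is degenerate and raises
    :class:`InvalidInputError`; zero variance with different means gives
    t = ±inf, p = 0.
    """
    g1, g2 = _as_summary(group1), _as_summary(group2)
    se1, se2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    se = se1 + se2
    if se == 0:
        if g1.mean == g2.mean:
            raise InvalidInputError(
                "degenerate comparison: both groups constant with equal means"
            )
        return TestResult(
            statistic=float(np.sign(g1.mean - g2.mean) * np.inf),
            df=float(g1.n + g2.n - 2),
            p_value=0.0,
            method="welch_t",
            groups=labels,
        )
    t = (g1.mean - g2.mean) / np.sqrt(se)
    df = se**2 / (se1**2 / (g1.n - 1) + se2**2 / (g2.n - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "welch_t", labels)


# ---------------------------------------------------------------------------
# Steel-Dwass


def _pair_rank_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Rank sum of ``a`` in the joint ranking, its null mean and variance.

    Ties get average ranks; the variance carries the standard tie
    correction  V = n1·n2/(N(N−1))·Σr² − n1·n2(N+1)²/(4(N−1)).
    """
    n1, n2 = len(a), len(b)
    N = n1 + n2
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    mean = n1 * (N + 1) / 2
    var = (
        n1 * n2 / (N * (N - 1)) * float(np.sum(ranks**2))
        - n1 * n2 * (N + 1) ** 2 / (4 * (N - 1))
    )
    return w, mean, var


def _pair_z(a: np.ndarray, b: np.ndarray) -> float:
    w, mean, var = _pair_rank_statistic(a, b)
    if var <= 0:  # all values tied across both groups
        return 0.0
    return (w - mean) / np.sqrt(var)


def _exact_pair_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exhaustive permutation p for the pair's rank sum."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mean = n1 * (N + 1) / 2
    dev_obs = abs(w_obs - mean)
    hits = 0
    for idx in combinations(range(N), n1):
        w = float(ranks[list(idx)].sum())
        if abs(w - mean) >= dev_obs - 1e-12:
            hits += 1
    return hits / comb(N, n1)


@dataclass(frozen=True)
class SteelDwassResult:
    """All-pairs comparison: symmetric p matrix with unit diagonal."""

    labels: tuple[str, ...]
    p_matrix: np.ndarray  # k×k, symmetric, 1.0 on the diagonal
    statistics: np.ndarray  # pairwise z (upper = lower by symmetry of |z|)
    results: tuple[TestResult, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_matrix, index=self.labels, columns=self.labels)


def steel_dwass(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    exact: bool = False,
) -> SteelDwassResult:
    """Steel–Dwass all-pairs comparison over k >= 2 groups.

    ``exact=True`` replaces the studentized-range approximation with an
    exhaustive per-pair permutation p (two-sided on the rank sum),
    available for groups of at most 8 values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise InvalidInputError(f"steel_dwass requires >= 2 groups, got {k}")
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise InvalidInputError(f"group {i} has n={arr.size}; need n >= 2")
    if labels is None:
        labels = tuple(f"group{i+1}" for i in range(k))
    else:
        labels = tuple(str(l) for l in labels)
        if len(labels) != k:
            raise InvalidInputError("labels length must match number of groups")
    if exact and any(arr.size > EXACT_MAX_N for arr in arrays):
        raise InvalidInputError(
            f"exact mode limited to groups of n <= {EXACT_MAX_N}"
        )

    p = np.full((k, k), 1.0)  # diagonal convention: p = 1 for i = j
    z_mat = np.zeros((k, k))
    results = []
    for i, j in combinations(range(k), 2):
        z = _pair_z(arrays[i], arrays[j])
        if exact:
            pij = _exact_pair_p(arrays[i], arrays[j])
            method = "steel_dwass_exact"
        else:
            q = abs(z) * np.sqrt(2.0)
            pij = float(sps.studentized_range.sf(q, k, np.inf))
            method = "steel_dwass"
        pij = float(min(max(pij, 0.0), 1.0))
        p[i, j] = p[j, i] = pij
        z_mat[i, j] = z
        z_mat[j, i] = -z
        results.append(
            TestResult(float(z), float("inf"), pij, method, (labels[i], labels[j]))
        )
    return SteelDwassResult(labels, p, z_mat, tuple(results))
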