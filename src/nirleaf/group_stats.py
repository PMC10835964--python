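"""Rank-based group comparisons and correlation.

Implements, from their definitions, the statistics used to compare predicted
leaf-nitrogen values across treatment groups and measurement sources:
the Kruskal-Wallis H test (with tie correction and a chi-square p value),
Dunn's post-hoc z test for pairwise group differences (Holm-adjusted by
default), and the Pearson product-moment correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DegenerateInputError


def _as_groups(g) -> dict:
    if isinstance(g, Mapping):
        groups = {k: np.asarray(v, dtype=float).ravel() for k, v in g.items()}
    else:
        groups = {i: np.asarray(v, dtype=float).ravel() for i, v in enumerate(g)}
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    for k, v in groups.items():
        if v.size == 0:
            raise ConfigurationError(f"group {k!r} is empty")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError(f"group {k!r} has non-finite values")
    return groups


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tied value groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


@dataclass(frozen=True)
class KWResult:
    h_statistic: float
    df: int
    p_value: float
    tie_correction: float
    n: int
    method: str = "chi2"

    def to_dict(self) -> dict:
        return {
            "h_statistic": self.h_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "tie_correction": self.tie_correction,
            "n": self.n,
            "method": self.method,
        }


def kruskal_wallis(
    g,
    exact: bool = False,
    n_permutations: int = 9999,
    rng=None,
) -> KWResult:
    """Kruskal-Wallis H test over labelled groups.

    Mid-ranks are assigned over the pooled sample;
    ``H = 12 / (N (N+1)) * sum n_i (Rbar_i - (N+1)/2)^2`` divided by the tie
    correction ``1 - sum(t^3 - t) / (N^3 - N)``.  The p value uses the
    chi-square approximation with ``df = k - 1``; ``exact=True`` replaces it
    with a Monte Carlo permutation p value (group labels permuted over the
    pooled values), appropriate for small groups.
    """
    groups = _as_groups(g)
    sizes = np.array([v.size for v in groups.values()])
    pooled = np.concatenate(list(groups.values()))
    n_total = pooled.size
    if n_total < 3:
        raise ConfigurationError("need at least 3 observations in total")

    h, correction = _h_statistic(pooled, sizes)
    df = len(groups) - 1
    if exact:
        rng = np.random.default_rng(rng)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            h_perm, _ = _h_statistic(perm, sizes)
            if h_perm >= h - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        method = "permutation"
    else:
        p = float(stats.chi2.sf(h, df)) if h > 0 else 1.0
        method = "chi2"
    return KWResult(
        h_statistic=h,
        df=df,
        p_value=p,
        tie_correction=correction,
        n=int(n_total),
        method=method,
    )


def _h_statistic(pooled: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    h = 0.0
    start = 0
    for n_i in sizes:
        r_mean = ranks[start : start + n_i].mean()
        h += n_i * (r_mean - (n_total + 1) / 2.0) ** 2
        start += n_i
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0.0:
        # all observations tied: H is 0 by construction; guard 0/0
        return 0.0, 1.0
    return float(h / correction), float(correction)


@dataclass
class DunnResult:
    """Pairwise Dunn z statistics; ``table`` has one row per unordered
    group pair with raw and adjusted two-sided p values."""

    table: pd.DataFrame
    adjustment: str

    def to_dict(self) -> dict:
        return {
            "adjustment": self.adjustment,
            "pairs": self.table.to_dict(orient="records"),
        }


def dunn_test(g, adjustment: str = "holm") -> DunnResult:
    """Dunn's post-hoc rank test for all group pairs.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)`` the tie term; two-sided p values from the
    standard normal, adjusted across all pairs (Holm by default, "none" for
    raw p values).
    """
    if adjustment not in ("holm", "none"):
        raise ConfigurationError(f"unknown adjustment {adjustment!r}")
    groups = _as_groups(g)
    labels = list(groups.keys())
    pooled = np.concatenate([groups[k] for k in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for k in labels:
        n_i = groups[k].size
        mean_ranks[k] = ranks[start : start + n_i].mean()
        sizes[k] = n_i
        start += n_i

    var_term = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_total - 1))
    rows = []
    for a, b in combinations(labels, 2):
        denom = np.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if denom == 0.0:
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / denom
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group_i": a, "group_j": b, "z_statistic": float(z), "p_raw": p_raw})
    table = pd.DataFrame(rows)
    if adjustment == "holm":
        table["p_adjusted"] = multipletests(table["p_raw"], method="holm")[1]
    else:
        table["p_adjusted"] = table["p_raw"]
    return DunnResult(table=table, adjustment=adjustment)


def pearson_cor(x: Sequence, y: Sequence) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ConfigurationError("x and y lengths differ")
    if x.size < 3:
        raise ConfigurationError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("correlation undefined for constant input")
    return float(np.dot(xc, yc) / (sx * sy))
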