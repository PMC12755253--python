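"""Nonparametric group comparison and Likert reader-study analysis.

Two families of analysis live here:

* metric comparison across methods — Kruskal-Wallis omnibus test with tie
  correction, followed by Dunn's pairwise z-tests with Holm step-down
  adjustment of the p-values;
* subjective preference analysis of 5-point Likert scores — for each pair
  of methods, every scoring instance (dataset x reader x case) contributes
  a win, a loss or a tie; the preference rate is wins/(wins+losses) with
  ties excluded, and its significance is a two-sided exact binomial test
  against a 0.5 null.

The Kruskal-Wallis and Dunn statistics are computed from first principles
(rank sums with tie correction) so they can be cross-checked against
independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

LIKERT_COLUMNS = ("dataset", "reader", "case", "method", "score")
INSTANCE_COLUMNS = ["dataset", "reader", "case"]

__all__ = [
    "PreferenceSummary",
    "GroupComparisonResult",
    "AllTiesError",
    "validate_likert_table",
    "kruskal_wallis",
    "dunn_holm",
    "holm_adjust",
    "likert_winner",
    "preference_rate",
    "exact_binomial_two_sided",
    "preference_analysis",
    "LIKERT_COLUMNS",
]


class AllTiesError(ValueError):
    """Raised when a preference rate is requested but every instance tied."""


@dataclass
class PreferenceSummary:
    method_a: str
    method_b: str
    wins_a: int
    wins_b: int
    ties: int
    preference_rate: float
    p_value: float


@dataclass
class GroupComparisonResult:
    metric: str
    kruskal_H: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: method_a, method_b, z, p_raw, p_holm


def _ranked(groups: Sequence[Sequence[float]]) -> Tuple[List[np.ndarray], np.ndarray]:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    out, start = [], 0
    for g in groups:
        out.append(ranks[start:start + len(g)])
        start += len(g)
    return out, pooled


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Rank-based H statistic with tie correction; p from chi-square (k-1 df)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    rank_groups, pooled = _ranked(groups)
    n = pooled.size
    h = 12.0 / (n * (n + 1)) * sum(rg.sum() ** 2 / rg.size for rg in rank_groups) \
        - 3.0 * (n + 1)
    ties = _tie_counts(pooled)
    correction = 1.0 - float(np.sum(ties ** 3 - ties)) / (n ** 3 - n)
    if correction == 0.0:  # every pooled value identical: no information
        return 0.0, 1.0
    h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down: sort ascending, multiply k-th by (m-k+1), running max, cap 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def dunn_holm(groups: Sequence[Sequence[float]],
              labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Dunn's pairwise z-tests (tie-corrected, normal approximation) + Holm.

    Returns a table with one row per unordered pair: z, raw two-sided p and
    Holm-adjusted p.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    rank_groups, pooled = _ranked(groups)
    n = pooled.size
    ties = _tie_counts(pooled)
    tie_term = float(np.sum(ties ** 3 - ties)) / (12.0 * (n - 1)) if n > 1 else 0.0
    variance_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = [rg.mean() for rg in rank_groups]
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(variance_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"method_a": labels[i], "method_b": labels[j], "z": z,
                     "p_raw": min(1.0, p_raw)})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    return table


def likert_winner(s_a: int, s_b: int) -> str:
    """'a' if s_a > s_b, 'b' if s_b > s_a, else 'tie'."""
    for s in (s_a, s_b):
        if not 1 <= s <= 5:
            raise ValueError(f"Likert scores must lie in [1, 5], got {s}")
    if s_a > s_b:
        return "a"
    if s_b > s_a:
        return "b"
    return "tie"


def preference_rate(wins_a: int, wins_b: int) -> float:
    """``W_a / (W_a + W_b)``, ties excluded."""
    if wins_a < 0 or wins_b < 0:
        raise ValueError("win counts must be non-negative")
    if wins_a + wins_b == 0:
        raise AllTiesError("all instances tied; preference rate undefined")
    return wins_a / (wins_a + wins_b)


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value by tail doubling.

    For the symmetric null ``p0 = 0.5`` this is
    ``min(1, 2 P(X >= max(k, n - k)))`` with X ~ Binomial(n, 1/2), computed
    as an exact rational sum.  (At p0 = 0.5 tail doubling coincides with the
    minimum-likelihood definition.)
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid k={k}, n={n}")
    if p0 != 0.5:
        raise ValueError("only the symmetric null p0 = 0.5 is supported")
    k_hi = max(k, n - k)
    tail = sum(comb(n, i) for i in range(k_hi, n + 1))
    return min(1.0, 2.0 * tail / 2 ** n)


def validate_likert_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format score table invariants and return it typed."""
    missing = [c for c in LIKERT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Likert table is missing columns {missing}")
    table = table.copy()
    table["score"] = table["score"].astype(int)
    if not table["score"].between(1, 5).all():
        raise ValueError("Likert scores must be integers in [1, 5]")
    dup = table.duplicated(subset=INSTANCE_COLUMNS + ["method"])
    if dup.any():
        raise ValueError("duplicate (instance, method) rows in Likert table")
    return table


def preference_analysis(table: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Full pairwise preference analysis of a long-format Likert table.

    Returns a dict with:

    * ``pairs`` — one row per method pair: wins, losses, ties, preference
      rate and exact binomial p-value (pairs with no shared instances are
      flagged with NaN statistics and excluded from the overall rates);
    * ``overall`` — per-method rate aggregating wins and losses across all
      of its head-to-head comparisons;
    * ``descriptives`` — mean +/- sample SD, median and IQR per method;
    * ``matrix`` — preference-rate matrix (row preferred over column), with
      0.5 on the diagonal by convention.
    """
    table = validate_likert_table(table)
    methods = sorted(table["method"].unique())
    wide = table.pivot_table(index=INSTANCE_COLUMNS, columns="method",
                             values="score", aggfunc="first")

    pair_rows: List[dict] = []
    wins_total = {m: 0 for m in methods}
    losses_total = {m: 0 for m in methods}
    matrix = pd.DataFrame(np.full((len(methods), len(methods)), np.nan),
                          index=methods, columns=methods)
    np.fill_diagonal(matrix.values, 0.5)

    for a, b in combinations(methods, 2):
        shared = wide[[a, b]].dropna()
        if shared.empty:
            pair_rows.append({"method_a": a, "method_b": b, "wins_a": 0, "wins_b": 0,
                              "ties": 0, "preference_rate": np.nan, "p_value": np.nan,
                              "shared_instances": 0})
            continue
        outcomes = [likert_winner(int(sa), int(sb))
                    for sa, sb in zip(shared[a], shared[b])]
        w_a = outcomes.count("a")
        w_b = outcomes.count("b")
        ties = outcomes.count("tie")
        try:
            rate = preference_rate(w_a, w_b)
            p = exact_binomial_two_sided(w_a, w_a + w_b)
        except AllTiesError:
            rate, p = np.nan, np.nan
        pair_rows.append({"method_a": a, "method_b": b, "wins_a": w_a, "wins_b": w_b,
                          "ties": ties, "preference_rate": rate, "p_value": p,
                          "shared_instances": len(shared)})
        wins_total[a] += w_a
        losses_total[a] += w_b
        wins_total[b] += w_b
        losses_total[b] += w_a
        if not np.isnan(rate):
            matrix.loc[a, b] = rate
            matrix.loc[b, a] = 1.0 - rate

    overall = pd.DataFrame({
        "method": methods,
        "wins": [wins_total[m] for m in methods],
        "losses": [losses_total[m] for m in methods],
    })
    denom = overall["wins"] + overall["losses"]
    overall["overall_rate"] = np.where(denom > 0, overall["wins"] / denom, np.nan)

    scores = table.groupby("method")["score"]
    descriptives = pd.DataFrame({
        "mean": scores.mean(),
        "sd": scores.std(),  # sample SD
        "median": scores.median(),
        "q1": scores.quantile(0.25),
        "q3": scores.quantile(0.75),
    }).reset_index()
    descriptives["iqr"] = descriptives["q3"] - descriptives["q1"]

    return {"pairs": pd.DataFrame(pair_rows), "overall": overall,
            "descriptives": descriptives, "matrix": matrix}
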