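"""Between-area and within-area comparisons of gender inequality scores.

Between areas: mean scores per area type (metropolitan, mid-sized city,
rural) compared with the Kruskal-Wallis omnibus test; where the omnibus is
significant, pair-by-pair Mann-Whitney U tests with a Bonferroni adjustment.

Within areas: Spearman correlation of each indicator's inequality score with
the DA's overall (both-sex) level of the same indicator; indicators with
|r| >= 0.4 are stratified into population-weighted tertiles of the overall
level, and mean scores are tabulated per (tertile x area type) with a
Kruskal-Wallis test across tertiles within each area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import AREA_TYPES, INDICATORS, IndicatorDefinition, overall_level_table

__all__ = [
    "kruskal_wallis",
    "pairwise_mwu_bonferroni",
    "spearman_r",
    "select_correlated_indicators",
    "population_weighted_tertiles",
    "tertile_score_summary",
    "between_area_comparison",
    "score_level_correlations",
    "ComparisonResult",
    "TertileAssignment",
]

TERTILE_LABELS = ("low", "intermediate", "high")


@dataclass
class ComparisonResult:
    """Omnibus and (gated) pairwise rank tests for one indicator's scores."""

    indicator: str
    group_stats: pd.DataFrame  # columns: group, n, mean, sd
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["group_a", "group_b", "u_statistic", "p_raw", "p_adjusted"]
        )
    )


@dataclass
class TertileAssignment:
    """Population-weighted tertile memberships for one indicator."""

    indicator: str
    assignments: pd.DataFrame  # columns: da_id, tertile
    boundaries: tuple[float, float]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate rank-constant input (all pooled values identical) has no rank
    variation: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("empty group")
    if sum(len(g) for g in arrays) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_mwu_bonferroni(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise Mann-Whitney U tests with Bonferroni adjustment.

    U is reported for the first group of each pair; p-values use the
    tie-corrected normal approximation (sample sizes here are hundreds to
    thousands of DAs) and are adjusted as min(1, n_pairs * p).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(combinations(labels, 2))
    rows = []
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError("empty group")
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "group_a": a,
            "group_b": b,
            "u_statistic": u,
            "p_raw": p,
            "p_adjusted": min(1.0, len(pairs) * p),
        })
    return pd.DataFrame(rows)


def spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns NaN for a constant input vector, where rank correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.spearmanr(x, y).statistic
    return float(r)


def select_correlated_indicators(correlations: dict[str, float],
                                 threshold: float = 0.4) -> list[str]:
    """Indicators whose score/overall-level correlation satisfies |r| >= threshold.

    The magnitude is used because strong negative correlations (income,
    unpaid housework) are as informative as positive ones; NaN correlations
    never qualify.
    """
    return [name for name, r in correlations.items()
            if not np.isnan(r) and abs(r) >= threshold]


def population_weighted_tertiles(table: pd.DataFrame,
                                 indicator: IndicatorDefinition,
                                 ) -> TertileAssignment:
    """Stratify DAs into population-weighted tertiles of the overall level.

    DAs are sorted by overall (both-sex) indicator level, ties broken by
    da_id; cumulative population is computed, and cuts fall at the first DAs
    whose cumulative totals reach 1/3 and 2/3 of the total population (the
    straddling DA goes to the lower tertile).  Each tertile's population is
    therefore within one DA's population of total/3.  Boundaries are the
    overall levels at the cut points, on the pooled DA universe (all area
    types together).
    """
    levels = overall_level_table(table, (indicator,))
    merged = levels.merge(table[["da_id", "pop_f", "pop_m"]], on="da_id")
    if len(merged) < 3:
        raise ValueError(f"{indicator.name}: need >= 3 DAs with a defined level")
    merged["pop"] = merged["pop_f"] + merged["pop_m"]
    merged = merged.sort_values(["level", "da_id"], kind="mergesort").reset_index(drop=True)
    cum = merged["pop"].cumsum().to_numpy(float)
    total = cum[-1]
    # first-reach rule: the DA that crosses a third stays in the lower tertile
    idx1 = int(np.searchsorted(cum, total / 3.0))
    idx2 = int(np.searchsorted(cum, 2.0 * total / 3.0))
    idx2 = max(idx2, idx1)
    tertile = np.full(len(merged), "high", dtype=object)
    tertile[: idx1 + 1] = "low"
    tertile[idx1 + 1: idx2 + 1] = "intermediate"
    boundaries = (float(merged["level"].iloc[idx1]),
                  float(merged["level"].iloc[min(idx2, len(merged) - 1)]))
    assignments = pd.DataFrame({
        "da_id": merged["da_id"],
        "indicator": indicator.name,
        "tertile": tertile,
    })
    return TertileAssignment(indicator.name, assignments, boundaries)


def tertile_score_summary(scores: pd.DataFrame,
                          assignment: TertileAssignment,
                          area_types: pd.DataFrame,
                          ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean score per (tertile x area type) plus per-area Kruskal-Wallis p.

    ``scores`` is the tidy score frame; ``area_types`` maps da_id to
    area_type.  The grid has tertiles as rows and area types as columns;
    the p-values compare the three tertiles within each area type.  Empty
    cells are NaN, and an area with fewer than two nonempty tertiles has its
    test skipped with a warning.
    """
    sub = scores.loc[scores["indicator"] == assignment.indicator,
                     ["da_id", "score"]]
    merged = sub.merge(assignment.assignments[["da_id", "tertile"]], on="da_id")
    merged = merged.merge(area_types[["da_id", "area_type"]], on="da_id")

    grid = (merged.pivot_table(index="tertile", columns="area_type",
                               values="score", aggfunc="mean")
            .reindex(index=list(TERTILE_LABELS), columns=list(AREA_TYPES)))
    grid.columns.name = None
    grid.index.name = "tertile"

    kw_p: dict[str, float] = {}
    for area in AREA_TYPES:
        area_scores = merged.loc[merged["area_type"] == area]
        groups = [area_scores.loc[area_scores["tertile"] == t, "score"].to_numpy()
                  for t in TERTILE_LABELS]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            warnings.warn(
                f"{assignment.indicator}/{area}: fewer than 2 nonempty tertiles; "
                "Kruskal-Wallis skipped", stacklevel=2)
            kw_p[area] = float("nan")
            continue
        _, p = kruskal_wallis(groups)
        kw_p[area] = p
    return grid, kw_p


def between_area_comparison(scores: pd.DataFrame,
                            area_types: pd.DataFrame,
                            definitions: tuple[IndicatorDefinition, ...] = INDICATORS,
                            alpha: float = 0.05,
                            force_pairwise: bool = False,
                            ) -> list[ComparisonResult]:
    """Compare score distributions across area types for each indicator.

    Pairwise Mann-Whitney tests are run only when the Kruskal-Wallis omnibus
    is significant at ``alpha`` (override with ``force_pairwise``).
    """
    merged = scores.merge(area_types[["da_id", "area_type"]], on="da_id")
    results = []
    for ind in definitions:
        sub = merged.loc[merged["indicator"] == ind.name]
        groups = {a: sub.loc[sub["area_type"] == a, "score"].to_numpy(float)
                  for a in AREA_TYPES}
        groups = {a: g for a, g in groups.items() if len(g) > 0}
        if len(groups) < 2:
            warnings.warn(f"{ind.name}: fewer than 2 nonempty area types; skipped",
                          stacklevel=2)
            continue
        stats_rows = [{"group": a, "n": len(g), "mean": float(np.mean(g)),
                       "sd": float(np.std(g, ddof=1)) if len(g) > 1 else 0.0}
                      for a, g in groups.items()]
        h, p = kruskal_wallis(list(groups.values()))
        res = ComparisonResult(
            indicator=ind.name,
            group_stats=pd.DataFrame(stats_rows),
            h_statistic=h,
            p_value=p,
        )
        if p < alpha or force_pairwise:
            res.pairwise = pairwise_mwu_bonferroni(groups)
        results.append(res)
    return results


def score_level_correlations(table: pd.DataFrame,
                             scores: pd.DataFrame,
                             definitions: tuple[IndicatorDefinition, ...] = INDICATORS,
                             ) -> dict[str, float]:
    """Spearman r between each indicator's score and its overall DA level."""
    levels = overall_level_table(table, definitions)
    out: dict[str, float] = {}
    for ind in definitions:
        s = scores.loc[scores["indicator"] == ind.name, ["da_id", "score"]]
        l = levels.loc[levels["indicator"] == ind.name, ["da_id", "level"]]
        merged = s.merge(l, on="da_id")
        if len(merged) < 3:
            out[ind.name] = float("nan")
            continue
        out[ind.name] = spearman_r(merged["level"].to_numpy(),
                                   merged["score"].to_numpy())
    return out
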