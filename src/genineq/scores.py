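"""Gender inequality scores per (DA, indicator) and their summaries.

The score is ``female / (female + male)`` applied to the two sex-specific
values of an indicator (proportions, or mean incomes for the income
indicator).  0.5 is perfect equality; values below 0.5 indicate
male-dominant, above 0.5 female-dominant inequality, with larger deviations
meaning more inequality.  When both sex values are exactly zero there is by
definition no gender difference and the score is attributed as 0.5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .indicators import INDICATORS, IndicatorDefinition, derive_flags

__all__ = ["inequality_score", "score_table", "summarize_scores"]

CONVENTION_NONE = "none"
CONVENTION_BOTH_ZERO = "both_zero"


def inequality_score(female_value: float, male_value: float) -> float:
    """female / (female + male); 0.5 by attribution when both are zero.

    Inputs are nonnegative: sex-specific proportions in [0, 1], or mean
    incomes in thousand CAD.  A one-sided zero yields the boundary score 0
    or 1 — a legitimate, maximal inequality.
    """
    if female_value < 0 or male_value < 0:
        raise ValueError(
            f"values must be nonnegative, got ({female_value}, {male_value})"
        )
    total = female_value + male_value
    if total == 0:
        return 0.5
    return female_value / total


def score_array(female: np.ndarray, male: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized score with the both-zero convention.

    Returns (scores, both_zero_mask).  NaN inputs propagate to NaN scores.
    """
    female = np.asarray(female, dtype=float)
    male = np.asarray(male, dtype=float)
    total = female + male
    both_zero = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(both_zero, 0.5, female / np.where(both_zero, 1.0, total))
    return scores, both_zero


def _eligible_mask(table: pd.DataFrame, ind: IndicatorDefinition,
                   flags: pd.DataFrame) -> pd.Series:
    """DAs for which a score for this indicator is defined.

    Requires positive denominators for both sexes (a zero denominator for
    one sex makes that sex's proportion undefined, so the cell is skipped),
    and excludes zero-labour-force DAs from labour-force indicators.
    """
    if ind.kind == "mean_value":
        ok = table["income_mean_f"].notna() & table["income_mean_m"].notna()
        ok &= (table["pop_f"] > 0) & (table["pop_m"] > 0)
    else:
        n = ind.name
        ok = (table[f"{n}_den_f"] > 0) & (table[f"{n}_den_m"] > 0)
        ok &= table[f"{n}_num_f"].notna() & table[f"{n}_num_m"].notna()
    if ind.requires_labour_force:
        ok &= ~flags["zero_labour_force"]
    return ok


def sex_value_arrays(table: pd.DataFrame, ind: IndicatorDefinition
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-DA female and male values of an indicator (proportions or incomes)."""
    if ind.kind == "mean_value":
        return (table["income_mean_f"].to_numpy(float),
                table["income_mean_m"].to_numpy(float))
    n = ind.name
    with np.errstate(invalid="ignore", divide="ignore"):
        p_f = table[f"{n}_num_f"].to_numpy(float) / table[f"{n}_den_f"].to_numpy(float)
        p_m = table[f"{n}_num_m"].to_numpy(float) / table[f"{n}_den_m"].to_numpy(float)
    return p_f, p_m


def score_table(table: pd.DataFrame,
                definitions: tuple[IndicatorDefinition, ...] = INDICATORS,
                ) -> pd.DataFrame:
    """Score every eligible (DA, indicator) cell of an already-filtered table.

    Returns a tidy frame (da_id, indicator, score, convention_applied).
    Labour-force indicators are skipped for zero-labour-force DAs, and cells
    where exactly one sex has a zero denominator are skipped (that sex's
    proportion is undefined); skipped cells are simply absent.
    """
    flags = derive_flags(table)
    if "zero_labour_force" in table.columns:
        flags["zero_labour_force"] = table["zero_labour_force"].astype(bool)
    pieces = []
    for ind in definitions:
        ok = _eligible_mask(table, ind, flags)
        sub = table.loc[ok]
        f, m = sex_value_arrays(sub, ind)
        s, both_zero = score_array(f, m)
        pieces.append(pd.DataFrame({
            "da_id": sub["da_id"].to_numpy(),
            "indicator": ind.name,
            "score": s,
            "convention_applied": np.where(both_zero, CONVENTION_BOTH_ZERO,
                                           CONVENTION_NONE),
        }))
    return pd.concat(pieces, ignore_index=True)


def summarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator descriptive statistics of the inequality scores.

    Mean, SD (n-1 denominator), median and quartiles (median-unbiased
    linear interpolation) plus the DA count; one row per indicator, in
    canonical indicator order.  Empty groups are omitted with a warning.
    """
    rows = []
    order = [i.name for i in INDICATORS if i.name in set(scores["indicator"])]
    for name in order:
        s = scores.loc[scores["indicator"] == name, "score"].to_numpy(float)
        if len(s) == 0:
            warnings.warn(f"no scores for indicator {name!r}; omitted", stacklevel=2)
            continue
        q1, med, q3 = np.quantile(s, [0.25, 0.5, 0.75], method="median_unbiased")
        rows.append({
            "indicator": name,
            "mean": float(np.mean(s)),
            "sd": float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "n_das": len(s),
        })
    return pd.DataFrame(rows)
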