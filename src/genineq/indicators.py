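"""Census indicator definitions, exclusion rules, and sex-specific proportions.

The unit of analysis is the dissemination area (DA), the smallest standard
Canadian census geography (~400-700 residents), used as a neighbourhood proxy.
Each DA row carries, per indicator and sex, an aggregate numerator and
denominator (person counts), plus per-sex mean employment income in thousand
CAD.  Twelve indicators span five dimensions of gender inequality:
demographic/household characteristics, education, income, work and leisure,
and political participation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AREA_TYPES = ("metropolitan", "mid_sized", "rural")

DIMENSIONS = (
    "demographic_household",
    "education",
    "income",
    "work_leisure",
    "political",
)

#: Column name of the mean-value (income) indicator's per-sex values.
INCOME_COLUMNS = ("income_mean_f", "income_mean_m")


class InputError(ValueError):
    """Malformed input table (duplicate ids, missing columns, ...)."""


class UndefinedProportionError(ValueError):
    """A proportion was requested for a zero denominator."""


@dataclass(frozen=True)
class IndicatorDefinition:
    """One census-derived gender-inequality indicator.

    Parameters
    ----------
    name
        Identifier used in column names and tidy outputs.
    dimension
        One of :data:`DIMENSIONS`.
    kind
        ``"proportion"`` (numerator/denominator per sex) or ``"mean_value"``
        (per-sex mean, used only by average employment income).
    age_floor
        Lower age bound of the census universe (informational; denominators
        in the input are assumed to already embody it).
    requires_labour_force
        True for indicators undefined in DAs with nobody in the labour force.
    full_sample
        True for items enumerated from 100% of households (demographic items);
        False for the 20%-sample long-form items.
    """

    name: str
    dimension: str
    kind: str = "proportion"
    age_floor: int | None = None
    requires_labour_force: bool = False
    full_sample: bool = False

    @property
    def columns(self) -> list[str]:
        """Input columns holding this indicator's per-sex values."""
        if self.kind == "mean_value":
            return list(INCOME_COLUMNS)
        n = self.name
        return [f"{n}_num_f", f"{n}_num_m", f"{n}_den_f", f"{n}_den_m"]


INDICATORS: tuple[IndicatorDefinition, ...] = (
    IndicatorDefinition("divorce", "demographic_household", age_floor=20, full_sample=True),
    IndicatorDefinition("single_headed_households", "demographic_household", full_sample=True),
    IndicatorDefinition("university_certification", "education", age_floor=20),
    IndicatorDefinition("no_high_school_diploma", "education", age_floor=20),
    IndicatorDefinition("avg_employment_income", "income", kind="mean_value", age_floor=15),
    IndicatorDefinition("labour_force_participation", "work_leisure", age_floor=15,
                        requires_labour_force=True),
    IndicatorDefinition("employment_rate", "work_leisure", age_floor=15,
                        requires_labour_force=True),
    IndicatorDefinition("managerial_positions", "work_leisure", age_floor=15),
    IndicatorDefinition("unpaid_elderly_care", "work_leisure", age_floor=25),
    IndicatorDefinition("unpaid_child_care", "work_leisure", age_floor=25),
    IndicatorDefinition("unpaid_housework", "work_leisure", age_floor=25),
    IndicatorDefinition("decision_making_positions", "political", age_floor=15),
)

INDICATOR_NAMES = tuple(ind.name for ind in INDICATORS)
PROPORTION_INDICATORS = tuple(ind for ind in INDICATORS if ind.kind == "proportion")


def get_indicator(name: str) -> IndicatorDefinition:
    for ind in INDICATORS:
        if ind.name == name:
            return ind
    raise KeyError(f"unknown indicator: {name!r}")


def census_columns() -> list[str]:
    """Full input CSV schema, in canonical order."""
    cols = ["da_id", "area_type", "pop_f", "pop_m"]
    for ind in PROPORTION_INDICATORS:
        cols.extend(ind.columns)
    cols.extend(INCOME_COLUMNS)
    return cols


#: Numeric columns that must be present and non-missing for a DA to be usable.
def required_value_columns() -> list[str]:
    return [c for c in census_columns() if c not in ("da_id", "area_type")]


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

def derive_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Derive exclusion flags from the data (never trusted from input).

    Returns a frame indexed like ``table`` with boolean columns
    ``missing_data``, ``single_sex`` and ``zero_labour_force``.
    A DA has zero labour force when its labour-force-participation
    numerators sum to zero (nobody in the labour force).
    """
    value_cols = [c for c in required_value_columns() if c in table.columns]
    missing = table[value_cols].isna().any(axis=1)
    single = (table["pop_f"] == 0) | (table["pop_m"] == 0)
    lf = table[["labour_force_participation_num_f",
                "labour_force_participation_num_m"]].sum(axis=1, min_count=1)
    zero_lf = lf.fillna(np.inf) == 0
    return pd.DataFrame(
        {"missing_data": missing, "single_sex": single, "zero_labour_force": zero_lf}
    )


@dataclass
class ExclusionLog:
    """Per-DA exclusion records plus bookkeeping counts.

    ``records`` has columns (da_id, reason) with reasons ``missing_data``,
    ``single_sex`` (both removed from the table) and ``zero_labour_force``
    (retained, but ineligible for labour-force indicators).  Reasons are
    mutually exclusive: missing data takes precedence over single-sex.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["da_id", "reason"])
    )
    n_input: int = 0
    n_retained: int = 0

    def count(self, reason: str) -> int:
        return int((self.records["reason"] == reason).sum())

    @property
    def n_missing(self) -> int:
        return self.count("missing_data")

    @property
    def n_single_sex(self) -> int:
        return self.count("single_sex")

    @property
    def n_zero_labour(self) -> int:
        return self.count("zero_labour_force")


def filter_das(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the global DA exclusion rules.

    DAs with any missing required field or an exclusively single-sex
    population are removed (gender inequality scores cannot be computed for
    them).  DAs with zero labour force are retained but flagged: they are
    excluded only from analyses of labour-force indicators.  Missing data
    takes precedence over single-sex when a DA qualifies for both, so the
    per-reason counts decompose deterministically.
    """
    if table["da_id"].duplicated().any():
        dupes = table.loc[table["da_id"].duplicated(), "da_id"].tolist()
        raise InputError(f"duplicate da_id values: {dupes[:5]}")

    flags = derive_flags(table)
    missing = flags["missing_data"]
    single = flags["single_sex"] & ~missing
    removed = missing | single

    recs = []
    for reason, mask in (("missing_data", missing), ("single_sex", single)):
        for da in table.loc[mask, "da_id"]:
            recs.append((da, reason))

    retained = table.loc[~removed].copy()
    zero_lf = flags.loc[~removed, "zero_labour_force"]
    retained["zero_labour_force"] = zero_lf.to_numpy()
    for da in retained.loc[retained["zero_labour_force"], "da_id"]:
        recs.append((da, "zero_labour_force"))

    log = ExclusionLog(
        records=pd.DataFrame(recs, columns=["da_id", "reason"]),
        n_input=len(table),
        n_retained=len(retained),
    )
    return retained.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def sex_proportion(record: pd.Series, indicator: IndicatorDefinition, sex: str) -> float:
    """Sex-specific proportion num/den for one DA record.

    Raises :class:`UndefinedProportionError` on a zero denominator (no
    eligible people of that sex); the caller decides how to handle it.
    """
    if indicator.kind != "proportion":
        raise ValueError(f"{indicator.name} is not a proportion indicator")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    suffix = "f" if sex == "female" else "m"
    num = record[f"{indicator.name}_num_{suffix}"]
    den = record[f"{indicator.name}_den_{suffix}"]
    if not den > 0:
        raise UndefinedProportionError(
            f"{indicator.name}: zero {sex} denominator in DA {record.get('da_id')}"
        )
    return float(num) / float(den)


def overall_proportion(record: pd.Series, indicator: IndicatorDefinition) -> float:
    """Combined-sex level of an indicator in one DA.

    Proportions: (num_f + num_m) / (den_f + den_m).  Income: the
    population-weighted mean of the two sex mean incomes.
    """
    if indicator.kind == "mean_value":
        pop_f, pop_m = float(record["pop_f"]), float(record["pop_m"])
        if pop_f + pop_m <= 0:
            raise UndefinedProportionError(f"DA {record.get('da_id')}: zero population")
        return (pop_f * float(record["income_mean_f"])
                + pop_m * float(record["income_mean_m"])) / (pop_f + pop_m)
    n = indicator.name
    den = float(record[f"{n}_den_f"]) + float(record[f"{n}_den_m"])
    if not den > 0:
        raise UndefinedProportionError(
            f"{indicator.name}: zero combined denominator in DA {record.get('da_id')}"
        )
    return (float(record[f"{n}_num_f"]) + float(record[f"{n}_num_m"])) / den


def overall_level_table(table: pd.DataFrame,
                        definitions: tuple[IndicatorDefinition, ...] = INDICATORS,
                        ) -> pd.DataFrame:
    """Vectorized overall levels: tidy frame (da_id, indicator, level).

    DAs with an undefined level (zero combined denominator or zero
    population) are omitted with a warning.
    """
    pieces = []
    for ind in definitions:
        if ind.kind == "mean_value":
            w = table["pop_f"] + table["pop_m"]
            level = (table["pop_f"] * table["income_mean_f"]
                     + table["pop_m"] * table["income_mean_m"]) / w.where(w > 0)
        else:
            n = ind.name
            den = table[f"{n}_den_f"] + table[f"{n}_den_m"]
            level = (table[f"{n}_num_f"] + table[f"{n}_num_m"]) / den.where(den > 0)
        sub = pd.DataFrame(
            {"da_id": table["da_id"], "indicator": ind.name, "level": level}
        )
        n_undef = int(sub["level"].isna().sum())
        if n_undef:
            warnings.warn(
                f"{ind.name}: {n_undef} DA(s) with undefined overall level omitted",
                stacklevel=2,
            )
            sub = sub.dropna(subset=["level"])
        pieces.append(sub)
    return pd.concat(pieces, ignore_index=True)
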