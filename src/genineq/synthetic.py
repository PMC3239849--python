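"""Seeded synthetic DA-level aggregate census generator.

Emulates the structure of a provincial dissemination-area extract: ~400-700
residents per DA, three area types, 100%-sample demographic items versus
20%-sample long-form items, sex-specific indicator rates near published
provincial means, and the exclusion pathologies downstream filters must
handle (missing data, single-sex DAs, DAs with zero labour force).

Ground truth is controllable: per-indicator sex rates set the level of
gender inequality, and ``heterogeneity_sd`` (a logit-scale between-DA SD of
the female rate) sets spatial heterogeneity — zero yields the homogeneous
null under which score variation reflects sampling noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .indicators import (
    AREA_TYPES,
    INCOME_COLUMNS,
    PROPORTION_INDICATORS,
    census_columns,
)

__all__ = [
    "ConfigError",
    "SexRates",
    "IncomeParams",
    "GeneratorConfig",
    "DEFAULT_SEX_RATES",
    "generate_census",
    "assign_area_types",
]


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass(frozen=True)
class SexRates:
    """True underlying indicator rates per sex."""

    p_female: float
    p_male: float

    def __post_init__(self) -> None:
        for name, p in (("p_female", self.p_female), ("p_male", self.p_male)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class IncomeParams:
    """Per-sex mean employment income model (thousand CAD).

    A DA's sex mean income is drawn as
    ``mean + Normal(0, between_da_sd) + Normal(0, person_sd / sqrt(pop_sex))``:
    real between-DA variation plus the sampling noise of averaging
    ``pop_sex`` individual incomes.  ``between_da_sd = 0`` gives the
    homogeneous income null.
    """

    mean_f: float = 22.0
    mean_m: float = 32.9
    person_sd_f: float = 15.0
    person_sd_m: float = 25.0
    between_da_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("person_sd_f", "person_sd_m", "between_da_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


# Sex-specific rates near the published provincial means for each indicator
# (female, male), e.g. divorce 11.2% vs 10.1%, labour force participation
# 57.0% vs 69.8%.
DEFAULT_SEX_RATES: dict[str, SexRates] = {
    "divorce": SexRates(0.112, 0.101),
    "single_headed_households": SexRates(0.137, 0.034),
    "university_certification": SexRates(0.147, 0.165),
    "no_high_school_diploma": SexRates(0.311, 0.308),
    "labour_force_participation": SexRates(0.570, 0.698),
    "employment_rate": SexRates(0.533, 0.643),
    "managerial_positions": SexRates(0.065, 0.114),
    "unpaid_elderly_care": SexRates(0.081, 0.045),
    "unpaid_child_care": SexRates(0.345, 0.257),
    "unpaid_housework": SexRates(0.798, 0.591),
    "decision_making_positions": SexRates(0.023, 0.017),
}

# Fraction of a DA's sex population in each indicator's census universe
# (age >= 15 / 20 / 25; None = household reference persons).
_AGE_FRACTIONS = {15: 0.80, 20: 0.75, 25: 0.70, None: 0.45}


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic census configuration.

    Defaults mirror the study composition: 11,612 DAs of 400-700 residents,
    12 DAs with missing data, 36 single-sex DAs, 15 DAs with zero labour
    force, and 20%-sample denominators for long-form items.
    """

    n_das: int = 11612
    population_range: tuple[int, int] = (400, 700)
    area_type_shares: tuple[float, float, float] = (0.6, 0.2, 0.2)
    sex_rates: dict[str, SexRates] = field(
        default_factory=lambda: dict(DEFAULT_SEX_RATES)
    )
    heterogeneity_sd: float = 0.2
    income_params: IncomeParams = field(default_factory=IncomeParams)
    n_missing: int = 12
    n_single_sex: int = 36
    n_zero_labour: int = 15
    sampling_fraction_20pct: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_das <= 0:
            raise ConfigError(f"n_das must be positive, got {self.n_das}")
        lo, hi = self.population_range
        if lo < 2 or hi < lo:
            raise ConfigError(
                f"population_range must satisfy 2 <= lo <= hi, got {self.population_range}"
            )
        shares = np.asarray(self.area_type_shares, dtype=float)
        if shares.shape != (3,) or (shares < 0).any() or abs(shares.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"area_type_shares must be 3 nonnegative weights summing to 1, "
                f"got {self.area_type_shares}"
            )
        if self.heterogeneity_sd < 0:
            raise ConfigError("heterogeneity_sd must be nonnegative")
        if not 0.0 < self.sampling_fraction_20pct <= 1.0:
            raise ConfigError(
                f"sampling_fraction_20pct must be in (0, 1], got {self.sampling_fraction_20pct}"
            )
        for name in ("n_missing", "n_single_sex", "n_zero_labour"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_missing + self.n_single_sex > self.n_das:
            raise ConfigError("n_missing + n_single_sex must not exceed n_das")
        for ind in PROPORTION_INDICATORS:
            if ind.name not in self.sex_rates:
                raise ConfigError(f"sex_rates missing indicator {ind.name!r}")

    def with_rates(self, **rates: SexRates) -> "GeneratorConfig":
        """Copy of the config with some indicators' sex rates replaced."""
        merged = dict(self.sex_rates)
        merged.update(rates)
        return replace(self, sex_rates=merged)


def assign_area_types(
    table: pd.DataFrame,
    shares: tuple[float, float, float],
    seed: int,
) -> pd.DataFrame:
    """Assign each DA one area-type label with the given probabilities."""
    shares_arr = np.asarray(shares, dtype=float)
    if shares_arr.shape != (3,) or (shares_arr < 0).any() or abs(shares_arr.sum() - 1.0) > 1e-9:
        raise ConfigError(
            f"area_type_shares must be 3 nonnegative weights summing to 1, got {shares}"
        )
    out = table.copy()
    rng = np.random.default_rng(seed)
    out["area_type"] = rng.choice(AREA_TYPES, size=len(table), p=shares_arr)
    return out


def _heterogeneous_rates(
    p: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray | float:
    """Per-DA female rates: logit-normal around p with between-DA SD `sd`."""
    if sd == 0.0 or p in (0.0, 1.0):
        return p
    z = rng.normal(0.0, sd, size=n)
    return expit(logit(np.clip(p, 1e-12, 1 - 1e-12)) + z)


def generate_census(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic DA-level aggregate census table.

    Per DA: total population uniform on ``population_range``; sex split
    Binomial(pop, 0.5) except forced single-sex DAs; per proportion
    indicator and sex, numerator ~ Binomial(denominator, rate), the female
    rate drawn around its configured value with logit-normal dispersion
    ``heterogeneity_sd``; per-sex DA mean incomes from the configured normal
    law.  Denominators of 20%-sample items are shrunk by
    ``sampling_fraction_20pct`` before the binomial draws.  Identical
    (config, seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_das
    lo, hi = config.population_range

    pop = rng.integers(lo, hi + 1, size=n)
    pop_f = rng.binomial(pop, 0.5)

    # designate disjoint pathology DAs
    order = rng.permutation(n)
    missing_idx = order[: config.n_missing]
    single_idx = order[config.n_missing : config.n_missing + config.n_single_sex]
    k = config.n_missing + config.n_single_sex
    n_zero = min(config.n_zero_labour, n - k)
    zero_lf_idx = order[k : k + n_zero]

    # alternate all-female / all-male among forced single-sex DAs
    all_female = single_idx[::2]
    all_male = single_idx[1::2]
    pop_f[all_female] = pop[all_female]
    pop_f[all_male] = 0
    pop_m = pop - pop_f

    width = max(5, len(str(n)))
    table = pd.DataFrame(
        {
            "da_id": [f"DA{i + 1:0{width}d}" for i in range(n)],
            "pop_f": pop_f.astype(float),
            "pop_m": pop_m.astype(float),
        }
    )

    for ind in PROPORTION_INDICATORS:
        rates = config.sex_rates[ind.name]
        frac = _AGE_FRACTIONS[ind.age_floor]
        if not ind.full_sample:
            frac *= config.sampling_fraction_20pct
        den_f = np.rint(pop_f * frac).astype(np.int64)
        den_m = np.rint(pop_m * frac).astype(np.int64)
        rate_f = _heterogeneous_rates(rates.p_female, config.heterogeneity_sd, n, rng)
        num_f = rng.binomial(den_f, rate_f)
        num_m = rng.binomial(den_m, rates.p_male)
        if ind.requires_labour_force and n_zero:
            num_f[zero_lf_idx] = 0
            num_m[zero_lf_idx] = 0
        table[f"{ind.name}_num_f"] = num_f.astype(float)
        table[f"{ind.name}_num_m"] = num_m.astype(float)
        table[f"{ind.name}_den_f"] = den_f.astype(float)
        table[f"{ind.name}_den_m"] = den_m.astype(float)

    ip = config.income_params
    for col, mu, psd, p_sex in (
        ("income_mean_f", ip.mean_f, ip.person_sd_f, pop_f),
        ("income_mean_m", ip.mean_m, ip.person_sd_m, pop_m),
    ):
        noise_da = rng.normal(0.0, ip.between_da_sd, size=n) if ip.between_da_sd else 0.0
        se = psd / np.sqrt(np.maximum(p_sex, 1))
        vals = mu + noise_da + rng.normal(0.0, 1.0, size=n) * se
        vals = np.maximum(vals, 0.1)
        vals[p_sex == 0] = 0.0  # no residents of this sex: no income cell
        table[col] = vals

    # blank one randomly chosen indicator's cells per missing-data DA
    blankable = [ind.columns for ind in PROPORTION_INDICATORS] + [list(INCOME_COLUMNS)]
    if config.n_missing:
        choices = rng.integers(0, len(blankable), size=config.n_missing)
        for row, c in zip(missing_idx, choices):
            table.loc[row, blankable[c]] = np.nan

    area_seed = int(rng.integers(2**31))
    table = assign_area_types(table, config.area_type_shares, area_seed)
    return table[census_columns()]
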