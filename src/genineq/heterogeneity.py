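"""Monte Carlo test for spatial heterogeneity of gender inequality scores.

Under the homogeneous-inequality null, every DA shares the same underlying
sex-specific rates (or income law), so across-DA variation in scores
reflects sampling noise only.  The test simulates that null — binomial
counts for proportion indicators, normal DA sex-means for income — on the
observed denominators, computes the sample variance of the simulated scores
per replicate, and compares it with the observed variance via an add-one
Monte Carlo p-value (r + 1) / (R + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicators import INDICATORS, IndicatorDefinition, derive_flags
from .scores import _eligible_mask, score_array, sex_value_arrays

__all__ = [
    "CannotTestError",
    "NullParams",
    "HeterogeneityResult",
    "pooled_null_params",
    "simulate_null_replicate",
    "heterogeneity_pvalue",
    "heterogeneity_all",
]


class CannotTestError(ValueError):
    """The heterogeneity test is undefined (e.g. < 2 eligible DAs)."""


@dataclass
class NullParams:
    """Pooled homogeneous-null parameters plus per-DA denominators.

    For proportion indicators, ``p_f``/``p_m`` are province-wide pooled
    rates (sum of numerators over sum of denominators per sex) and
    ``den_f``/``den_m`` the per-DA denominators.  For income, ``mu``/``sigma``
    per sex describe the person-level normal law, and a DA's simulated sex
    mean is Normal(mu, sigma / sqrt(den)) with den the sex population.
    """

    indicator: str
    kind: str
    da_ids: np.ndarray
    den_f: np.ndarray
    den_m: np.ndarray
    p_f: float | None = None
    p_m: float | None = None
    mu_f: float | None = None
    mu_m: float | None = None
    sigma_f: float | None = None
    sigma_m: float | None = None

    @property
    def n_das(self) -> int:
        return len(self.da_ids)


@dataclass
class HeterogeneityResult:
    """Observed score variance, the Monte Carlo null, and the p-value."""

    indicator: str
    observed_variance: float
    null_variances: np.ndarray = field(repr=False)
    p_value: float
    n_replicates: int
    seed: int
    n_das: int


def _eligible_sorted(table: pd.DataFrame, ind: IndicatorDefinition) -> pd.DataFrame:
    """Eligible DAs in canonical (da_id) order.

    Sorting makes the test invariant to input row order: each DA keeps the
    same position in the replicate draw stream regardless of how the table
    was arranged.
    """
    flags = derive_flags(table)
    if "zero_labour_force" in table.columns:
        flags["zero_labour_force"] = table["zero_labour_force"].astype(bool)
    sub = table.loc[_eligible_mask(table, ind, flags)]
    return sub.sort_values("da_id", kind="mergesort").reset_index(drop=True)


def _weighted_sigma(x: np.ndarray, w: np.ndarray) -> float:
    """Person-level SD implied by DA means x_i ~ N(mu, sigma^2 / w_i)."""
    mu = float(np.average(x, weights=w))
    n = len(x)
    if n < 2:
        return 0.0
    return float(np.sqrt(np.sum(w * (x - mu) ** 2) / (n - 1)))


def pooled_null_params(table: pd.DataFrame, indicator: IndicatorDefinition) -> NullParams:
    """Pool sex-specific rates (or income moments) across all eligible DAs."""
    sub = _eligible_sorted(table, indicator)
    if len(sub) < 2:
        raise CannotTestError(
            f"{indicator.name}: need >= 2 eligible DAs, have {len(sub)}"
        )
    da_ids = sub["da_id"].to_numpy()
    if indicator.kind == "mean_value":
        den_f = sub["pop_f"].to_numpy(float)
        den_m = sub["pop_m"].to_numpy(float)
        x_f = sub["income_mean_f"].to_numpy(float)
        x_m = sub["income_mean_m"].to_numpy(float)
        return NullParams(
            indicator=indicator.name, kind="mean_value", da_ids=da_ids,
            den_f=den_f, den_m=den_m,
            mu_f=float(np.average(x_f, weights=den_f)),
            mu_m=float(np.average(x_m, weights=den_m)),
            sigma_f=_weighted_sigma(x_f, den_f),
            sigma_m=_weighted_sigma(x_m, den_m),
        )
    n = indicator.name
    den_f = sub[f"{n}_den_f"].to_numpy(float)
    den_m = sub[f"{n}_den_m"].to_numpy(float)
    tot_f, tot_m = den_f.sum(), den_m.sum()
    if tot_f == 0 or tot_m == 0:
        raise CannotTestError(f"{indicator.name}: zero pooled denominator")
    return NullParams(
        indicator=indicator.name, kind="proportion", da_ids=da_ids,
        den_f=den_f, den_m=den_m,
        p_f=float(sub[f"{n}_num_f"].sum() / tot_f),
        p_m=float(sub[f"{n}_num_m"].sum() / tot_m),
    )


def _simulate_score_matrix(params: NullParams, rng: np.random.Generator,
                           n_replicates: int) -> np.ndarray:
    """(R, n_das) matrix of null-simulated scores."""
    shape = (n_replicates, params.n_das)
    if params.kind == "proportion":
        den_f = params.den_f.astype(np.int64)
        den_m = params.den_m.astype(np.int64)
        num_f = rng.binomial(den_f, params.p_f, size=shape)
        num_m = rng.binomial(den_m, params.p_m, size=shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_f = num_f / den_f
            p_m = num_m / den_m
        scores, _ = score_array(p_f, p_m)
    else:
        se_f = params.sigma_f / np.sqrt(np.maximum(params.den_f, 1.0))
        se_m = params.sigma_m / np.sqrt(np.maximum(params.den_m, 1.0))
        x_f = np.maximum(rng.normal(params.mu_f, se_f, size=shape), 0.0)
        x_m = np.maximum(rng.normal(params.mu_m, se_m, size=shape), 0.0)
        scores, _ = score_array(x_f, x_m)
    return scores


def simulate_null_replicate(params: NullParams, seed: int) -> float:
    """Sample variance of one replicate of null-simulated scores."""
    rng = np.random.default_rng(seed)
    scores = _simulate_score_matrix(params, rng, 1)[0]
    return float(np.var(scores, ddof=1))


def _observed_variance(table: pd.DataFrame, ind: IndicatorDefinition
                       ) -> tuple[float, int]:
    sub = _eligible_sorted(table, ind)
    if len(sub) < 2:
        raise CannotTestError(f"{ind.name}: need >= 2 eligible DAs, have {len(sub)}")
    f, m = sex_value_arrays(sub, ind)
    scores, _ = score_array(f, m)
    return float(np.var(scores, ddof=1)), len(sub)


def heterogeneity_pvalue(table: pd.DataFrame, indicator: IndicatorDefinition,
                         n_replicates: int = 999, seed: int = 0,
                         ) -> HeterogeneityResult:
    """Monte Carlo heterogeneity test for one indicator.

    p = (1 + #{null variances >= observed}) / (R + 1), so p is bounded below
    by 1/(R+1) and can never be zero.  The eligible DA set (positive
    denominators for both sexes; labour force present where required) is the
    same for the observed and every null variance.
    """
    if n_replicates < 19:
        raise ValueError(f"n_replicates must be >= 19, got {n_replicates}")
    params = pooled_null_params(table, indicator)
    observed, n_das = _observed_variance(table, indicator)
    rng = np.random.default_rng(seed)
    null_scores = _simulate_score_matrix(params, rng, n_replicates)
    null_variances = np.var(null_scores, axis=1, ddof=1)
    r = int(np.sum(null_variances >= observed))
    p = (1 + r) / (n_replicates + 1)
    return HeterogeneityResult(
        indicator=indicator.name,
        observed_variance=observed,
        null_variances=null_variances,
        p_value=p,
        n_replicates=n_replicates,
        seed=seed,
        n_das=n_das,
    )


def heterogeneity_all(table: pd.DataFrame,
                      definitions: tuple[IndicatorDefinition, ...] = INDICATORS,
                      n_replicates: int = 999, seed: int = 0) -> pd.DataFrame:
    """Run the heterogeneity test for every indicator; tidy results frame.

    Each indicator gets an independent substream spawned from the master
    seed, so adding indicators or replicates does not perturb the others.
    """
    children = np.random.SeedSequence(seed).spawn(len(definitions))
    rows = []
    for ind, child in zip(definitions, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            res = heterogeneity_pvalue(table, ind, n_replicates, sub_seed)
        except CannotTestError:
            continue
        rows.append({
            "indicator": res.indicator,
            "observed_variance": res.observed_variance,
            "p_value": res.p_value,
            "n_replicates": res.n_replicates,
            "n_das": res.n_das,
            "seed": res.seed,
        })
    return pd.DataFrame(rows)
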