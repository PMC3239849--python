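import numpy as np
import pandas as pd
import pytest

from genineq.indicators import PROPORTION_INDICATORS, census_columns
from genineq.synthetic import GeneratorConfig, generate_census


def make_census(n_das=200, seed=0, **overrides):
    """Synthetic census with pathologies disabled unless overridden."""
    defaults = dict(n_das=n_das, n_missing=0, n_single_sex=0, n_zero_labour=0,
                    seed=seed)
    defaults.update(overrides)
    return generate_census(GeneratorConfig(**defaults))


def manual_census(rows):
    """Build a census table from a list of per-DA dicts.

    Unspecified numerators/denominators default to a well-behaved cell
    (num=10, den=100 per sex); incomes default to 20/30 thousand CAD.
    ``rows`` entries may override any schema column.
    """
    records = []
    for i, row in enumerate(rows):
        rec = {"da_id": f"DA{i + 1:05d}", "area_type": "metropolitan",
               "pop_f": 250.0, "pop_m": 250.0,
               "income_mean_f": 20.0, "income_mean_m": 30.0}
        for ind in PROPORTION_INDICATORS:
            rec[f"{ind.name}_num_f"] = 10.0
            rec[f"{ind.name}_num_m"] = 10.0
            rec[f"{ind.name}_den_f"] = 100.0
            rec[f"{ind.name}_den_m"] = 100.0
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)[census_columns()]


@pytest.fixture(scope="session")
def clean_census():
    """200 pathology-free DAs, fixed seed."""
    return make_census(n_das=200, seed=42)


@pytest.fixture(scope="session")
def pathological_census():
    """500 DAs with missing-data, single-sex and zero-labour DAs."""
    return make_census(n_das=500, seed=7, n_missing=12, n_single_sex=36,
                       n_zero_labour=15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
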