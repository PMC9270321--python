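import numpy as np
import pandas as pd
import pytest

from morbinet.cohort_io import CohortTable, Variable, VariableSchema


def small_schema(extra_vars=(), psu_levels=None):
    """Two diseases, one binary covariate group, binary outcome, flat design."""
    variables = [
        Variable("d1", "binary", "disease"),
        Variable("d2", "binary", "disease"),
        Variable("g", "categorical", "covariate", levels=("a", "b"), reference="a"),
        Variable("y", "binary", "outcome"),
        *extra_vars,
        Variable("stratum", "categorical", "design", subtype="stratum", levels=("s1", "s2")),
        Variable("psu", "count", "design", subtype="psu"),
        Variable("weight", "continuous", "design", subtype="weight"),
    ]
    return VariableSchema(variables)


def flat_table(n, rng, n_psu=None, extra_cols=None, extra_vars=()):
    """Unit-weight single-stratum table; one PSU per row unless n_psu given."""
    df = pd.DataFrame(
        {
            "d1": rng.integers(0, 2, n).astype(float),
            "d2": rng.integers(0, 2, n).astype(float),
            "g": rng.choice(["a", "b"], n),
            "y": rng.integers(0, 2, n).astype(float),
            "stratum": "s1",
            "psu": np.arange(n) if n_psu is None else rng.integers(n_psu, size=n),
            "weight": 1.0,
        }
    )
    if extra_cols:
        for k, v in extra_cols.items():
            df[k] = v
    return CohortTable(df, small_schema(extra_vars=extra_vars))


def chain_theta(p, coupling=1.2):
    theta = np.zeros((p, p))
    for i in range(p - 1):
        theta[i, i + 1] = theta[i + 1, i] = coupling
    return theta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
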