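import numpy as np
import pytest

from prefmap.design import DesignMatrix
from prefmap.instruments import default_tariff
from prefmap.synthetic_cohort import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tariff():
    return default_tariff()


@pytest.fixture(scope="session")
def cohort():
    """A study-sized synthetic cohort (n = 1,050)."""
    return generate_cohort(SimConfig(n=1050, seed=11))


@pytest.fixture(scope="session")
def cohort_small():
    return generate_cohort(SimConfig(n=400, seed=3))


def make_design(arrays: dict[str, np.ndarray], intercept: bool = True) -> DesignMatrix:
    """Assemble a DesignMatrix from named columns (helper for estimator tests)."""
    names = list(arrays)
    n = len(next(iter(arrays.values())))
    cols = [np.ones(n)] if intercept else []
    if intercept:
        names = ["const"] + names
    cols += [np.asarray(v, dtype=float) for v in arrays.values()]
    return DesignMatrix(
        values=np.column_stack(cols),
        columns=tuple(names),
        has_intercept=intercept,
        index=np.arange(n),
    )
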