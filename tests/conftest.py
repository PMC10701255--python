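import numpy as np
import pandas as pd
import pytest

import caseboot as cb
from caseboot.core_model import PseudoDataset


def pseudo_from_2x2(case_exposed, case_unexposed, sub_exposed, sub_unexposed):
    """Saturated 2x2 pseudo dataset with a single binary covariate."""
    z = np.concatenate(
        [
            np.ones(case_exposed),
            np.zeros(case_unexposed),
            np.ones(sub_exposed),
            np.zeros(sub_unexposed),
        ]
    )
    n1 = case_exposed + case_unexposed
    n0 = sub_exposed + sub_unexposed
    X = np.column_stack([np.ones(n1 + n0), z])
    d = np.concatenate([np.ones(n1), np.zeros(n0)])
    return PseudoDataset(X=X, d=d, columns=("intercept", "z"))


def random_design_table(rng, ids):
    """A small covariate table (z + exclusive trinomial dummies) for given ids."""
    n = len(ids)
    cat = rng.integers(0, 3, n)
    return pd.DataFrame(
        {
            "id": [str(i) for i in ids],
            "z": rng.integers(0, 2, n),
            "x2": (cat == 0).astype(int),
            "x3": (cat == 1).astype(int),
        }
    )


@pytest.fixture
def two_by_two():
    # D=1: 10 exposed, 5 unexposed; D=0: 20 exposed, 40 unexposed
    return pseudo_from_2x2(10, 5, 20, 40)


@pytest.fixture(scope="session")
def default_params():
    return cb.SimulationParams()


@pytest.fixture(scope="session")
def fixed_sample(default_params):
    """One case-cohort sample (N=2,000, 20% subcohort) with duplication."""
    cohort = cb.generate_cohort(default_params, rng_seed=11)
    sample = cb.draw_case_cohort_sample(
        cohort, default_params.subcohort_fraction, rng_seed=12
    )
    assert sample.m > 0
    return sample


@pytest.fixture
def disjoint_sample():
    """A case-cohort sample with m = 0 built from disjoint user tables."""
    rng = np.random.default_rng(5)
    cases = random_design_table(rng, range(100))
    subcohort = random_design_table(rng, range(1000, 1160))
    sample = cb.sample_from_tables(cases, subcohort)
    assert sample.m == 0
    return sample
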