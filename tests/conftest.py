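import numpy as np
import pandas as pd
import pytest

from glycostrat.cohort import GP_COLUMNS, N_GP, GlycomicsCohort


def make_cohort_frame(n, rng, ages=None, labels=None, sexes=None,
                      years=None, plates=None):
    """Small valid cohort table with Dirichlet GP rows."""
    gp = rng.dirichlet(np.full(N_GP, 30.0), size=n)
    tab = pd.DataFrame(gp, columns=GP_COLUMNS)
    tab.insert(0, "sample_id", [f"T{i:04d}" for i in range(n)])
    tab["age"] = ages if ages is not None else rng.integers(30, 70, n)
    tab["sex"] = sexes if sexes is not None else \
        np.where(rng.uniform(size=n) < 0.5, "male", "female")
    tab["year"] = years if years is not None else "Y1"
    tab["plate"] = plates if plates is not None else "P1"
    tab["label"] = labels if labels is not None else \
        np.where(np.arange(n) % 2 == 0, "case", "control")
    return tab


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_cohort(rng):
    return GlycomicsCohort(make_cohort_frame(12, rng))
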