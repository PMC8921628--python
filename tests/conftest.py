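import numpy as np
import pandas as pd
import pytest

from mvprof.cohort_labeling import (
    assemble_cohort,
    build_negative_set,
    build_positive_set,
)
from mvprof.synthetic_fixtures import FixtureConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study (paper-scale set sizes), one seed."""
    return generate_cohort(FixtureConfig(seed=20))


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    c = default_cohort
    keys = set(c.truth["variant"])
    pos = build_positive_set(c.occurrences, c.dataset_ids)
    absent, singleton = build_negative_set(c.occurrences, keys)
    cohort = assemble_cohort(pos, absent | singleton, c.holdout, keys)
    return cohort.labels()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
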