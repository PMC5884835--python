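import numpy as np
import pytest

import morphid as m


@pytest.fixture(scope="session")
def schema():
    return m.default_schema()


@pytest.fixture(scope="session")
def cohort60(schema):
    """Default-parameter synthetic cohort: 60 subjects x 3 timepoints x 510 features."""
    return m.generate_cohort(m.default_config(60, seed=11, schema=schema))


def make_table(values, subjects=None, timepoints=None, names=None):
    """Small FeatureTable helper for hand-built fixtures."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if subjects is None:
        subjects = [f"s{i}" for i in range(n)]
    if timepoints is None:
        timepoints = [1] * n
    if names is None:
        names = [f"f{j}" for j in range(p)]
    return m.FeatureTable(subjects, np.asarray(timepoints), list(names), values)


@pytest.fixture
def two_class_1d():
    """Class A at {0,1}, class B at {4,5} on a single feature."""
    return make_table(
        [[0.0], [1.0], [4.0], [5.0]],
        subjects=["A", "A", "B", "B"],
        timepoints=[1, 2, 1, 2],
        names=["x"],
    )
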