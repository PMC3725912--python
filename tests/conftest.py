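import numpy as np
import pandas as pd
import pytest

import votefuse as vf


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic study (42/42 train, 73/52 test), seed 1."""
    return vf.simulate_cohort(vf.SimSpec(seed=1))


@pytest.fixture(scope="session")
def prep_default(sim_default):
    return vf.preprocess_cohorts(sim_default.train, sim_default.test)


@pytest.fixture(scope="session")
def qc_fixture():
    return vf.make_qc_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_calls(pairs, name="m1", ids=None):
    """Build a marker call Series from a list of strings/None."""
    ids = ids or [f"s{i}" for i in range(len(pairs))]
    return pd.Series(pairs, index=ids, name=name, dtype=object)


def toy_labels(case_ids, control_ids):
    return pd.Series(
        [vf.CASE] * len(case_ids) + [vf.CONTROL] * len(control_ids),
        index=list(case_ids) + list(control_ids),
        name="label",
    )
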