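import numpy as np
import pytest

import exhaz as ex


@pytest.fixture(scope="session")
def constant_table():
    return ex.make_fixture_lifetable("constant", rate=0.02)


@pytest.fixture(scope="session")
def two_step_table():
    return ex.make_fixture_lifetable("two-step", rate=0.01, step_age=70.0, rate_hi=0.02)


@pytest.fixture(scope="session")
def gompertz_table():
    return ex.make_fixture_lifetable("gompertz-like", r0=1e-4, g=0.09)


@pytest.fixture(scope="session")
def us_table():
    return ex.load_us_male_1990()


@pytest.fixture(scope="session")
def sim_config():
    return ex.SimConfig(n_subjects=300, n_replicates=2)


@pytest.fixture(scope="session")
def small_cohort(gompertz_table, sim_config):
    """One deterministic 300-subject cohort on the synthetic table."""
    rng = np.random.default_rng(2024)
    data, truth = ex.assemble_cohort(
        300, sim_config, ex.scenario("A"), gompertz_table, rng
    )
    return data


@pytest.fixture(scope="session")
def small_spec(small_cohort, sim_config):
    return ex.model_spec_for(small_cohort, sim_config, ex.scenario("A"), "breakpoint", (70.0, 80.0))
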