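import numpy as np
import pytest

from chromdoe.datasets import load_design_responses, study_factors
from chromdoe.rsm import fit_quadratic


@pytest.fixture(scope="session")
def factors():
    return study_factors()


@pytest.fixture(scope="session")
def study_table():
    """The packaged 15-run design with its measured responses."""
    return load_design_responses()


@pytest.fixture(scope="session")
def run_time_model(study_table):
    design, responses = study_table
    return fit_quadratic(design, responses["run_time"], response_name="run_time")


@pytest.fixture(scope="session")
def all_models(study_table):
    design, responses = study_table
    return {
        name: fit_quadratic(design, responses[name], response_name=name)
        for name in responses.names
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240531)
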