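import numpy as np
import pytest

import hipexo as hx


@pytest.fixture(scope="session")
def default_trial():
    return hx.make_subject(seed=1)


@pytest.fixture(scope="session")
def model():
    return hx.default_model()


@pytest.fixture(scope="session")
def cohort():
    """The default seven-subject synthetic cohort."""
    return hx.make_cohort(7, seed=42)


@pytest.fixture(scope="session")
def default_sweep(cohort, model):
    """Full 16-point spring-coefficient sweep of the default cohort."""
    return hx.run_sweep(cohort, spec=model)
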