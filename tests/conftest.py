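import numpy as np
import pytest

from pmlfa import GenerationConfig, generate, study_model


@pytest.fixture(scope="session")
def pop_dataset_m3():
    """Mid-sized sample from the population model, three categories."""
    return generate(GenerationConfig(n=500, m=3, seed=42))


@pytest.fixture(scope="session")
def pop_dataset_m2():
    return generate(GenerationConfig(n=500, m=2, seed=42))


@pytest.fixture(scope="session")
def study_specs_m3():
    return {mid: study_model(mid, 6, 3) for mid in
            ("baseline", "one_factor", "two_factor")}


@pytest.fixture
def rng():
    return np.random.default_rng(20220421)
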