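import pytest

import treecea as tc


@pytest.fixture(scope="session")
def table1():
    """Arms and settings loaded from the packaged model-input fixture."""
    return tc.load_parameters(tc.packaged_config_path())


@pytest.fixture(scope="session")
def cohort_spec():
    return tc.default_cohort_spec()


@pytest.fixture(scope="session")
def small_cohort(cohort_spec):
    """One synthetic cohort at the published arm sizes (43 / 34), fixed seed."""
    return tc.generate(cohort_spec, seed=20220119)
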