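import pytest

from gliopanel import default_panel, load_cohort_truth


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort_truth():
    return load_cohort_truth()
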