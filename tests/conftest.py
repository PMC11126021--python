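import hypothesis
import pytest

from qsrare import prominent_case

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def prominent_table():
    """The benchmark prominent-haplotypes composition (N=100,000, H=3083)."""
    return prominent_case()
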