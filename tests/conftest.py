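import pytest
from hypothesis import settings

from snpmeta import StudyTable, filter_table, load_example_table

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1() -> StudyTable:
    """The bundled 21-study example table."""
    return load_example_table()


@pytest.fixture(scope="session")
def asian_rs4245739(table1) -> StudyTable:
    """The seven Asian rs4245739 studies with full genotype counts."""
    return filter_table(table1, {"snp_id": "rs4245739", "ethnicity": "Asian"})
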