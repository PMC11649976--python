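import pytest

from p450template.fixtures import load_fixture_set
from p450template.geometry import load_canonical_template, trim_template


@pytest.fixture(scope="session")
def template():
    return load_canonical_template()


@pytest.fixture(scope="session")
def trimmed(template):
    """Small 4-ring sub-template for exhaustive searches."""
    return trim_template(template, ["A", "B", "C", "D"])


@pytest.fixture(scope="session")
def records():
    return load_fixture_set()


@pytest.fixture(scope="session")
def record_map(records):
    return {(r.ligand, r.reaction): r for r in records}
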