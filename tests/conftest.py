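import pathlib
import sys

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(pathlib.Path(__file__).parent))

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from ggprel.relations import build_genia_taxonomy  # noqa: E402
from ggprel.fixtures import worked_examples  # noqa: E402


@pytest.fixture(scope="session")
def tax():
    return build_genia_taxonomy()


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


@pytest.fixture(scope="session")
def examples_by_name(examples):
    return {e.name: e for e in examples}
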