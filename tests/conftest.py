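import pytest
from hypothesis import HealthCheck, settings

from klnrank import worked_example_graph

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy():
    """The packaged worked-example network (13 nodes, 18 edges)."""
    return worked_example_graph()
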