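import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import balv1 as b

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_geometry():
    return b.build_geometry(400, 100, 1.0)


@pytest.fixture(scope="session")
def tiny_network(tiny_geometry):
    """A 500-neuron balanced network small enough for unit tests."""
    layout = b.assign_orientations(tiny_geometry, "random", seed=11)
    graph = b.sample_connectivity(
        tiny_geometry, b.ConnectivityParams(k=40, sigma=0.2), seed=12
    )
    rec = b.RecurrentParams(k=40)
    return {"geom": tiny_geometry, "layout": layout, "graph": graph, "rec": rec}
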