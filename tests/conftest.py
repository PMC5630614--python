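import numpy as np
import pytest

from ooctrack import synth, tracking
from ooctrack.benchmark import exact_linear_polar_track  # noqa: F401  (test helper)


@pytest.fixture(scope="session")
def benchmark_scene():
    """Rendered tracking benchmark scene (tracks, params, stack, truth)."""
    tracks, params = synth.simulate_tracking_benchmark(seed=11)
    stack, truth = synth.render_stack(tracks, params, seed=11)
    return tracks, params, stack, truth


@pytest.fixture
def tracking_config():
    return tracking.TrackingConfig()
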