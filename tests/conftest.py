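import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """A 5%-density recovery phantom with its measured masks (shared)."""
    from placvasc.experiments import recovery_spec
    from placvasc.phantom import generate_volume_phantom
    from placvasc.segmentation import find_thresholds, segment

    spec = recovery_spec(0.05, seed=11)
    volume, truth = generate_volume_phantom(spec)
    thresholds = find_thresholds(volume)
    tissue, vessel = segment(volume, thresholds)
    return {
        "spec": spec,
        "volume": volume,
        "truth": truth,
        "thresholds": thresholds,
        "tissue": tissue,
        "vessel": vessel,
    }


@pytest.fixture(scope="session")
def null_runs():
    """Twenty homogeneous-phantom null runs (shared by several tests)."""
    from placvasc.experiments import run_null_pattern

    return [run_null_pattern(seed) for seed in range(20)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
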