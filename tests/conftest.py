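import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from falldetect.experiments import TWO_CLASS_MIX, TWO_CLASS_N, build_feature_dataset
from falldetect.foreground import SegmentationParams
from falldetect.synthetic import ScenarioSpec, simulate_sequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fall_sequence():
    """A noisy fall scenario with ground truth (the default study conditions)."""
    return simulate_sequence(ScenarioSpec(scenario="fall", seed=1))


@pytest.fixture(scope="session")
def clean_fall_sequence():
    """Noise-free fall scenario for exact-recovery checks."""
    return simulate_sequence(ScenarioSpec(scenario="fall", noise_sigma=0.0, seed=3))


@pytest.fixture(scope="session")
def exact_params():
    """Segmentation with noise suppression off: planted masks recover exactly."""
    return SegmentationParams(distance_floor=0.0, erosion_radius=0)


@pytest.fixture(scope="session")
def two_class_features():
    """Pooled window features of the balanced fall/walk dataset, seed 1."""
    X, y, table = build_feature_dataset(TWO_CLASS_MIX, TWO_CLASS_N, seed=1)
    return X, y, table
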