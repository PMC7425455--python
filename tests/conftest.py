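import numpy as np
import pytest

from vrfmed.synthetic import GroundTruth, generate_cohort, generate_gmv_images


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale ground truth: 16^3 grid, 40 subjects, default effects."""
    return GroundTruth(
        group_sizes=(12, 10, 10, 8),
        grid_shape=(16, 16, 16),
        roi_specs=(
            ("ROI_A", (0.38, 0.42, 0.50), 2.0),
            ("ROI_B", (0.62, 0.58, 0.50), 2.0),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return generate_cohort(small_truth)


@pytest.fixture(scope="session")
def small_bundle(small_truth, small_cohort):
    return generate_gmv_images(small_cohort, small_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
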