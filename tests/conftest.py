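import numpy as np
import pytest

from autoaspects import (
    CohortSpec,
    Hemisphere,
    LesionSpec,
    PhantomSpec,
    Region,
    build_synthetic_atlas,
    simulate_cohort,
    simulate_volume,
)


@pytest.fixture(scope="session")
def atlas64():
    """Soft-margin synthetic atlas on a 64x64x32 grid."""
    return build_synthetic_atlas((64, 64, 32), seed=1)


@pytest.fixture(scope="session")
def atlas48():
    """Smaller soft-margin atlas for cohort-level tests."""
    return build_synthetic_atlas((48, 48, 24), seed=2)


@pytest.fixture(scope="session")
def atlas_hard():
    """Hard-weight (binary) atlas: exact closed-form regional means."""
    return build_synthetic_atlas((64, 64, 32), seed=1, margin=0.0)


@pytest.fixture(scope="session")
def lesioned_volume(atlas64):
    """Noise-free phantom with 10% drops in CN, INS, M1 on the left."""
    spec = PhantomSpec(
        background_hu_sd=0.0,
        lesions=(
            LesionSpec(Region.CN, Hemisphere.LEFT, 10.0),
            LesionSpec(Region.INS, Hemisphere.LEFT, 10.0),
            LesionSpec(Region.M1, Hemisphere.LEFT, 10.0),
        ),
        seed=7,
    )
    return simulate_volume(atlas64, spec)


@pytest.fixture(scope="session")
def noisy_cohort(atlas48):
    """Small noisy cohort with known ground truth (deterministic)."""
    spec = CohortSpec(n_patients=30, drop_range_pct=(8.0, 15.0))
    return simulate_cohort(atlas48, spec, seed=11)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
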