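import numpy as np
import pytest

from cochmap import (
    CochlearMeasurements,
    GeneratorConfig,
    GeometryConfig,
    cohort_to_frame,
    eca_cdl,
    generate_cohort,
)


@pytest.fixture(scope="session")
def mean_measurements():
    """Population-mean basal-turn calipers."""
    return CochlearMeasurements(A=8.7, B=6.5, H=4.0)


@pytest.fixture(scope="session")
def mean_cdl(mean_measurements):
    return eca_cdl(mean_measurements, GeometryConfig())


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort as a list of records."""
    return generate_cohort(GeneratorConfig(seed=20260920))


@pytest.fixture(scope="session")
def default_cohort_frame(default_cohort):
    return cohort_to_frame(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
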