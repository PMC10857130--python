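import numpy as np
import pytest

from sersmap.scan import GridGeometry
from sersmap.simulate import NoiseModel, SourceSpec, default_axis, simulate_scan


@pytest.fixture(scope="session")
def geometry():
    return GridGeometry()


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def small_geometry():
    return GridGeometry(6, 6, 15.0)


@pytest.fixture(scope="session")
def center_bzd_scan():
    """Single BZD source at the array center, default noise, fixed seed."""
    return simulate_scan(
        [SourceSpec("BZD", (7.5, 7.5), (2.0, 2.0), 1.0)],
        noise=NoiseModel(seed=7),
    )


@pytest.fixture(scope="session")
def clean_center_scan():
    """Noise-free single-source scan: gas + baseline only (no broadband
    pedestal), gap bands still zeroed."""
    return simulate_scan(
        [SourceSpec("BZD", (7.5, 7.5), (2.0, 2.0), 1.0)],
        noise=NoiseModel(additive_sd=0.0, multiplicative_sd=0.0, seed=0),
        background=0.0,
    )
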