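"""Shared fixtures: the default device solved once per session."""
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from muos import (DeviceGeometry, GridSpec, build_domain_mask, solve_steady,
                  extract_axial_profile, partition_regions, TransportParams)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return DeviceGeometry()


@pytest.fixture(scope="session")
def mask_dx1(geometry):
    return build_domain_mask(geometry, GridSpec(dx=1.0))


@pytest.fixture(scope="session")
def steady_field(mask_dx1):
    """Default R=1 steady field at dx=1 µm."""
    return solve_steady(mask_dx1, TransportParams())


@pytest.fixture(scope="session")
def mid_profile(steady_field, mask_dx1):
    return extract_axial_profile(steady_field, mask_dx1.n_channels // 2)


@pytest.fixture(scope="session")
def regions(mid_profile, geometry):
    return partition_regions(mid_profile, geometry)
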