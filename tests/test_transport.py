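"""Transport solver: analytic oracles, conservation, profiles and statistics."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from muos import (AxialProfile, DeviceGeometry, GridSpec, SolverError,
                  TransportParams, boundary_wall_fluxes, build_domain_mask,
                  extract_axial_profile, linearity_r2,
                  make_straight_channel_mask, partition_regions, rmse,
                  solve_steady, solve_transient, time_to_steady_fraction)
from muos.geometry import DomainMask, CHANNEL0


# ---------------------------------------------------------------- steady

def test_equal_boundary_values_give_uniform_field(mask_dx1):
    field = solve_steady(mask_dx1, TransportParams(), c_left=1.0, c_right=1.0)
    assert np.allclose(field.values[mask_dx1.inside], 1.0, atol=1e-9)


def test_straight_channel_linear_profile():
    mask = make_straight_channel_mask(length=90, width=20, dx=0.5)
    field = solve_steady(mask, TransportParams(u_channel=0.0))
    profile = extract_axial_profile(field, 0)
    expected = profile.x / 90.0
    assert np.abs(profile.c - expected).max() < 1e-10
    assert float(profile.at(45.0)) == pytest.approx(0.5, abs=1e-6)


@pytest.mark.parametrize("peclet", [1.0, 3.0, -2.0])
def test_straight_channel_advection_matches_exponential(peclet):
    # closed form: C(x) = (exp(Pe x/L) - 1) / (exp(Pe) - 1)
    L = 90.0
    mask = make_straight_channel_mask(length=L, width=20, dx=0.5)
    params = TransportParams(u_channel=peclet * 13.5 / L)
    profile = extract_axial_profile(solve_steady(mask, params), 0)
    exact = np.expm1(peclet * profile.x / L) / np.expm1(peclet)
    assert np.abs(profile.c - exact).max() < 0.005


def test_maximum_principle_across_flow_ratios(mask_dx1):
    for R in (0.5, 2.0, 3.0):
        field = solve_steady(mask_dx1, TransportParams(QR=R))
        v = field.values[mask_dx1.inside]
        assert v.min() >= 0.0 and v.max() <= 1.0


def test_steady_flux_conservation(steady_field):
    fluxes = boundary_wall_fluxes(steady_field)
    assert fluxes["source"] > 0 > fluxes["sink"]
    imbalance = abs(fluxes["source"] + fluxes["sink"]) / fluxes["source"]
    assert imbalance < 0.005


def test_grid_convergence_of_channel_midpoint(geometry, mid_profile):
    mask = build_domain_mask(geometry, GridSpec(dx=0.5))
    fine = extract_axial_profile(solve_steady(mask, TransportParams()),
                                 mask.n_channels // 2)
    coarse_mid = float(mid_profile.at(195.0))
    fine_mid = float(fine.at(195.0))
    assert abs(coarse_mid - fine_mid) / fine_mid < 0.01


def test_disconnected_domain_raises():
    inside = np.zeros((5, 15), dtype=bool)
    inside[:, 0:4] = True
    inside[:, 6:9] = True   # island: no contact with either pinned column
    inside[:, 11:15] = True
    thickness = np.where(inside, 10.0, 0.0)
    labels = np.where(inside, CHANNEL0, 0).astype(np.int32)
    mask = DomainMask(inside=inside, thickness=thickness, labels=labels,
                      dx=1.0, n_channels=1, channel_span=(0.0, 15.0))
    with pytest.raises(SolverError, match="disconnected"):
        solve_steady(mask, TransportParams(u_channel=0.0))


# -------------------------------------------------------------- transient

def test_steady_state_is_transient_fixed_point(mask_dx1, steady_field):
    res = solve_transient(mask_dx1, TransportParams(), t_end=10, dt=5,
                          field0=steady_field)
    final = res.fields[-1].values[mask_dx1.inside]
    initial = steady_field.values[mask_dx1.inside]
    assert np.abs(final - initial).max() < 1e-8


def test_transient_mass_accounting(mask_dx1):
    res = solve_transient(mask_dx1, TransportParams(), t_end=20, dt=2)
    rel = np.abs(res.mass_change - res.boundary_influx) / np.abs(res.boundary_influx)
    assert rel.max() < 1e-3


def test_transient_converges_to_steady(steady_field):
    mask = steady_field.mask
    res = solve_transient(mask, TransportParams(), t_end=4000, dt=20,
                          store_every=200)
    final = res.fields[-1].values[mask.inside]
    target = steady_field.values[mask.inside]
    assert np.abs(final - target).max() < 0.01


def test_time_to_steady_halving_dt(mask_dx1):
    t_coarse = time_to_steady_fraction(mask_dx1, TransportParams(), dt=8.0)
    t_fine = time_to_steady_fraction(mask_dx1, TransportParams(), dt=4.0)
    assert abs(t_coarse - t_fine) / t_fine < 0.05


# ------------------------------------------------------ profiles, regions

def test_profile_of_uniform_field(mask_dx1):
    field = solve_steady(mask_dx1, TransportParams(), c_left=1.0, c_right=1.0)
    profile = extract_axial_profile(field, 0)
    assert np.allclose(profile.c, 1.0, atol=1e-9)
    with pytest.raises(IndexError):
        extract_axial_profile(field, 99)


def test_profile_monotone_and_channel_dominated(mid_profile):
    assert np.all(np.diff(mid_profile.c) >= -1e-9)
    drop = float(mid_profile.at(240.0)) - float(mid_profile.at(150.0))
    assert drop > 0.4  # most of the drop happens across the channel


def test_partition_regions_linear_profile(geometry):
    x = np.linspace(150, 240, 91)
    c = 0.25 + (0.80 - 0.25) * (x - 150) / 90.0
    regions = partition_regions(AxialProfile(x=x, c=c), geometry)
    assert regions.L.c_range == pytest.approx((0.25, 0.25 + 0.55 / 3), abs=1e-6)
    assert regions.M.c_range == pytest.approx((0.25 + 0.55 / 3, 0.25 + 2 * 0.55 / 3), abs=1e-6)
    assert regions.H.c_range == pytest.approx((0.25 + 2 * 0.55 / 3, 0.80), abs=1e-6)
    assert [r.x_span for r in regions] == [(150, 180), (180, 210), (210, 240)]


def test_partition_regions_constant_profile(geometry):
    x = np.linspace(0, 390, 40)
    regions = partition_regions(AxialProfile(x=x, c=np.full_like(x, 0.3)), geometry)
    for r in regions:
        assert r.c_range == pytest.approx((0.3, 0.3))


def test_partition_regions_requires_coverage(geometry):
    short = AxialProfile(x=np.linspace(150, 200, 20), c=np.linspace(0, 1, 20))
    with pytest.raises(ValueError, match="cover"):
        partition_regions(short, geometry)


def test_region_labels_by_position(regions):
    assert regions.locate(160.0) == "L"
    assert regions.locate(195.0) == "M"
    assert regions.locate(225.0) == "H"
    assert regions.locate(100.0) == "OUTSIDE"


# ------------------------------------------------------------- statistics

def test_r2_of_exact_line():
    x = np.linspace(150, 240, 30)
    prof = AxialProfile(x=x, c=0.001 * x + 0.1)
    assert linearity_r2(prof, (150, 240)) == pytest.approx(1.0, abs=1e-12)


def test_r2_errors():
    prof = AxialProfile(x=np.array([1.0, 2.0]), c=np.array([0.1, 0.2]))
    with pytest.raises(ValueError, match=">=3"):
        linearity_r2(prof, (0, 10))


def test_rmse_hand_computed_values():
    assert rmse([1, 2], [1, 4]) == pytest.approx(np.sqrt(2), abs=1e-12)
    assert rmse([0.3, 0.7, 0.1], [0.3, 0.7, 0.1]) == 0.0
    with pytest.raises(ValueError, match="length mismatch"):
        rmse([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        rmse([], [])


@given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30))
def test_rmse_symmetry_and_nonnegativity(values):
    a = np.asarray(values)
    b = a[::-1].copy()
    assert rmse(a, b) == pytest.approx(rmse(b, a))
    assert rmse(a, b) >= 0.0
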