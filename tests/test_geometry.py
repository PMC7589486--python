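"""Stereographic eye-model geometry: closed forms, conservation, zoning."""

import numpy as np
import pytest

from uwfchoroid.geometry import (DEFAULT_ZONE_BOUNDARIES_MM, EXCLUDED, FPR, MPR, MR, NPR,
                                 EyeModel, area_map, assign_zones, geodesic_distance,
                                 geodesic_from_plane_radius, geodesic_map, pixel_area,
                                 plane_radius_from_geodesic, spherical_cap_area)


def test_plane_radius_closed_form(small_model):
    # fovea maps to the tangent point; 90 deg of arc maps to rho = 2R tan(45) = 2R
    assert plane_radius_from_geodesic(0.0, small_model) == 0.0
    R = small_model.sphere_radius
    assert plane_radius_from_geodesic(np.pi * R / 2, small_model) == pytest.approx(2 * R)


def test_plane_radius_strictly_increasing(small_model):
    d = np.linspace(0, 30, 1000)
    rho = plane_radius_from_geodesic(d, small_model)
    assert np.all(np.diff(rho) > 0)


def test_plane_radius_domain_error(small_model):
    with pytest.raises(ValueError):
        plane_radius_from_geodesic(-1.0, small_model)
    with pytest.raises(ValueError):
        plane_radius_from_geodesic(np.pi * 12.0, small_model)


@pytest.mark.parametrize("d", [0.5, 3.0, 10.0, 15.0])
def test_geodesic_plane_round_trip(d, small_model):
    rho = plane_radius_from_geodesic(d, small_model)
    assert float(geodesic_from_plane_radius(rho, small_model)) == pytest.approx(d, abs=1e-9)


def test_pixel_area_at_fovea_and_2R(small_model):
    # zero radius -> scale 1; plane radius 2R -> cos^4(45 deg) = 1/4
    fr, fc = small_model.fovea_pixel
    assert pixel_area((fr, fc), small_model) == pytest.approx(small_model.pixel_pitch**2)
    model = EyeModel(grid_shape=(3, 2000), pixel_pitch=24.0 / 1999, fovea_pixel=(1, 0))
    # pixel (1, 1999) sits at plane radius 24 mm = 2R
    assert pixel_area((1, 1999), model) == pytest.approx(0.25 * model.pixel_pitch**2)


def test_area_scale_bounded_and_decreasing(small_model):
    areas = area_map(small_model)
    assert np.all(areas > 0)
    assert np.all(areas <= small_model.pixel_pitch**2 + 1e-15)
    centre_row = areas[small_model.fovea_pixel[0], small_model.fovea_pixel[1]:]
    assert np.all(np.diff(centre_row) < 0)


def test_geodesic_against_3d_great_circle_oracle(small_model, rng):
    """Pixel geodesics agree with distances computed through explicit 3-D
    sphere coordinates obtained by inverse stereographic projection."""
    R = small_model.sphere_radius
    fr, fc = small_model.fovea_pixel
    for _ in range(50):
        r = rng.integers(0, small_model.grid_shape[0])
        c = rng.integers(0, small_model.grid_shape[1])
        # inverse stereographic: plane point (x, y) -> 3-D point on the sphere
        x = (c - fc) * small_model.pixel_pitch
        y = (r - fr) * small_model.pixel_pitch
        rho2 = x * x + y * y
        denom = rho2 + 4 * R * R
        px = 4 * R * R * x / denom
        py = 4 * R * R * y / denom
        pz = R * (rho2 - 4 * R * R) / denom  # fovea at (0, 0, -R), centre at origin
        fovea3 = np.array([0.0, 0.0, -R])
        p3 = np.array([px, py, pz])
        angle = np.arccos(np.clip(np.dot(fovea3, p3) / R**2, -1, 1))
        assert geodesic_distance((r, c), small_model) == pytest.approx(R * angle, abs=1e-9)


def test_disc_area_matches_spherical_cap(small_model):
    """Summed per-pixel areas over a geodesic disc match 2 pi R^2 (1 - cos(d/R))."""
    areas = area_map(small_model)
    dist = geodesic_map(small_model)
    for d in (2.0, 4.0, 6.0):
        measured = areas[dist <= d].sum()
        expected = spherical_cap_area(d, small_model.sphere_radius)
        assert measured == pytest.approx(expected, rel=0.005)


def test_zone_assignment_by_geodesic_distance():
    model = EyeModel(grid_shape=(801, 801), pixel_pitch=0.05, fovea_pixel=(400, 400))
    zones = assign_zones(model, np.ones(model.grid_shape, dtype=bool))
    dist = geodesic_map(model)

    def zone_at(target_mm):
        idx = np.unravel_index(np.argmin(np.abs(dist[400] - target_mm)), (801,))
        return zones.labels[400, idx[0]]

    assert zone_at(2.0) == MR
    assert zone_at(5.0) == NPR
    assert zone_at(12.0) == MPR
    assert zone_at(16.0) == FPR
    assert zone_at(0.2) == EXCLUDED


def test_zone_assignment_edge_cases(small_model):
    all_false = np.zeros(small_model.grid_shape, dtype=bool)
    with pytest.warns(UserWarning, match="fovea"):
        zones = assign_zones(small_model, all_false)
    assert np.all(zones.labels == EXCLUDED)


def test_zone_partition_translation_invariant():
    visible = np.ones((120, 120), dtype=bool)
    m1 = EyeModel(grid_shape=(120, 120), pixel_pitch=0.2, fovea_pixel=(40, 40))
    m2 = EyeModel(grid_shape=(120, 120), pixel_pitch=0.2, fovea_pixel=(60, 60))
    z1 = assign_zones(m1, visible).labels
    z2 = assign_zones(m2, visible).labels
    # central 40-px windows around each fovea are identical
    assert np.array_equal(z1[20:60, 20:60], z2[40:80, 40:80])


def test_zones_partition_is_disjoint_and_exhaustive(small_model):
    visible = np.ones(small_model.grid_shape, dtype=bool)
    zones = assign_zones(small_model, visible)
    dist = geodesic_map(small_model)
    b = DEFAULT_ZONE_BOUNDARIES_MM
    inside = (dist >= b[0])
    assert np.all(np.isin(zones.labels[inside], [MR, NPR, MPR, FPR]))
    assert np.all(zones.labels[~inside] == EXCLUDED)


def test_model_validation():
    with pytest.raises(ValueError):
        EyeModel(grid_shape=(10, 10), pixel_pitch=-1.0, fovea_pixel=(5, 5))
    with pytest.raises(ValueError):
        EyeModel(grid_shape=(10, 10), pixel_pitch=0.1, fovea_pixel=(20, 5))


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.floats(0.0, 30.0), st.floats(0.0, 30.0))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_forward_map_order_preserving_property(d1, d2):
    """The stereographic forward map preserves ordering of geodesic distances
    and round-trips through its inverse."""
    model = EyeModel(grid_shape=(11, 11), pixel_pitch=0.1, fovea_pixel=(5, 5))
    r1 = float(plane_radius_from_geodesic(d1, model))
    r2 = float(plane_radius_from_geodesic(d2, model))
    assert (d1 <= d2) == (r1 <= r2)
    assert float(geodesic_from_plane_radius(r1, model)) == pytest.approx(d1, abs=1e-9)
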