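import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvloops.errors import InconsistentContourError, InvalidInputError
from lvloops.geometry import (
    CineContourSet,
    InsertionPointTracks,
    PlanarContour,
    ViewTrack,
    av_plane_displacement,
    compute_geometry_series,
    endocardial_surface_area,
    epicardial_radius,
    lv_mass,
    lv_volume,
    mass_variation,
    max_epicardial_cross_section,
    polygon_area,
    polygon_perimeter,
    radial_displacement,
    resample_cycle,
    smooth_sliding_mean,
)


def circle(r, n=80, center=(0.0, 0.0), kind="epi"):
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    return PlanarContour(pts, kind)


def square(side, kind="endo"):
    s = side
    return PlanarContour(np.array([[0, 0], [s, 0], [s, s], [0, s]], float), kind)


# ---------------------------------------------------------------------------
# contour type invariants


@pytest.mark.parametrize(
    "pts",
    [
        np.zeros((2, 2)),  # too few points
        np.array([[0, 0], [0, 0], [1, 0], [0, 1]], float),  # duplicate
        np.array([[0, 0], [1, 1], [2, 2]], float),  # collinear: zero area
    ],
)
def test_contour_rejects_degenerate_point_sets(pts):
    with pytest.raises(InvalidInputError):
        PlanarContour(pts, "endo")


# ---------------------------------------------------------------------------
# cycle-grid signal operations


def test_resample_preserves_constants_and_identity():
    assert np.allclose(resample_cycle(np.full(25, 7.0), 100), 7.0)
    y = np.array([1.0, 2.0, 1.0])
    assert np.allclose(resample_cycle(y, 3), y)


def test_resample_matches_analytic_sine():
    t25 = np.arange(25) / 25
    out = resample_cycle(np.sin(2 * np.pi * t25), 100)
    t100 = np.arange(100) / 100
    assert np.max(np.abs(out - np.sin(2 * np.pi * t100))) < 0.01


def test_resample_idempotent_on_own_grid():
    rng = np.random.default_rng(0)
    y = rng.normal(size=40)
    assert np.allclose(resample_cycle(y, 40), y)


def test_resample_rejects_short_input():
    with pytest.raises(InvalidInputError):
        resample_cycle([1.0, 2.0], 100)
    with pytest.raises(InvalidInputError):
        resample_cycle([1.0, 2.0, 3.0], 2)


def test_smoothing_is_circular_three_point_mean():
    assert np.allclose(smooth_sliding_mean([3, 0, 0, 0]), [1, 1, 0, 1])
    assert np.allclose(smooth_sliding_mean(np.full(10, 4.2)), 4.2)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_smoothing_conserves_cycle_sum(seed):
    y = np.random.default_rng(seed).normal(size=50)
    assert np.isclose(smooth_sliding_mean(y).sum(), y.sum(), rtol=1e-12)


# ---------------------------------------------------------------------------
# polygon measurements against analytic oracles


def test_perimeter_and_area_of_square():
    sq = square(10.0)
    assert polygon_perimeter(sq) == pytest.approx(40.0)
    assert polygon_area(square(1.0)) == pytest.approx(1.0)


def test_circle_measurements_within_two_permille():
    c = circle(20.0)
    assert polygon_perimeter(c) == pytest.approx(2 * np.pi * 20, rel=1e-3)
    assert polygon_area(c) == pytest.approx(np.pi * 20**2, rel=2e-3)
    assert epicardial_radius(circle(25.0)) == pytest.approx(25.0, rel=2e-3)


def test_measurements_invariant_under_translation():
    a, b = circle(17.0), circle(17.0, center=(5.0, -3.0))
    assert polygon_area(a) == pytest.approx(polygon_area(b), rel=1e-12)
    assert polygon_perimeter(a) == pytest.approx(polygon_perimeter(b), rel=1e-12)
    assert epicardial_radius(a) == pytest.approx(epicardial_radius(b), rel=1e-12)


def test_ellipse_radius_matches_brute_force_mean():
    th = 2 * np.pi * np.arange(80) / 80
    pts = np.column_stack([30 * np.cos(th), 20 * np.sin(th)])
    oracle = np.mean(np.linalg.norm(pts - pts.mean(axis=0), axis=1))
    assert epicardial_radius(PlanarContour(pts, "epi")) == pytest.approx(oracle)
    assert oracle == pytest.approx(25.3, abs=0.2)


def test_endocardial_surface_area_formula():
    # circumference x slice thickness, in cm^2
    c = circle(20.0, kind="endo")
    assert endocardial_surface_area(c, 8.0) == pytest.approx(
        2 * np.pi * 20 * 8 / 100, rel=1e-3
    )
    assert endocardial_surface_area(square(10.0), 10.0) == pytest.approx(4.0)
    with pytest.raises(InvalidInputError):
        endocardial_surface_area(c, 0.0)
    with pytest.warns(UserWarning):
        endocardial_surface_area(circle(20.0, kind="epi"), 8.0)
    with pytest.raises(InvalidInputError):
        endocardial_surface_area(circle(20.0, kind="epi"), 8.0, strict=True)


# ---------------------------------------------------------------------------
# frame-level stack measurements


def stack_of_cylinder(r_endo, r_epi, n_slices, thickness, n_frames=3):
    cs = CineContourSet(n_frames=n_frames, n_slices=n_slices,
                        slice_thickness=thickness)
    for f in range(n_frames):
        for s in range(n_slices):
            cs.add(f, s, circle(r_endo, kind="endo"))
            cs.add(f, s, circle(r_epi, kind="epi"))
    return cs


def test_lv_volume_disc_summation():
    cs = stack_of_cylinder(20.0, 30.0, n_slices=80, thickness=1.0)
    # pi r^2 L with polygon discretization of the circle
    assert lv_volume(cs, 0) == pytest.approx(np.pi * 400 * 80 / 1000, rel=2e-3)


def test_lv_mass_from_wall_volume():
    cs = stack_of_cylinder(20.0, 30.0, n_slices=80, thickness=1.0)
    wall = np.pi * (900 - 400) * 80 / 1000
    assert lv_mass(cs, 0) == pytest.approx(wall * 1.05, rel=2e-3)


def test_lv_mass_rejects_epi_smaller_than_endo():
    cs = CineContourSet(n_frames=3, n_slices=1, slice_thickness=8.0)
    for f in range(3):
        cs.add(f, 0, circle(30.0, kind="endo"))
        cs.add(f, 0, circle(20.0, kind="epi"))
    with pytest.raises(InconsistentContourError):
        lv_mass(cs, 0)


def test_max_epicardial_cross_section_picks_largest_slice():
    cs = CineContourSet(n_frames=3, n_slices=3, slice_thickness=8.0)
    for f in range(3):
        for s, r in enumerate([30.0, 33.0, 31.0]):
            cs.add(f, s, circle(r, kind="epi"))
            cs.add(f, s, circle(r - 8, kind="endo"))
    assert max_epicardial_cross_section(cs, 0) == pytest.approx(
        np.pi * 33**2 / 100, rel=2e-3
    )


def test_mass_variation_arithmetic():
    mv = mass_variation([100.0, 102.0, 98.0])
    assert np.allclose(mv.deviations_pct, [0.0, 2.0, -2.0])
    mv2 = mass_variation(np.full(10, 84.0))
    assert mv2.mean_pct == 0.0 and mv2.sd_pct == 0.0


# ---------------------------------------------------------------------------
# displacements


def test_radial_displacement_is_inward_positive_and_zero_at_ed():
    r = np.array([30.0, 28.0, 27.5, 29.0])
    d = radial_displacement(r, 0)
    assert d[0] == 0.0
    assert d[2] == pytest.approx(2.5)


def test_avpd_perpendicular_distance_and_parallel_motion():
    # ED line through (0,0)-(40,0), apex toward -y; point at (10,-8) is 8 mm
    nf = 3
    pts = np.zeros((nf, 2, 2))
    pts[:, 1, 0] = 40.0
    pts[1, 0] = (10.0, -8.0)
    pts[1, 1] = (50.0, -8.0)
    pts[2, 0] = (5.0, 0.0)  # parallel, in-plane motion
    pts[2, 1] = (45.0, 0.0)
    views = [
        ViewTrack(name=n, apex_direction=np.array([0.0, -1.0]), points=pts.copy())
        for n in ("a", "b", "c")
    ]
    tracks = InsertionPointTracks(views=views)
    avpd = av_plane_displacement(tracks, 0)
    assert avpd[0] == 0.0
    assert avpd[1] == pytest.approx(8.0)
    assert avpd[2] == pytest.approx(0.0)


def test_avpd_requires_distinct_ed_points():
    pts = np.zeros((3, 2, 2))
    views = [
        ViewTrack(name=n, apex_direction=np.array([0.0, 1.0]), points=pts.copy())
        for n in ("a", "b", "c")
    ]
    with pytest.raises(InvalidInputError):
        av_plane_displacement(InsertionPointTracks(views=views), 0)


# ---------------------------------------------------------------------------
# pipeline-level invariants on the phantom


def test_displacements_zero_at_ed_by_construction(default_run):
    g = default_run.geometry
    assert g.avpd[g.frame_of_ed] == 0.0
    for s in g.included_slices:
        assert g.epi_displacement[s][g.frame_of_ed] == 0.0


def test_volume_and_sv_track_phantom_truth(default_run):
    g, truth = default_run.geometry, default_run.truth
    assert g.sv == pytest.approx(truth.sv, rel=0.02)
    assert g.sv == pytest.approx(g.edv - g.esv)


def test_mass_conserved_on_phantom(default_run):
    mv = mass_variation(default_run.geometry.mass)
    assert np.max(np.abs(mv.deviations_pct)) < 0.5


def test_geometry_invariant_under_rigid_translation():
    from lvloops.phantom import PhantomParams, generate_phantom

    p = PhantomParams(n_frames=12, slice_thickness=4.0, avpd_amplitude=0.0)
    a = generate_phantom(p)
    shifted = a.contours
    for key, kinds in shifted.contours.items():
        for kind, c in kinds.items():
            kinds[kind] = PlanarContour(c.points + np.array([7.0, -4.0]), c.kind)
    ga = compute_geometry_series(generate_phantom(p).contours)
    gb = compute_geometry_series(shifted)
    assert np.allclose(ga.volume, gb.volume, rtol=1e-12)
    assert np.allclose(ga.mass, gb.mass, rtol=1e-12)
    assert np.allclose(ga.max_epi_cross_section, gb.max_epi_cross_section, rtol=1e-12)
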