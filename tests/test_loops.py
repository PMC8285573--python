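import numpy as np
import pytest

from lvloops.errors import InvalidInputError
from lvloops.loops import (
    decompose_stroke_work,
    force_from_pressure_area,
    longitudinal_stroke_work,
    loop_area,
    max_systolic_avpd,
    pv_stroke_work,
    radial_stroke_work,
    signed_loop_area,
    sv_partition,
    work_per_ejected_volume,
)


# ---------------------------------------------------------------------------
# force arithmetic


@pytest.mark.parametrize(
    "p_mmhg, a_cm2, expected_n",
    [
        (100.0, 40.0, 53.33),
        (0.0, 120.0, 0.0),
        (100.0, 150.0, 200.0),  # human-scale peak radial force
    ],
)
def test_force_from_pressure_area(p_mmhg, a_cm2, expected_n):
    assert force_from_pressure_area(p_mmhg, a_cm2) == pytest.approx(
        expected_n, rel=1e-3
    )


def test_force_rejects_negative_area():
    with pytest.raises(InvalidInputError):
        force_from_pressure_area(100.0, -1.0)


def test_force_is_linear_in_pressure():
    a = np.full(10, 35.0)
    p = np.linspace(10, 120, 10)
    assert np.allclose(
        force_from_pressure_area(2 * p, a), 2 * force_from_pressure_area(p, a)
    )


# ---------------------------------------------------------------------------
# loop integration


def test_rectangle_and_triangle_loop_areas():
    # force 10 -> 20 N over 5 mm displacement
    x = np.array([0.0, 0.005, 0.005, 0.0])
    y = np.array([10.0, 10.0, 20.0, 20.0])
    assert loop_area(x, y) == pytest.approx(0.05)
    tx = np.array([0.0, 0.01, 0.01])
    ty = np.array([0.0, 0.0, 10.0])
    assert loop_area(tx, ty) == pytest.approx(0.05)


def test_zero_displacement_loop_is_zero():
    y = np.linspace(0, 50, 20)
    assert loop_area(np.zeros(20), y) == 0.0


def test_degenerate_loop_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert loop_area([1.0, 1.0], [2.0, 2.0]) == 0.0


def test_loop_area_orientation_free(rng):
    x = rng.normal(size=64)
    y = rng.normal(size=64)
    assert loop_area(x, y) == pytest.approx(loop_area(x[::-1], y[::-1]), rel=1e-12)
    assert signed_loop_area(x, y) == pytest.approx(
        -signed_loop_area(x[::-1], y[::-1]), rel=1e-12
    )


def test_shoelace_equals_trapezoidal_contour_integral(rng):
    # |oint y dx| via the trapezoid rule on the closed loop is
    # algebraically the shoelace sum; check to 1e-10 relative
    for _ in range(100):
        n = int(rng.integers(10, 200))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        xc = np.append(x, x[0])
        yc = np.append(y, y[0])
        trap = abs(np.sum(0.5 * (yc[1:] + yc[:-1]) * np.diff(xc)))
        assert loop_area(x, y) == pytest.approx(trap, rel=1e-10, abs=1e-14)


# ---------------------------------------------------------------------------
# stroke work


def test_rectangular_pv_loop_closed_form():
    # eject at 90 mmHg, fill at 10 mmHg, SV 60 mL -> 0.640 J
    v = np.array([160.0, 100.0, 100.0, 160.0])
    p = np.array([90.0, 90.0, 10.0, 10.0])
    assert pv_stroke_work(v, p) == pytest.approx(0.640, abs=5e-4)
    with pytest.warns(UserWarning):  # constant volume: degenerate loop
        assert pv_stroke_work(np.full(4, 120.0), p) == 0.0


def test_longitudinal_work_zero_without_displacement():
    f = np.linspace(10, 60, 30)
    assert longitudinal_stroke_work(f, np.zeros(30)) == 0.0


def test_radial_work_is_additive_over_slices():
    t = np.arange(50) / 50
    d = 2.0 * np.sin(np.pi * t) ** 2
    f = 30.0 + 40.0 * np.sin(np.pi * (t - 0.05)) ** 2
    single, _ = radial_stroke_work({0: f}, {0: d})
    double, per = radial_stroke_work({0: f, 1: f}, {0: d, 1: d})
    assert double == pytest.approx(2 * single, rel=1e-12)
    assert per[0] == pytest.approx(per[1])


def test_work_scales_linearly_with_pressure(thin_mixed_run):
    from lvloops.loops import decompose_stroke_work
    from lvloops.pressure import PressureCurve

    g = thin_mixed_run.geometry
    base = thin_mixed_run.decomposition
    doubled = decompose_stroke_work(
        g, PressureCurve(2.0 * thin_mixed_run.pressure.values)
    )
    assert doubled.sw_pv == pytest.approx(2 * base.sw_pv, rel=1e-9)
    assert doubled.sw_long == pytest.approx(2 * base.sw_long, rel=1e-9)
    assert doubled.sw_rad == pytest.approx(2 * base.sw_rad, rel=1e-9)
    assert doubled.frac_long == pytest.approx(base.frac_long, rel=1e-9)


# ---------------------------------------------------------------------------
# stroke-volume partition and WEV


def test_sv_partition_arithmetic_matches_cohort_scale_example():
    sv_long, sv_rad = sv_partition(16.0, [42.0, 40.0, 35.0], 115.0)
    assert sv_long == pytest.approx(65.6)
    assert sv_rad == pytest.approx(49.4)


def test_sv_partition_zero_avpd_puts_all_in_radial():
    sv_long, sv_rad = sv_partition(0.0, [40.0, 41.0], 80.0)
    assert sv_long == 0.0 and sv_rad == 80.0


def test_sv_partition_warns_when_longitudinal_exceeds_total():
    with pytest.warns(UserWarning):
        sv_long, sv_rad = sv_partition(30.0, [40.0, 41.0], 50.0)
    assert sv_rad < 0


def test_sv_partition_needs_two_areas():
    with pytest.raises(InvalidInputError):
        sv_partition(10.0, [40.0], 50.0)


def test_wev_arithmetic_and_scale_invariance():
    assert work_per_ejected_volume(0.59, 50.0) == pytest.approx(11.8)
    assert work_per_ejected_volume(0.0, 50.0) == 0.0
    assert work_per_ejected_volume(1.18, 100.0) == pytest.approx(
        work_per_ejected_volume(0.59, 50.0)
    )
    with pytest.raises(InvalidInputError):
        work_per_ejected_volume(0.5, 0.0)


def test_max_systolic_avpd_is_circular():
    avpd = np.roll(np.concatenate([np.linspace(0, 9, 40), np.linspace(9, 0, 60)]), 70)
    assert max_systolic_avpd(avpd, 70, (70 + 39) % 100) == pytest.approx(9.0)


def test_decomposition_percentages_sum_to_100(default_run):
    d = default_run.decomposition
    assert d.frac_long + d.frac_rad == pytest.approx(100.0)
    assert d.sv_long + d.sv_rad == pytest.approx(d.sv)
    assert d.sw_fl_total == pytest.approx(d.sw_long + d.sw_rad)
    assert d.sw_pv > 0 and d.sw_long > 0 and d.sw_rad > 0


def test_decomposition_fraction_example():
    # 0.19 J longitudinal, 0.20 J radial -> 48.7 / 51.3 %
    frac = 100 * 0.19 / (0.19 + 0.20)
    assert frac == pytest.approx(48.7, abs=0.05)
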