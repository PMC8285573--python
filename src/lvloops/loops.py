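"""Force-length loops and the stroke-work decomposition.

The blood pressure P exerts a balancing force F = P x A on each
myocardial surface (Newton's third law). Two global force-length loops
follow:

- *Longitudinal*: F_long = P x (maximum epicardial cross-sectional
  area), paired with the AV-plane displacement. The epicardial — not
  endocardial — area is used because both the blood pool and the
  myocardium shorten longitudinally, like a piston spanning the whole
  epicardial cross-section.
- *Radial*: per short-axis slice, F_rad = P x (endocardial surface
  area of that slice), paired with the inward epicardial displacement.
  The epicardial displacement isolates tissue displacement from wall
  thickening; one loop is integrated per slice because the ventricle
  is not circular, and the slice areas differ.

The area inside each loop is the work done in that direction; their
sum is validated against the conventional pressure-volume (PV) loop
stroke work. The stroke volume is partitioned analogously
(longitudinal SV = maximal end-systolic AV-plane displacement x the
mean of the two largest basal epicardial areas at ED), giving the work
per ejected volume (WEV, mJ/mL) of each pumping mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from lvloops.errors import InvalidInputError
from lvloops.geometry import GeometrySeries
from lvloops.pressure import PressureCurve
from lvloops.units import CM2_TO_M2, J_TO_MJ, MMHG_TO_PA, ML_TO_M3, MM_TO_M


@dataclass
class WorkDecomposition:
    """Stroke-work decomposition of one heartbeat.

    ``sw_pv`` is the reference PV-loop stroke work; ``sw_long`` and
    ``sw_rad`` the force-length loop areas; ``frac_*`` their shares of
    the force-length total in percent. ``sv_long``/``sv_rad`` is the
    stroke-volume partition and ``wev_*`` the work per ejected volume.
    """

    sw_pv: float  # J
    sw_long: float  # J
    sw_rad: float  # J
    sw_rad_by_slice: dict[int, float]  # J
    sv: float  # mL
    sv_long: float  # mL
    sv_rad: float  # mL

    @property
    def sw_fl_total(self) -> float:
        return self.sw_long + self.sw_rad

    @property
    def frac_long(self) -> float:
        return 100.0 * self.sw_long / self.sw_fl_total

    @property
    def frac_rad(self) -> float:
        return 100.0 * self.sw_rad / self.sw_fl_total

    @property
    def fl_vs_pv_percent(self) -> float:
        """Signed relative difference of FL-total vs PV stroke work, %."""
        return 100.0 * (self.sw_fl_total - self.sw_pv) / self.sw_pv

    @property
    def wev_long(self) -> float:
        """Longitudinal work per ejected volume, mJ/mL (nan if sv_long <= 0)."""
        if self.sv_long <= 0:
            return float("nan")
        return work_per_ejected_volume(self.sw_long, self.sv_long)

    @property
    def wev_rad(self) -> float:
        """Radial work per ejected volume, mJ/mL (nan if sv_rad <= 0)."""
        if self.sv_rad <= 0:
            return float("nan")
        return work_per_ejected_volume(self.sw_rad, self.sv_rad)

    def to_dict(self) -> dict[str, float | dict[int, float]]:
        """Unit-suffixed flat export."""
        return {
            "sw_pv_J": self.sw_pv,
            "sw_long_J": self.sw_long,
            "sw_rad_J": self.sw_rad,
            "sw_fl_total_J": self.sw_fl_total,
            "sw_rad_by_slice_J": dict(self.sw_rad_by_slice),
            "frac_long_pct": self.frac_long,
            "frac_rad_pct": self.frac_rad,
            "fl_vs_pv_pct": self.fl_vs_pv_percent,
            "sv_mL": self.sv,
            "sv_long_mL": self.sv_long,
            "sv_rad_mL": self.sv_rad,
            "wev_long_mJ_per_mL": self.wev_long,
            "wev_rad_mJ_per_mL": self.wev_rad,
        }


# ---------------------------------------------------------------------------
# forces


def force_from_pressure_area(pressure_mmhg, area_cm2):
    """F = P x A in newtons, from mmHg and cm^2 (scalar or elementwise)."""
    p = np.asarray(pressure_mmhg, dtype=float)
    a = np.asarray(area_cm2, dtype=float)
    if np.any(a < 0):
        raise InvalidInputError("area must be >= 0")
    out = p * MMHG_TO_PA * a * CM2_TO_M2
    return float(out) if out.ndim == 0 else out


def longitudinal_force(
    pressure: PressureCurve, max_epi_cross_section: np.ndarray
) -> np.ndarray:
    """Longitudinal force per grid point, N."""
    a = np.asarray(max_epi_cross_section, dtype=float)
    if a.shape != pressure.values.shape:
        raise InvalidInputError("pressure and area grids differ in length")
    return force_from_pressure_area(pressure.values, a)


def radial_force_slice(
    pressure: PressureCurve, endo_surface_area: np.ndarray
) -> np.ndarray:
    """Radial force of one slice per grid point, N."""
    a = np.asarray(endo_surface_area, dtype=float)
    if a.shape != pressure.values.shape:
        raise InvalidInputError("pressure and area grids differ in length")
    return force_from_pressure_area(pressure.values, a)


# ---------------------------------------------------------------------------
# loop integration


def signed_loop_area(x: Sequence[float], y: Sequence[float]) -> float:
    """Signed shoelace area of the closed loop traced by (x(t), y(t)).

    Positive for counterclockwise traversal.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidInputError("loop coordinates must be equal-length 1-D")
    return 0.5 * float(
        np.sum(xa * np.roll(ya, -1) - np.roll(xa, -1) * ya)
    )


def loop_area(x: Sequence[float], y: Sequence[float]) -> float:
    """Absolute area enclosed by the closed loop (x(t), y(t)), in the
    product unit of the inputs (J for metres and newtons).

    Orientation-free: traversal direction does not change the result.
    Degenerate loops (fewer than 3 distinct vertices) yield 0 with a
    warning.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.unique(np.column_stack([xa, ya]), axis=0).shape[0] < 3:
        warnings.warn("degenerate loop with <3 distinct vertices; area = 0",
                      stacklevel=2)
        return 0.0
    return abs(signed_loop_area(xa, ya))


# ---------------------------------------------------------------------------
# stroke work


def pv_stroke_work(volume_ml: Sequence[float], pressure_mmhg: Sequence[float]) -> float:
    """Stroke work as the area within the pressure-volume loop, J."""
    v = np.asarray(volume_ml, dtype=float)
    p = np.asarray(pressure_mmhg, dtype=float)
    if v.shape != p.shape:
        raise InvalidInputError("volume and pressure grids differ in length")
    return loop_area(v * ML_TO_M3, p * MMHG_TO_PA)


def longitudinal_stroke_work(f_long: Sequence[float], avpd_mm: Sequence[float]) -> float:
    """Area of the longitudinal force-length loop, J."""
    f = np.asarray(f_long, dtype=float)
    d = np.asarray(avpd_mm, dtype=float)
    if f.shape != d.shape:
        raise InvalidInputError("force and displacement grids differ in length")
    return loop_area(d * MM_TO_M, f)


def radial_stroke_work(
    f_rad_by_slice: Mapping[int, Sequence[float]],
    epi_disp_by_slice: Mapping[int, Sequence[float]],
) -> tuple[float, dict[int, float]]:
    """Total radial stroke work and the per-slice breakdown, J.

    One force-length loop per included slice; the total is the sum of
    the slice-loop areas.
    """
    slices = sorted(f_rad_by_slice)
    if not slices:
        raise InvalidInputError("no included slices for radial stroke work")
    if set(slices) != set(epi_disp_by_slice):
        raise InvalidInputError("force and displacement slice sets differ")
    per_slice = {
        s: longitudinal_stroke_work(f_rad_by_slice[s], epi_disp_by_slice[s])
        for s in slices
    }
    return sum(per_slice.values()), per_slice


def sv_partition(
    avpd_max_es_mm: float,
    basal_epi_areas_ed_cm2: Sequence[float],
    sv_ml: float,
) -> tuple[float, float]:
    """Partition stroke volume into longitudinal and radial parts, mL.

    sv_long = (maximum end-systolic AV-plane displacement) x (mean of
    the two largest basal epicardial cross-sections at ED); sv_rad is
    the remainder. A longitudinal part exceeding total SV is reported
    as-is (negative sv_rad) with a warning, so inconsistent inputs stay
    visible.
    """
    areas = np.asarray(basal_epi_areas_ed_cm2, dtype=float)
    if areas.size < 2:
        raise InvalidInputError("need at least 2 epicardial areas")
    if sv_ml <= 0:
        raise InvalidInputError("sv must be > 0")
    two_largest = np.sort(areas)[-2:]
    sv_long = (avpd_max_es_mm / 10.0) * float(two_largest.mean())  # cm * cm^2
    if sv_long > sv_ml:
        warnings.warn(
            f"longitudinal SV ({sv_long:.1f} mL) exceeds total SV "
            f"({sv_ml:.1f} mL); radial SV will be negative",
            stacklevel=2,
        )
    return sv_long, sv_ml - sv_long


def work_per_ejected_volume(sw_j: float, sv_ml: float) -> float:
    """Work per ejected volume, mJ/mL."""
    if sv_ml <= 0:
        raise InvalidInputError("sv must be > 0")
    return sw_j * J_TO_MJ / sv_ml


def max_systolic_avpd(
    avpd: np.ndarray, frame_of_ed: int, frame_of_es: int
) -> float:
    """Maximum AV-plane displacement over systole (ED to ES, circular), mm."""
    n = avpd.size
    length = (frame_of_es - frame_of_ed) % n
    idx = (frame_of_ed + np.arange(length + 1)) % n
    return float(avpd[idx].max())


def decompose_stroke_work(
    geometry: GeometrySeries, pressure: PressureCurve
) -> WorkDecomposition:
    """Full stroke-work decomposition of one beat.

    Computes PV-loop stroke work, the longitudinal and per-slice radial
    force-length loop areas, the stroke-volume partition and both WEV
    values, all from signals already aligned on the common cycle grid.
    """
    if pressure.n != geometry.n:
        raise InvalidInputError("pressure and geometry grids differ in length")
    sw_pv = pv_stroke_work(geometry.volume, pressure.values)

    f_long = longitudinal_force(pressure, geometry.max_epi_cross_section)
    sw_long = longitudinal_stroke_work(f_long, geometry.avpd)

    f_rad = {
        s: radial_force_slice(pressure, geometry.endo_surface_area[s])
        for s in geometry.included_slices
    }
    sw_rad, by_slice = radial_stroke_work(f_rad, geometry.epi_displacement)

    avpd_max = max_systolic_avpd(
        geometry.avpd, geometry.frame_of_ed, geometry.frame_of_es
    )
    basal_areas = [
        geometry.epi_area[s][geometry.frame_of_ed]
        for s in geometry.included_slices
    ]
    sv_long, sv_rad = sv_partition(avpd_max, basal_areas, geometry.sv)

    return WorkDecomposition(
        sw_pv=sw_pv,
        sw_long=sw_long,
        sw_rad=sw_rad,
        sw_rad_by_slice=by_slice,
        sv=geometry.sv,
        sv_long=sv_long,
        sv_rad=sv_rad,
    )
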