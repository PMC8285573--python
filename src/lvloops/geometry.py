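"""Contour-stack geometry and kinematics.

Turns short-axis endo/epicardial contour stacks and tracked basal
insertion points into the per-frame geometric signals the force-length
analysis needs — cavity volume, myocardial mass, endocardial surface
area and epicardial radius per slice, the maximum epicardial
cross-section, epicardial inward displacement, and atrioventricular
(AV) plane displacement — all resampled onto a common n-point cycle
grid (default 100) and optionally smoothed with a three-point sliding
mean.

Conventions
-----------
- Coordinates in mm; areas returned in cm^2; volumes in mL; mass in g.
- AV-plane displacement (AVPD) is positive toward the apex and zero at
  the end-diastolic (ED) grid point.
- Epicardial displacement is positive inward and zero at ED.
- ED is the grid point of maximum volume, end systole (ES) the grid
  point of minimum volume.
- The cardiac cycle is treated as periodic: resampling interpolates
  with wraparound and smoothing uses circular neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from lvloops.errors import InconsistentContourError, InvalidInputError
from lvloops.units import MM2_TO_CM2, MYOCARDIAL_DENSITY

ENDO = "endo"
EPI = "epi"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PlanarContour:
    """A closed planar contour (last point implicitly connects to first).

    Parameters
    ----------
    points
        Array of shape (n, 2), coordinates in mm, n >= 3.
    kind
        ``"endo"`` or ``"epi"``.
    """

    points: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError("contour points must have shape (n, 2)")
        if pts.shape[0] < 3:
            raise InvalidInputError("a contour needs at least 3 points")
        if self.kind not in (ENDO, EPI):
            raise InvalidInputError(f"unknown contour kind {self.kind!r}")
        closed = np.vstack([pts, pts[:1]])
        if np.any(np.all(np.diff(closed, axis=0) == 0.0, axis=1)):
            raise InvalidInputError("duplicated consecutive contour points")
        object.__setattr__(self, "points", pts)
        if _shoelace(pts) <= 0.0:
            raise InvalidInputError("contour encloses no area")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class CineContourSet:
    """Per-frame, per-slice endo/epi contours of a short-axis cine stack.

    ``contours[(frame, slice)]`` maps contour kind to
    :class:`PlanarContour`; a missing entry means the slice was not
    delineated in that frame (e.g. a basal slice crossed by the AV
    plane during systole).
    """

    n_frames: int
    n_slices: int
    slice_thickness: float  # mm
    slice_gap: float = 0.0  # mm
    frame_times_ms: np.ndarray | None = None
    contours: dict[tuple[int, int], dict[str, PlanarContour]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise InvalidInputError("slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise InvalidInputError("slice_gap must be >= 0")
        if self.n_frames < 3:
            raise InvalidInputError("need at least 3 frames")
        if self.frame_times_ms is not None:
            self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)

    @property
    def slice_spacing(self) -> float:
        """Centre-to-centre slice spacing in mm."""
        return self.slice_thickness + self.slice_gap

    def add(self, frame: int, slc: int, contour: PlanarContour) -> None:
        self.contours.setdefault((frame, slc), {})[contour.kind] = contour

    def get(self, frame: int, slc: int, kind: str) -> PlanarContour | None:
        return self.contours.get((frame, slc), {}).get(kind)

    def has(self, frame: int, slc: int, kind: str) -> bool:
        return self.get(frame, slc, kind) is not None

    def validate(self) -> None:
        """Check the stack invariants, raising on violation."""
        ok = False
        for s in range(self.n_slices):
            if all(
                self.has(f, s, ENDO) and self.has(f, s, EPI)
                for f in range(self.n_frames)
            ):
                ok = True
                break
        if not ok:
            raise InvalidInputError(
                "no slice has both endo and epi contours in every frame"
            )

    def slice_presence(self, slc: int) -> np.ndarray:
        """Boolean mask over frames where the slice has both contours."""
        return np.array(
            [self.has(f, slc, ENDO) and self.has(f, slc, EPI)
             for f in range(self.n_frames)]
        )

    def slices_complete_all_frames(self) -> list[int]:
        """Slices with both contours present in every frame."""
        return [
            s for s in range(self.n_slices) if bool(self.slice_presence(s).all())
        ]


@dataclass
class ViewTrack:
    """Two basal insertion points of one long-axis view, over all frames."""

    name: str
    apex_direction: np.ndarray  # (2,) unit vector, in-view coordinates
    points: np.ndarray  # (n_frames, 2, 2) mm

    def __post_init__(self) -> None:
        self.apex_direction = np.asarray(self.apex_direction, dtype=float)
        nrm = np.linalg.norm(self.apex_direction)
        if nrm == 0:
            raise InvalidInputError("apex_direction must be nonzero")
        self.apex_direction = self.apex_direction / nrm
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (2, 2):
            raise InvalidInputError("view points must have shape (n_frames, 2, 2)")


@dataclass
class InsertionPointTracks:
    """Six basal myocardial insertion points (two per long-axis view)."""

    views: list[ViewTrack]

    def __post_init__(self) -> None:
        if len(self.views) != 3:
            raise InvalidInputError("expected exactly 3 long-axis views")
        n = {v.points.shape[0] for v in self.views}
        if len(n) != 1:
            raise InvalidInputError("all views must cover the same frames")

    @property
    def n_frames(self) -> int:
        return self.views[0].points.shape[0]


class MassVariation(NamedTuple):
    """Per-frame percent deviation of LV mass from its cycle mean."""

    mean_pct: float
    sd_pct: float
    deviations_pct: np.ndarray


@dataclass
class GeometrySeries:
    """Derived per-grid-point geometric and kinematic signals.

    All arrays have length ``n``. Per-slice signals are keyed by slice
    index and cover the slices admitted by the basal-slice policy
    (``included_slices``); the rest are listed in ``excluded_slices``.
    """

    n: int
    volume: np.ndarray  # mL
    mass: np.ndarray  # g
    endo_surface_area: dict[int, np.ndarray]  # cm^2 per slice
    epi_area: dict[int, np.ndarray]  # cm^2 per slice (cross-section)
    epi_radius: dict[int, np.ndarray]  # mm per slice
    epi_displacement: dict[int, np.ndarray]  # mm, positive inward
    max_epi_cross_section: np.ndarray  # cm^2
    avpd: np.ndarray  # mm, positive toward apex
    frame_of_ed: int
    frame_of_es: int
    included_slices: list[int]
    excluded_slices: list[int]

    @property
    def edv(self) -> float:
        return float(self.volume[self.frame_of_ed])

    @property
    def esv(self) -> float:
        return float(self.volume[self.frame_of_es])

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per grid point per signal."""
        rows = []
        grid = np.arange(self.n)

        def emit(signal: str, values: np.ndarray, unit: str, slc=None):
            for g, v in zip(grid, values):
                rows.append(
                    {"grid_point": g, "signal": signal, "slice": slc,
                     "value": float(v), "unit": unit}
                )

        emit("volume", self.volume, "mL")
        emit("mass", self.mass, "g")
        emit("max_epi_cross_section", self.max_epi_cross_section, "cm2")
        emit("avpd", self.avpd, "mm")
        for s in self.included_slices:
            emit("endo_surface_area", self.endo_surface_area[s], "cm2", s)
            emit("epi_area", self.epi_area[s], "cm2", s)
            emit("epi_radius", self.epi_radius[s], "mm", s)
            emit("epi_displacement", self.epi_displacement[s], "mm", s)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal operations


def resample_cycle(values: Sequence[float], n: int) -> np.ndarray:
    """Resample one periodic cycle onto an ``n``-point grid.

    Samples are taken to lie at fractions i/m of the cycle (i = 0..m-1)
    and are interpolated piecewise-linearly with periodic wraparound,
    so the output grid j/n (j = 0..n-1) starts at the same cycle phase.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise InvalidInputError("need at least 3 samples spanning one cycle")
    if n < 3:
        raise InvalidInputError("target grid must have at least 3 points")
    m = y.size
    x = np.arange(m + 1) / m
    y_ext = np.append(y, y[0])
    return np.interp(np.arange(n) / n, x, y_ext)


def smooth_sliding_mean(values: Sequence[float]) -> np.ndarray:
    """Three-point sliding mean with circular boundary.

    The cardiac cycle is periodic, so the first and last grid points
    are neighbours; the circular window therefore conserves the cycle
    sum exactly.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise InvalidInputError("need at least 3 samples to smooth")
    return (np.roll(y, 1) + y + np.roll(y, -1)) / 3.0


# ---------------------------------------------------------------------------
# contour measurements


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(contour: PlanarContour) -> float:
    """Perimeter of the closed contour polygon, mm."""
    pts = contour.points
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def polygon_area(contour: PlanarContour) -> float:
    """Absolute (orientation-independent) enclosed area, mm^2."""
    return float(_shoelace(contour.points))


def contour_centroid(contour: PlanarContour) -> np.ndarray:
    """Centre point: arithmetic mean of the contour points, mm."""
    return contour.points.mean(axis=0)


def epicardial_radius(contour: PlanarContour) -> float:
    """Mean distance from the point-centroid to the contour points, mm."""
    c = contour_centroid(contour)
    return float(np.mean(np.linalg.norm(contour.points - c, axis=1)))


def endocardial_surface_area(
    contour: PlanarContour, slice_thickness: float, *, strict: bool = False
) -> float:
    """Endocardial surface area of one slice, cm^2.

    Circumference of the endocardial delineation multiplied by the
    slice thickness. With ``strict`` a non-endocardial contour raises
    instead of warning.
    """
    if slice_thickness <= 0:
        raise InvalidInputError("slice_thickness must be > 0")
    if contour.kind != ENDO:
        msg = "endocardial_surface_area called on a non-endocardial contour"
        if strict:
            raise InvalidInputError(msg)
        warnings.warn(msg, stacklevel=2)
    return polygon_perimeter(contour) * slice_thickness * MM2_TO_CM2


# ---------------------------------------------------------------------------
# frame-level measurements


def lv_volume(contour_set: CineContourSet, frame: int) -> float:
    """Cavity volume of one frame by disc summation, mL.

    Sum over slices (with an endocardial contour in this frame) of the
    endocardial cross-sectional area times the slice spacing. Basal
    slices absent in a frame — crossed by the AV plane — simply do not
    contribute, which is what makes the disc sum track longitudinal
    volume displacement.
    """
    total = 0.0
    found = False
    for s in range(contour_set.n_slices):
        c = contour_set.get(frame, s, ENDO)
        if c is not None:
            total += polygon_area(c) * contour_set.slice_spacing
            found = True
    if not found:
        raise InvalidInputError(f"frame {frame} has no endocardial contours")
    return total / 1000.0  # mm^3 -> mL


def lv_mass(
    contour_set: CineContourSet, frame: int, density: float = MYOCARDIAL_DENSITY
) -> float:
    """Myocardial mass of one frame, g: wall volume x tissue density."""
    wall_mm3 = 0.0
    found = False
    for s in range(contour_set.n_slices):
        endo = contour_set.get(frame, s, ENDO)
        epi = contour_set.get(frame, s, EPI)
        if endo is None or epi is None:
            continue
        a_endo, a_epi = polygon_area(endo), polygon_area(epi)
        if a_epi < a_endo:
            raise InconsistentContourError(
                f"frame {frame}, slice {s}: epicardial area smaller than "
                "endocardial area"
            )
        wall_mm3 += (a_epi - a_endo) * contour_set.slice_spacing
        found = True
    if not found:
        raise InvalidInputError(f"frame {frame} has no endo+epi contour pair")
    return wall_mm3 / 1000.0 * density


def mass_variation(mass: Sequence[float]) -> MassVariation:
    """Per-frame percent deviation of mass from the cycle mean.

    Myocardial mass is conserved over the heartbeat, so this is the
    standard consistency check on the delineations.
    """
    m = np.asarray(mass, dtype=float)
    if m.size < 3:
        raise InvalidInputError("need at least 3 mass samples")
    mean = m.mean()
    if mean == 0:
        raise InvalidInputError("zero mean mass")
    dev = 100.0 * (m - mean) / mean
    return MassVariation(float(dev.mean()), float(dev.std(ddof=1)), dev)


def max_epicardial_cross_section(contour_set: CineContourSet, frame: int) -> float:
    """Largest epicardial cross-sectional area over slices, cm^2."""
    areas = [
        polygon_area(c)
        for s in range((contour_set.n_slices))
        if (c := contour_set.get(frame, s, EPI)) is not None
    ]
    if not areas:
        raise InvalidInputError(f"frame {frame} has no epicardial contours")
    return max(areas) * MM2_TO_CM2


# ---------------------------------------------------------------------------
# displacements


def radial_displacement(epi_radius_series: Sequence[float], frame_of_ed: int) -> np.ndarray:
    """Inward epicardial displacement d_epi(t) = r_ED - r(t), mm."""
    r = np.asarray(epi_radius_series, dtype=float)
    if not 0 <= frame_of_ed < r.size:
        raise InvalidInputError("frame_of_ed outside the radius series")
    return r[frame_of_ed] - r


def _point_plane_distances(
    tracks: InsertionPointTracks, frame_of_ed: int
) -> np.ndarray:
    """Signed perpendicular distance of each of the 6 points to its
    view's ED AV-plane line, positive toward the apex. Shape (6, n_frames)."""
    if not 0 <= frame_of_ed < tracks.n_frames:
        raise InvalidInputError("frame_of_ed outside the tracks")
    out = []
    for view in tracks.views:
        p_ed = view.points[frame_of_ed]  # (2, 2)
        along = p_ed[1] - p_ed[0]
        if np.linalg.norm(along) == 0:
            raise InvalidInputError(
                f"view {view.name!r}: ED insertion points coincide, "
                "AV-plane line undefined"
            )
        normal = np.array([-along[1], along[0]])
        normal /= np.linalg.norm(normal)
        if normal @ view.apex_direction < 0:
            normal = -normal
        for k in (0, 1):
            out.append((view.points[:, k, :] - p_ed[0]) @ normal)
    return np.asarray(out)


def av_plane_displacement(
    tracks: InsertionPointTracks, frame_of_ed: int
) -> np.ndarray:
    """Global AV-plane displacement per frame, mm, positive toward apex.

    For each insertion point, the signed perpendicular distance to its
    view's end-diastolic AV-plane line (through that view's two ED
    point positions); the global AVPD is the mean over all six points.
    Zero at the ED frame by construction.
    """
    return _point_plane_distances(tracks, frame_of_ed).mean(axis=0)


# ---------------------------------------------------------------------------
# pipeline


def _fill_gaps_periodic(values: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Linearly interpolate missing samples of a periodic cycle signal."""
    if present.all():
        return values
    if not present.any():
        raise InvalidInputError("signal has no present samples")
    m = values.size
    idx = np.flatnonzero(present)
    # unwrap onto an extended axis so interpolation crosses the cycle seam
    x = np.concatenate([idx, idx + m])
    y = np.concatenate([values[idx], values[idx]])
    return np.interp(np.arange(m) + m, x, y)


def compute_geometry_series(
    contour_set: CineContourSet,
    tracks: InsertionPointTracks | None = None,
    *,
    n: int = 100,
    smooth: bool = True,
    density: float = MYOCARDIAL_DENSITY,
    basal_slice_policy: str = "zero_force",
) -> GeometrySeries:
    """Full geometry/kinematics pipeline on a common cycle grid.

    Per-frame measurements are resampled (periodic linear) to ``n``
    grid points and, if ``smooth``, passed through the circular
    three-point sliding mean. ED/ES are then the grid points of
    maximum/minimum volume, and both displacement signals are
    re-referenced so they are exactly zero at ED.

    ``basal_slice_policy`` governs slices the AV plane crosses during
    systole (contours absent in some frames):

    - ``"zero_force"`` (default): the slice participates in the radial
      computations with endocardial surface area zero while it is
      absent — there is no ventricular wall at that level then — which
      is the exact accounting of the radial work done by the basal
      band the AV plane sweeps.
    - ``"exclude"``: only slices delineated in every frame enter the
      per-slice radial computations; partially present slices are
      dropped (and listed in ``excluded_slices``), which discards the
      basal band's radial work.
    """
    if basal_slice_policy not in ("zero_force", "exclude"):
        raise InvalidInputError(f"unknown basal_slice_policy {basal_slice_policy!r}")
    contour_set.validate()
    if tracks is not None and tracks.n_frames != contour_set.n_frames:
        raise InvalidInputError("tracks and contours cover different frame counts")
    nf = contour_set.n_frames

    def prep(per_frame: np.ndarray) -> np.ndarray:
        g = resample_cycle(per_frame, n)
        return smooth_sliding_mean(g) if smooth else g

    volume = prep(np.array([lv_volume(contour_set, f) for f in range(nf)]))
    mass = prep(np.array([lv_mass(contour_set, f, density) for f in range(nf)]))
    max_cs = prep(
        np.array([max_epicardial_cross_section(contour_set, f) for f in range(nf)])
    )

    frame_of_ed = int(np.argmax(volume))
    frame_of_es = int(np.argmin(volume))

    full = contour_set.slices_complete_all_frames()
    if basal_slice_policy == "zero_force":
        included = [
            s for s in range(contour_set.n_slices)
            if contour_set.slice_presence(s).any()
        ]
    else:
        included = full
    excluded = [s for s in range(contour_set.n_slices) if s not in included]

    endo_sa: dict[int, np.ndarray] = {}
    epi_area: dict[int, np.ndarray] = {}
    epi_rad: dict[int, np.ndarray] = {}
    epi_disp: dict[int, np.ndarray] = {}
    for s in included:
        present = contour_set.slice_presence(s)
        sa = np.zeros(nf)
        area = np.zeros(nf)
        rad = np.zeros(nf)
        for f in np.flatnonzero(present):
            sa[f] = endocardial_surface_area(
                contour_set.get(f, s, ENDO), contour_set.slice_thickness
            )
            area[f] = polygon_area(contour_set.get(f, s, EPI)) * MM2_TO_CM2
            rad[f] = epicardial_radius(contour_set.get(f, s, EPI))
        endo_sa[s] = prep(sa)  # zero while absent: no wall at that level
        epi_area[s] = prep(area)
        epi_rad[s] = prep(_fill_gaps_periodic(rad, present))
        epi_disp[s] = radial_displacement(epi_rad[s], frame_of_ed)

    if tracks is not None:
        ed_frame_raw = int(
            np.argmax([lv_volume(contour_set, f) for f in range(nf)])
        )
        per_point = _point_plane_distances(tracks, ed_frame_raw)
        avpd = np.mean([prep(d) for d in per_point], axis=0)
        avpd = avpd - avpd[frame_of_ed]
    else:
        avpd = np.zeros(n)

    return GeometrySeries(
        n=n,
        volume=volume,
        mass=mass,
        endo_surface_area=endo_sa,
        epi_area=epi_area,
        epi_radius=epi_rad,
        epi_displacement=epi_disp,
        max_epi_cross_section=max_cs,
        avpd=avpd,
        frame_of_ed=frame_of_ed,
        frame_of_es=frame_of_es,
        included_slices=included,
        excluded_slices=excluded,
    )
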