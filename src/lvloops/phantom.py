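"""Synthetic deforming-LV phantom with analytic ground truth.

A wall-volume-conserving cylinder stands in for the left ventricle:
the apex is fixed, the AV plane (the base) descends toward the apex by
the AV-plane displacement avpd(t) (longitudinal pumping), and the
epicardial radius moves inward by d_epi(t) (radial pumping). The
endocardial radius follows from conservation of the myocardial wall
volume

    pi * (r_epi^2 - r_endo^2) * L = const,   L(t) = L_ED - avpd(t).

This reproduces the two defining behaviours of the piston/cylinder
model: isolated longitudinal contraction thickens the wall without
epicardial inward motion, and the blood volume displaced by AV-plane
motion equals the epicardial cross-section times the plane travel. The
generator emits exactly the inputs the analysis pipeline consumes —
short-axis contour stacks (contours exist in a frame only when the
slice centre lies apical to the AV plane), insertion-point tracks and
a two-phase pressure waveform — plus a :class:`PhantomTruth` computed
on a dense internal time grid, independent of the emitted frames.

Default dimensions emulate a mid-size adult/large-swine ventricle
(EDV ~100 mL, SV ~59 mL, AVPD 12 mm, epicardial excursion 2 mm, 30
frames) with sub-millimetre slices so that disc-summation
discretization stays well below the test tolerances (clinical stacks
use ~8 mm slices; the thin slices isolate model behaviour from
discretization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from lvloops.errors import InvalidInputError
from lvloops.geometry import (
    CineContourSet,
    InsertionPointTracks,
    PlanarContour,
    ViewTrack,
)
from lvloops.pressure import PressureRecording
from lvloops.units import MMHG_TO_PA, ML_TO_M3


@dataclass(frozen=True)
class PhantomPressure:
    """Two-phase pressure waveform specification, mmHg.

    ``rectangular``: pressure is ``eject_level`` while volume falls and
    ``fill_level`` while it rises (with ``edp`` at the single ED
    instant), which makes stroke work exactly (eject - fill) * SV.
    ``smooth``: a continuously differentiable pulse
    edp + (eject_level - edp) * sin^2(pi t / t_pulse) over systole and
    early relaxation, settling at ``edp`` through diastole.
    """

    edp: float = 5.0
    fill_level: float = 10.0
    eject_level: float = 110.0
    waveform: str = "smooth"

    def __post_init__(self) -> None:
        if self.eject_level <= self.fill_level:
            raise InvalidInputError("eject_level must exceed fill_level")
        if self.waveform not in ("rectangular", "smooth"):
            raise InvalidInputError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, motion and acquisition parameters of the phantom."""

    r_epi_ed: float = 30.0  # mm
    wall_thickness_ed: float = 10.0  # mm
    length_ed: float = 80.0  # mm
    slice_thickness: float = 0.5  # mm
    n_slices: int | None = None  # default: fill length_ed
    n_frames: int = 30
    points_per_contour: int = 80
    avpd_amplitude: float = 12.0  # mm
    epi_inward_amplitude: float = 2.0  # mm
    systole_fraction: float = 0.35
    pressure: PhantomPressure = field(default_factory=PhantomPressure)
    rr_s: float = 1.0  # cycle duration
    noise_sd: float = 0.0  # mm, radial contour noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.wall_thickness_ed < self.r_epi_ed:
            raise InvalidInputError("require 0 < wall thickness < epicardial radius")
        if not 0 <= self.avpd_amplitude < self.length_ed:
            raise InvalidInputError("avpd_amplitude must be in [0, length_ed)")
        if self.epi_inward_amplitude < 0:
            raise InvalidInputError("amplitudes must be >= 0")
        if self.n_frames < 10:
            raise InvalidInputError("need at least 10 frames")
        if not 0 < self.systole_fraction < 1:
            raise InvalidInputError("systole_fraction must be in (0, 1)")
        if self.slice_thickness <= 0 or self.points_per_contour < 3:
            raise InvalidInputError("invalid slice/contour discretization")

    @property
    def slices(self) -> int:
        if self.n_slices is not None:
            return self.n_slices
        return int(math.floor(self.length_ed / self.slice_thickness))

    @property
    def r_endo_ed(self) -> float:
        return self.r_epi_ed - self.wall_thickness_ed

    @property
    def wall_volume_mm3(self) -> float:
        return math.pi * (self.r_epi_ed**2 - self.r_endo_ed**2) * self.length_ed


def thin_wall_params(**overrides) -> PhantomParams:
    """Membrane-limit phantom: wall 0.3 mm (wall/r_epi = 1%).

    In the cylinder model the force-length total deviates from PV
    stroke work by -loop-integral of P * 2 pi L w d(d_epi) — first
    order in the wall thickness w — so energy-conservation checks in
    the thin-wall limit need w << r_epi, not merely w of a few mm.
    """
    return PhantomParams(**{"wall_thickness_ed": 0.3, **overrides})


def patient_like_params(**overrides) -> PhantomParams:
    """Dilated ventricle emulating a heart-failure patient: EDV
    ~350 mL, EF ~26%, AVPD 8.3 mm, epicardial excursion 1.7 mm."""
    defaults = dict(
        r_epi_ed=45.0,
        length_ed=90.0,
        wall_thickness_ed=10.0,
        avpd_amplitude=8.3,
        epi_inward_amplitude=1.7,
        slice_thickness=0.6,
    )
    return PhantomParams(**{**defaults, **overrides})


@dataclass
class PhantomTruth:
    """Ground truth on a dense internal time grid (independent of the
    emitted frames).

    ``sv_long``/``sv_rad`` follow the method's own definition
    (maximal end-systolic AV-plane displacement times the basal ED
    epicardial cross-section, remainder radial) evaluated on the exact
    cylinder; ``sv_long_exact`` is the exact longitudinal volume
    displacement integral over systole, for reference.
    """

    n_dense: int
    t: np.ndarray  # cycle fraction
    avpd: np.ndarray  # mm
    d_epi: np.ndarray  # mm
    volume: np.ndarray  # mL
    pressure: np.ndarray  # mmHg
    wall_volume: float  # mL
    sv: float  # mL
    sv_long: float  # mL
    sv_rad: float  # mL
    sv_long_exact: float  # mL
    sw_pv: float  # J


# ---------------------------------------------------------------------------
# motion and pressure models


def _activation(t: np.ndarray | float, systole_fraction: float) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 activation: half-cosine rise over systole,
    half-cosine return over diastole."""
    t = np.asarray(t, dtype=float) % 1.0
    ts = systole_fraction
    rise = 0.5 * (1.0 - np.cos(np.pi * t / ts))
    fall = 0.5 * (1.0 + np.cos(np.pi * (t - ts) / (1.0 - ts)))
    return np.where(t <= ts, rise, fall)


def motion_model(
    params: PhantomParams, t: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(avpd, r_epi, r_endo, L) at cycle fraction(s) ``t``.

    The endocardial radius solves the wall-volume conservation
    constraint; parameters for which the wall would fill the whole
    cavity (r_endo^2 < 0) are rejected.
    """
    s = _activation(t, params.systole_fraction)
    avpd = params.avpd_amplitude * s
    d_epi = params.epi_inward_amplitude * s
    length = params.length_ed - avpd
    r_epi = params.r_epi_ed - d_epi
    r_endo_sq = r_epi**2 - params.wall_volume_mm3 / (np.pi * length)
    if np.any(r_endo_sq <= 0):
        raise InvalidInputError(
            "wall-volume conservation unsolvable: wall would fill the cavity"
        )
    return avpd, r_epi, np.sqrt(r_endo_sq), length


def cavity_volume(params: PhantomParams, t: np.ndarray | float) -> np.ndarray:
    """Exact cavity volume at cycle fraction(s) ``t``, mL."""
    _, _, r_endo, length = motion_model(params, t)
    return np.pi * r_endo**2 * length / 1000.0


def pressure_waveform(params: PhantomParams, t: np.ndarray | float) -> np.ndarray:
    """Phantom LV pressure at cycle fraction(s) ``t``, mmHg."""
    spec = params.pressure
    t = np.asarray(t, dtype=float) % 1.0
    if spec.waveform == "rectangular":
        ts = params.systole_fraction
        p = np.where(t <= ts, spec.eject_level, spec.fill_level)
        p = np.where(t == 0.0, spec.edp, p)
        return p
    t_pulse = min(1.25 * params.systole_fraction, 0.95)
    pulse = np.sin(np.pi * np.minimum(t, t_pulse) / t_pulse) ** 2
    return spec.edp + (spec.eject_level - spec.edp) * pulse


# ---------------------------------------------------------------------------
# ground truth


def _dense_truth(params: PhantomParams, n_dense: int = 2000) -> PhantomTruth:
    # put the end of systole exactly on the dense grid so the volume
    # extremes are sampled exactly
    n_dense = int(
        round(round(n_dense * params.systole_fraction) / params.systole_fraction)
    )
    t = np.arange(n_dense) / n_dense
    avpd, r_epi, r_endo, length = motion_model(params, t)
    volume = np.pi * r_endo**2 * length / 1000.0
    pressure = pressure_waveform(params, t)
    sv = float(volume.max() - volume.min())

    if params.pressure.waveform == "rectangular":
        sw_pv = (
            (params.pressure.eject_level - params.pressure.fill_level)
            * MMHG_TO_PA
            * sv
            * ML_TO_M3
        )
    else:
        v_si = np.append(volume, volume[0]) * ML_TO_M3
        p_si = np.append(pressure, pressure[0]) * MMHG_TO_PA
        sw_pv = abs(float(np.trapezoid(p_si, v_si)))

    # method-definition longitudinal SV: max end-systolic AVPD (cm) x
    # basal ED epicardial cross-section (cm^2)
    sv_long = (params.avpd_amplitude / 10.0) * (np.pi * params.r_epi_ed**2 / 100.0)
    # exact piston integral over systole: int pi r_epi^2 d(avpd)
    sys_mask = t <= params.systole_fraction
    sv_long_exact = float(
        np.trapezoid(np.pi * r_epi[sys_mask] ** 2, avpd[sys_mask]) / 1000.0
    )
    return PhantomTruth(
        n_dense=n_dense,
        t=t,
        avpd=avpd,
        d_epi=params.r_epi_ed - r_epi,
        volume=volume,
        pressure=pressure,
        wall_volume=params.wall_volume_mm3 / 1000.0,
        sv=sv,
        sv_long=float(sv_long),
        sv_rad=float(sv - sv_long),
        sv_long_exact=sv_long_exact,
        sw_pv=float(sw_pv),
    )


# ---------------------------------------------------------------------------
# emission


@dataclass
class PhantomData:
    """Everything the generator emits for one synthetic subject."""

    params: PhantomParams
    contours: CineContourSet
    tracks: InsertionPointTracks
    pressure_frames: np.ndarray  # mmHg at the emitted frame times
    truth: PhantomTruth


def _circle(center: np.ndarray, radius: float, n: int,
            noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    r = radius + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def generate_phantom(params: PhantomParams) -> PhantomData:
    """Generate one synthetic subject (contours, tracks, pressure, truth).

    Slices sit at fixed stations z_i = (i + 1/2) * slice thickness
    below the ED base; a slice's contours exist in a frame iff its
    centre lies apical to the AV plane in that frame. The same seed
    yields bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    nf = params.n_frames
    t = np.arange(nf) / nf
    avpd, r_epi, r_endo, _ = motion_model(params, t)

    contours = CineContourSet(
        n_frames=nf,
        n_slices=params.slices,
        slice_thickness=params.slice_thickness,
        slice_gap=0.0,
        frame_times_ms=t * params.rr_s * 1000.0,
    )
    center = np.array([0.0, 0.0])
    z = (np.arange(params.slices) + 0.5) * params.slice_thickness
    for f in range(nf):
        for s in range(params.slices):
            if z[s] <= avpd[f]:
                continue  # slice is basal to the AV plane: atrium, no LV wall
            contours.add(
                f, s,
                PlanarContour(
                    _circle(center, r_endo[f], params.points_per_contour,
                            params.noise_sd, rng),
                    "endo",
                ),
            )
            contours.add(
                f, s,
                PlanarContour(
                    _circle(center, r_epi[f], params.points_per_contour,
                            params.noise_sd, rng),
                    "epi",
                ),
            )

    # two insertion points per long-axis view, riding on the AV plane;
    # in-view coordinates: x across the plane, y toward the apex
    views = []
    for name in ("2ch", "3ch", "4ch"):
        pts = np.empty((nf, 2, 2))
        pts[:, 0, 0] = -r_epi
        pts[:, 1, 0] = r_epi
        pts[:, 0, 1] = avpd
        pts[:, 1, 1] = avpd
        views.append(ViewTrack(name=name, apex_direction=np.array([0.0, 1.0]),
                               points=pts.copy()))
    tracks = InsertionPointTracks(views=views)

    return PhantomData(
        params=params,
        contours=contours,
        tracks=tracks,
        pressure_frames=pressure_waveform(params, t),
        truth=_dense_truth(params),
    )


def frame_pressure_curve(data: PhantomData, n: int = 100):
    """The phantom's per-frame pressure resampled onto the analysis
    grid, as a :class:`~lvloops.pressure.PressureCurve` (frames start
    at ED, so no synchronization shift is needed)."""
    from lvloops.geometry import resample_cycle
    from lvloops.pressure import PressureCurve

    return PressureCurve(resample_cycle(data.pressure_frames, n))


def phantom_pressure_recording(
    params: PhantomParams,
    *,
    n_beats: int = 10,
    sample_dt_s: float = 0.004,
    period_jitter: float = 0.0,
    noise_sd_mmhg: float = 0.0,
    seed: int | None = None,
) -> PressureRecording:
    """A multi-beat invasive-style pressure recording of the phantom.

    Beats use the smooth waveform; per-beat duration is jittered by a
    uniform factor in (1 - jitter, 1 + jitter). For the invasive
    analysis route (beat detection, beat averaging, synchronization).
    """
    if n_beats < 1:
        raise InvalidInputError("need at least one beat")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    smooth = replace(params, pressure=replace(params.pressure, waveform="smooth"))
    durations = params.rr_s * (
        1.0 + period_jitter * rng.uniform(-1.0, 1.0, n_beats)
    )
    times, values = [], []
    t0 = 0.0
    for dur in durations:
        nb = max(int(round(dur / sample_dt_s)), 8)
        tb = np.arange(nb) / nb
        times.append(t0 + tb * dur)
        values.append(pressure_waveform(smooth, tb))
        t0 += dur
    times = np.concatenate(times)
    values = np.concatenate(values)
    if noise_sd_mmhg > 0:
        values = values + rng.normal(0.0, noise_sd_mmhg, values.size)
    return PressureRecording(times=times, values=values)


def params_for_sv_split(
    base: PhantomParams, sv_total_ml: float, long_fraction: float
) -> PhantomParams:
    """Solve motion amplitudes so the phantom has a prescribed total SV
    and longitudinal SV fraction (by the method's SV-partition
    definition on the exact geometry)."""
    if not 0 < long_fraction < 1:
        raise InvalidInputError("long_fraction must be in (0, 1)")
    basal_area_cm2 = np.pi * base.r_epi_ed**2 / 100.0
    avpd_amp = long_fraction * sv_total_ml / basal_area_cm2 * 10.0  # mm

    def sv_error(a_r: float) -> float:
        p = replace(base, avpd_amplitude=avpd_amp, epi_inward_amplitude=a_r)
        try:
            v = cavity_volume(p, np.array([0.0, p.systole_fraction]))
        except InvalidInputError:
            return 1e9  # cavity collapse: SV far beyond any target
        return float(v[0] - v[1]) - sv_total_ml

    if sv_error(0.0) >= 0:
        raise InvalidInputError(
            "longitudinal motion alone already exceeds the target SV"
        )
    a_r = float(
        brentq(sv_error, 0.0, 0.95 * base.wall_thickness_ed, xtol=1e-10)
    )
    if abs(sv_error(a_r)) > 1e-6 * sv_total_ml:
        raise InvalidInputError("target SV unreachable with this geometry")
    return replace(base, avpd_amplitude=avpd_amp, epi_inward_amplitude=a_r)
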