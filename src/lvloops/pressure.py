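"""Left-ventricular pressure on the cycle grid.

Two routes produce the P(t) curve that enters the force-length loops:

1. *Invasive*: a multi-beat catheter recording is split into beats,
   each beat is resampled onto its own normalized time, the beats are
   averaged pointwise, and the average beat is circularly shifted so
   its end-diastolic landmark lines up with the geometry's ED frame.

2. *Noninvasive*: a time-varying elastance model

       P(t) = E(t) * (V(t) - V0),   E(t) = E_min + alpha * E_N(t_N)

   where E_N is a normalized double-Hill elastance shape (common to
   mammalian ventricles), scaled subject-specifically so that pressure
   at the ED frame equals the assumed end-diastolic pressure (default
   5 mmHg) and peak pressure equals a calibration target (default the
   brachial systolic cuff pressure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from lvloops.errors import (
    BeatDetectionError,
    InvalidInputError,
    ModelDomainError,
    SynchronizationError,
)
from lvloops.geometry import GeometrySeries, resample_cycle


@dataclass
class PressureRecording:
    """A sampled LV pressure trace: times in s, pressure in mmHg."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidInputError("times and values must be equal-length 1-D")
        if self.times.size < 4:
            raise InvalidInputError("recording too short")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class PressureCurve:
    """LV pressure on the n-point cycle grid, mmHg."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 3:
            raise InvalidInputError("pressure curve needs >= 3 grid points")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def peak(self) -> float:
        return float(self.values.max())


# ---------------------------------------------------------------------------
# invasive route


def detect_beats(
    recording: PressureRecording,
    *,
    upstroke_fraction: float = 0.5,
    refractory_fraction: float = 0.5,
    start_fraction: float = 0.05,
    smooth_window_s: float = 0.02,
) -> list[tuple[int, int]]:
    """Split a recording into beat windows ``[(start, stop), ...]``.

    Systolic upstrokes are located where the (lightly smoothed) dP/dt
    exceeds ``upstroke_fraction`` of its global maximum, separated by a
    refractory period of ``refractory_fraction`` times the median
    inter-upstroke interval. Each beat starts at the end-diastolic foot
    of its upstroke: the last preceding sample where pressure sits
    within ``start_fraction`` of the pulse amplitude above the local
    diastolic minimum. Windows with implausible durations (outside
    0.75-1.25 times the median) are dropped as truncated beats.
    """
    p, t = recording.values, recording.times
    dt = float(np.median(np.diff(t)))
    width = max(3, int(round(smooth_window_s / dt)) | 1)
    if width < p.size:
        kernel = np.ones(width) / width
        p_s = np.convolve(np.pad(p, width // 2, mode="edge"), kernel, "valid")
        p_s = p_s[: p.size]
    else:
        p_s = p
    dpdt = np.gradient(p_s, t)
    peak_rate = dpdt.max()
    if peak_rate <= 0:
        raise BeatDetectionError("pressure never rises; no beats found")
    above = dpdt >= upstroke_fraction * peak_rate
    candidates = np.flatnonzero(above & ~np.roll(above, 1))
    candidates = candidates[candidates > 0]
    if candidates.size < 2:
        raise BeatDetectionError(
            f"found {candidates.size} upstroke(s); need >= 2 for beat averaging"
        )
    med = np.median(np.diff(t[candidates]))
    upstrokes = [int(candidates[0])]
    for c in candidates[1:]:
        if t[c] - t[upstrokes[-1]] >= refractory_fraction * med:
            upstrokes.append(int(c))
    if len(upstrokes) < 2:
        raise BeatDetectionError("refractory filtering left fewer than 2 upstrokes")

    amplitude = float(p_s.max() - p_s.min())
    starts = []
    for idx, u in enumerate(upstrokes):
        lo = upstrokes[idx - 1] if idx else 0
        local_min = float(p_s[lo:u + 1].min())
        thresh = local_min + start_fraction * amplitude
        below = np.flatnonzero(p_s[lo:u + 1] <= thresh)
        starts.append(lo + int(below[-1]) if below.size else u)

    # matched-filter refinement: threshold crossings jitter by several
    # samples under noise, so re-align each start against a template of
    # the whole beat (best timing SNR uses every sample, not the foot)
    if len(starts) > 1:
        med_len = int(round(float(np.median(np.diff(starts)))))
        k_len = max(3, int(0.9 * med_len))
        half = max(1, int(0.1 * med_len))
        for _ in range(2):
            segs = [p[s : s + k_len] for s in starts if s + k_len <= p.size]
            if not segs:
                break
            template = np.mean(segs, axis=0)
            refined = []
            for s in starts:
                best_s, best_ssd = s, np.inf
                for d in range(-half, half + 1):
                    a = s + d
                    if a < 0 or a + k_len > p.size:
                        continue
                    ssd = float(np.sum((p[a : a + k_len] - template) ** 2))
                    if ssd < best_ssd:
                        best_s, best_ssd = a, ssd
                refined.append(best_s)
            starts = refined
        starts = sorted(set(starts))

    bounds = starts + [p.size - 1]
    windows = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    durations = np.array([t[b] - t[a] for a, b in windows])
    med_dur = float(np.median(durations))
    kept = [
        w for w, d in zip(windows, durations)
        if 0.75 * med_dur <= d <= 1.25 * med_dur
    ]
    if not kept:
        raise BeatDetectionError("no plausibly complete beats found")
    return kept


def average_beat(
    recording: PressureRecording,
    beats: list[tuple[int, int]],
    n: int = 100,
    *,
    align: bool = True,
) -> PressureCurve:
    """Resample each beat to ``n`` points of normalized beat time and
    average pointwise.

    With ``align`` (default), residual beat-to-beat timing jitter of
    the window boundaries is removed before averaging by circularly
    shifting each resampled beat to its best cross-correlation with
    the running mean (two refinement passes); this keeps the steep
    systolic upstroke from being smeared by segmentation noise.
    """
    if not beats:
        raise InvalidInputError("empty beat list")
    resampled = []
    for start, stop in beats:
        tb = recording.times[start : stop + 1]
        pb = recording.values[start : stop + 1]
        if tb.size < 3:
            raise InvalidInputError(f"beat window ({start}, {stop}) too short")
        tn = (tb - tb[0]) / (tb[-1] - tb[0])
        resampled.append(np.interp(np.arange(n) / n, tn, pb))
    stack = np.asarray(resampled)
    if align and stack.shape[0] > 1:
        for _ in range(2):
            ref = stack.mean(axis=0)
            f_ref = np.conj(np.fft.rfft(ref))
            for i in range(stack.shape[0]):
                corr = np.fft.irfft(np.fft.rfft(stack[i]) * f_ref, n)
                stack[i] = np.roll(stack[i], -int(np.argmax(corr)))
    return PressureCurve(stack.mean(axis=0))


def _ed_landmark(values: np.ndarray) -> int:
    """Grid index of the diastolic minimum preceding the systolic
    upstroke, on a single-cycle periodic curve."""
    dp = np.roll(values, -1) - values
    if dp.max() <= 0:
        raise SynchronizationError(
            "pressure curve has no upstroke; end-diastolic landmark undetectable"
        )
    up = int(np.argmax(dp))  # steepest rise
    n = values.size
    j = up
    for _ in range(n - 1):
        prev = (j - 1) % n
        if values[prev] <= values[j]:
            j = prev
        else:
            break
    return j


def synchronize_to_volume(
    pressure: PressureCurve, geometry: GeometrySeries
) -> PressureCurve:
    """Circularly shift pressure so its end-diastolic landmark (the
    diastolic minimum before the upstroke) sits at the geometry's ED
    grid point."""
    if pressure.n != geometry.n:
        raise InvalidInputError("pressure and geometry grids differ in length")
    landmark = _ed_landmark(pressure.values)
    shift = geometry.frame_of_ed - landmark
    return PressureCurve(np.roll(pressure.values, shift))


def invasive_pressure(
    recording: PressureRecording, geometry: GeometrySeries, *, n: int | None = None
) -> PressureCurve:
    """Beat-average an invasive recording and synchronize it to the
    geometry grid."""
    n = geometry.n if n is None else n
    beats = detect_beats(recording)
    return synchronize_to_volume(average_beat(recording, beats, n), geometry)


# ---------------------------------------------------------------------------
# noninvasive (elastance) route


@dataclass
class ElastanceInputs:
    """Inputs of the noninvasive elastance pressure model.

    ``sbp``/``dbp`` are brachial cuff pressures in mmHg; ``edp`` the
    assumed end-diastolic LV pressure (5 mmHg when unknown); ``v0`` the
    equilibrium volume in mL (approximated as zero); ``peak_target``
    the calibrated peak LV pressure (defaults to ``sbp``). The
    normalized elastance shape is a double-Hill curve

        E_N(x) = [(x/tau1)^n1 / (1+(x/tau1)^n1)] * [1 / (1+(x/tau2)^n2)]

    rescaled to [0, 1] over normalized cycle time x in [0, 1); the
    default shape parameters are the published human-average values.
    """

    sbp: float
    dbp: float
    edp: float = 5.0
    v0: float = 0.0
    peak_target: float | None = None
    anchor: str = "es"
    tau1: float = 0.269
    n1: float = 1.32
    tau2: float = 0.452
    n2: float = 21.9

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp > 0:
            raise InvalidInputError("require sbp > dbp > 0")
        if self.edp < 0 or self.v0 < 0:
            raise InvalidInputError("edp and v0 must be >= 0")
        if self.anchor not in ("es", "peak"):
            raise InvalidInputError(f"unknown anchor mode {self.anchor!r}")

    @property
    def target(self) -> float:
        return self.sbp if self.peak_target is None else self.peak_target

    def shape(self, x: np.ndarray) -> np.ndarray:
        """Normalized elastance E_N on normalized time x in [0, 1)."""
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            a = (x / self.tau1) ** self.n1
            e = (a / (1.0 + a)) / (1.0 + (x / self.tau2) ** self.n2)
        e[~np.isfinite(e)] = 0.0
        m = e.max()
        if m <= 0:
            raise InvalidInputError("degenerate elastance shape parameters")
        return e / m


def elastance_pressure(
    volume: np.ndarray | GeometrySeries,
    inputs: ElastanceInputs,
    *,
    frame_of_ed: int | None = None,
) -> PressureCurve:
    """Noninvasive LV pressure from volume and cuff pressure.

    P(t) = E(t)(V(t) - V0) with E(t) = E_min + alpha E_N(t_N), where
    normalized time t_N runs from the ED frame. The first calibration
    anchor is always P(ED) = edp exactly (it fixes E_min, since
    E_N(0) = 0). The second depends on ``inputs.anchor``:

    - ``"es"`` (default): pressure at the end-systolic (minimum-volume)
      frame equals ``inputs.target`` — an end-systolic elastance anchor,
      so peak pressure may exceed the target during ejection. This is
      the mode whose stroke work grows steeply as v0 approaches ESV.
    - ``"peak"``: the cycle maximum of P equals ``inputs.target``
      (within solver tolerance), found numerically.
    """
    if isinstance(volume, GeometrySeries):
        if frame_of_ed is None:
            frame_of_ed = volume.frame_of_ed
        volume = volume.volume
    v = np.asarray(volume, dtype=float)
    if frame_of_ed is None:
        frame_of_ed = int(np.argmax(v))
    if v.ndim != 1 or v.size < 3:
        raise InvalidInputError("volume must be a 1-D cycle signal")
    dv = v - inputs.v0
    if np.any(dv <= 0):
        raise ModelDomainError("volume must exceed v0 at every grid point")

    n = v.size
    # normalized cycle time starting at ED
    x = ((np.arange(n) - frame_of_ed) % n) / n
    e_shape = inputs.shape(x)

    e_min = inputs.edp / dv[frame_of_ed]
    base = e_min * dv  # pressure with alpha = 0

    if inputs.anchor == "es":
        frame_of_es = int(np.argmin(v))
        e_n_es = float(e_shape[frame_of_es])
        if e_n_es <= 0:
            raise ModelDomainError(
                "normalized elastance vanishes at the end-systolic frame"
            )
        alpha = (inputs.target / dv[frame_of_es] - e_min) / e_n_es
        if alpha < 0:
            raise ModelDomainError(
                "end-systolic target below the passive pressure; check edp/sbp"
            )
    else:

        def peak_minus_target(a: float) -> float:
            return float(np.max(base + a * e_shape * dv) - inputs.target)

        if inputs.target <= base.max():
            raise ModelDomainError(
                "peak target below the passive (alpha=0) pressure; check edp/sbp"
            )
        hi = (inputs.target - base.min()) / (e_shape * dv).max() + 1.0
        alpha = brentq(peak_minus_target, 0.0, hi, xtol=1e-12)
    return PressureCurve(base + alpha * e_shape * dv)
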