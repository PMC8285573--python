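"""Exchange formats, run configuration and the end-to-end pipeline.

Formats (all plain text, human-inspectable):

- contour exchange JSON (versioned): short-axis contour stacks plus
  long-axis insertion-point tracks;
- pressure CSV with columns ``time_s, pressure_mmHg``;
- run configuration YAML/JSON;
- results JSON with unit-suffixed keys, plus tidy CSV exports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from lvloops.errors import ConfigError, ParseError
from lvloops.geometry import (
    CineContourSet,
    GeometrySeries,
    InsertionPointTracks,
    PlanarContour,
    ViewTrack,
    compute_geometry_series,
    mass_variation,
)
from lvloops.loops import WorkDecomposition, decompose_stroke_work
from lvloops.pressure import (
    ElastanceInputs,
    PressureCurve,
    PressureRecording,
    elastance_pressure,
    invasive_pressure,
)
from lvloops.stats import V0SweepResult, v0_sweep
from lvloops.units import MYOCARDIAL_DENSITY

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# contour exchange JSON


def write_contour_exchange(
    path: str | Path,
    contours: CineContourSet,
    tracks: InsertionPointTracks | None = None,
) -> None:
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "meta": {
            "n_frames": contours.n_frames,
            "n_slices": contours.n_slices,
            "slice_thickness_mm": contours.slice_thickness,
            "slice_gap_mm": contours.slice_gap,
            "frame_times_ms": (
                None
                if contours.frame_times_ms is None
                else [float(v) for v in contours.frame_times_ms]
            ),
        },
        "contours": [
            {
                "frame": f,
                "slice": s,
                "kind": kind,
                "points": [[float(x), float(y)] for x, y in c.points],
            }
            for (f, s), kinds in sorted(contours.contours.items())
            for kind, c in sorted(kinds.items())
        ],
    }
    if tracks is not None:
        doc["tracks"] = {
            "views": [
                {
                    "name": v.name,
                    "apex_direction": [float(a) for a in v.apex_direction],
                    "points": [
                        [f, k, float(v.points[f, k, 0]), float(v.points[f, k, 1])]
                        for f in range(v.points.shape[0])
                        for k in (0, 1)
                    ],
                }
                for v in tracks.views
            ]
        }
    Path(path).write_text(json.dumps(doc))


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ParseError(f"{where}: missing required field {key!r}")
    return mapping[key]


def read_contour_exchange(
    path: str | Path,
) -> tuple[CineContourSet, InsertionPointTracks | None]:
    """Read and validate a contour-exchange file.

    Raises :class:`ParseError` naming the offending field, frame or
    slice on any schema violation.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    meta = _require(doc, "meta", str(path))
    n_frames = int(_require(meta, "n_frames", "meta"))
    n_slices = int(_require(meta, "n_slices", "meta"))
    thickness = float(_require(meta, "slice_thickness_mm", "meta"))
    gap = float(meta.get("slice_gap_mm", 0.0))
    times = meta.get("frame_times_ms")
    cset = CineContourSet(
        n_frames=n_frames,
        n_slices=n_slices,
        slice_thickness=thickness,
        slice_gap=gap,
        frame_times_ms=None if times is None else np.asarray(times, dtype=float),
    )
    for i, entry in enumerate(_require(doc, "contours", str(path))):
        where = f"contours[{i}]"
        f = int(_require(entry, "frame", where))
        s = int(_require(entry, "slice", where))
        kind = _require(entry, "kind", where)
        pts = np.asarray(_require(entry, "points", where), dtype=float)
        if not 0 <= f < n_frames or not 0 <= s < n_slices:
            raise ParseError(f"{where}: frame {f}/slice {s} out of range")
        try:
            cset.add(f, s, PlanarContour(points=pts, kind=kind))
        except Exception as exc:
            raise ParseError(f"{where} (frame {f}, slice {s}): {exc}") from exc
    bad_frames = [
        f
        for f in range(n_frames)
        if not any(cset.has(f, s, "endo") for s in range(n_slices))
    ]
    if bad_frames:
        raise ParseError(
            f"frames without any endocardial contour: {bad_frames}"
        )

    tracks = None
    if "tracks" in doc:
        views = []
        for v in _require(doc["tracks"], "views", "tracks"):
            where = f"tracks.views[{v.get('name', '?')}]"
            pts = np.full((n_frames, 2, 2), np.nan)
            for f, k, x, y in _require(v, "points", where):
                pts[int(f), int(k)] = (x, y)
            if np.isnan(pts).any():
                raise ParseError(f"{where}: track does not cover all frames")
            views.append(
                ViewTrack(
                    name=_require(v, "name", where),
                    apex_direction=np.asarray(
                        _require(v, "apex_direction", where), dtype=float
                    ),
                    points=pts,
                )
            )
        tracks = InsertionPointTracks(views=views)
    return cset, tracks


# ---------------------------------------------------------------------------
# pressure CSV


def write_pressure_csv(path: str | Path, recording: PressureRecording) -> None:
    pd.DataFrame(
        {"time_s": recording.times, "pressure_mmHg": recording.values}
    ).to_csv(path, index=False)


def read_pressure_csv(path: str | Path) -> PressureRecording:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable CSV ({exc})") from exc
    for col in ("time_s", "pressure_mmHg"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return PressureRecording(
        times=df["time_s"].to_numpy(float),
        values=df["pressure_mmHg"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# run configuration


_ELASTANCE_KEYS = {"sbp", "dbp", "edp", "v0", "peak_target",
                   "tau1", "n1", "tau2", "n2"}


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    contours: str
    pressure_mode: str  # "invasive" | "elastance"
    pressure_csv: str | None = None
    elastance: dict[str, float] = field(default_factory=dict)
    n: int = 100
    smooth: bool = True
    basal_slice_policy: str = "zero_force"
    density: float = MYOCARDIAL_DENSITY
    sweep: bool = False
    seed: int = 0

    _KEYS = {
        "contours", "pressure_mode", "pressure_csv", "elastance", "n",
        "smooth", "basal_slice_policy", "density", "sweep", "seed",
    }

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - cls._KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "contours" not in raw:
            raise ConfigError("missing required config key 'contours'")
        if "pressure_mode" not in raw:
            raise ConfigError("missing required config key 'pressure_mode'")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.pressure_mode not in ("invasive", "elastance"):
            raise ConfigError(f"unknown pressure_mode {self.pressure_mode!r}")
        if self.pressure_mode == "invasive" and not self.pressure_csv:
            raise ConfigError("invasive mode requires 'pressure_csv'")
        if self.pressure_mode == "elastance":
            unknown = set(self.elastance) - _ELASTANCE_KEYS
            if unknown:
                raise ConfigError(f"unknown elastance keys: {sorted(unknown)}")
            if "sbp" not in self.elastance or "dbp" not in self.elastance:
                raise ConfigError(
                    "elastance mode requires cuff pressures 'sbp' and 'dbp'"
                )
        if self.n < 3:
            raise ConfigError("grid length n must be >= 3")
        if self.basal_slice_policy not in ("zero_force", "exclude"):
            raise ConfigError(
                f"unknown basal_slice_policy {self.basal_slice_policy!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class ResultsBundle:
    """Everything one analysis run produces."""

    config: RunConfig
    geometry: GeometrySeries
    pressure: PressureCurve
    decomposition: WorkDecomposition
    sweep: V0SweepResult | None
    log: list[str]

    def to_dict(self) -> dict[str, Any]:
        mv = mass_variation(self.geometry.mass)
        out: dict[str, Any] = {
            "schema_version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "config_hash": self.config.hash,
            "units": {
                "work": "J", "volume": "mL", "pressure": "mmHg",
                "displacement": "mm", "area": "cm2", "wev": "mJ/mL",
            },
            "decomposition": self.decomposition.to_dict(),
            "geometry": {
                "edv_mL": self.geometry.edv,
                "esv_mL": self.geometry.esv,
                "sv_mL": self.geometry.sv,
                "frame_of_ed": self.geometry.frame_of_ed,
                "frame_of_es": self.geometry.frame_of_es,
                "included_slices": self.geometry.included_slices,
                "excluded_slices": self.geometry.excluded_slices,
                "mass_variation_mean_pct": mv.mean_pct,
                "mass_variation_sd_pct": mv.sd_pct,
            },
            "pressure": {
                "peak_mmHg": self.pressure.peak,
                "ed_mmHg": float(
                    self.pressure.values[self.geometry.frame_of_ed]
                ),
            },
            "log": self.log,
        }
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "results.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
        )
        self.geometry.to_frame().to_csv(outdir / "geometry.csv", index=False)
        pd.DataFrame(
            {
                "grid_point": np.arange(self.geometry.n),
                "pressure_mmHg": self.pressure.values,
                "volume_mL": self.geometry.volume,
                "avpd_mm": self.geometry.avpd,
            }
        ).to_csv(outdir / "loops.csv", index=False)
        if self.sweep is not None:
            self.sweep.to_frame().to_csv(outdir / "v0_sweep.csv", index=False)


def run_analysis(config: RunConfig, *, base_dir: str | Path | None = None) -> ResultsBundle:
    """Execute the pipeline: geometry -> pressure -> decomposition
    (-> V0 sweep). Deterministic for fixed inputs and config."""
    config.validate()
    base = Path(base_dir) if base_dir is not None else Path(".")
    log: list[str] = []

    contour_path = base / config.contours
    cset, tracks = read_contour_exchange(contour_path)
    geometry = compute_geometry_series(
        cset,
        tracks,
        n=config.n,
        smooth=config.smooth,
        density=config.density,
        basal_slice_policy=config.basal_slice_policy,
    )
    log.append(
        f"geometry: EDV {geometry.edv:.1f} mL, ESV {geometry.esv:.1f} mL, "
        f"{len(geometry.included_slices)} slices included, "
        f"{len(geometry.excluded_slices)} excluded"
    )

    if config.pressure_mode == "invasive":
        recording = read_pressure_csv(base / config.pressure_csv)
        pressure = invasive_pressure(recording, geometry)
        log.append(
            f"pressure: invasive recording, {recording.duration:.1f} s, "
            f"peak {pressure.peak:.1f} mmHg"
        )
        inputs = None
    else:
        inputs = ElastanceInputs(**config.elastance)
        pressure = elastance_pressure(geometry, inputs)
        log.append(
            f"pressure: elastance model, EDP {inputs.edp:g} mmHg, "
            f"V0 {inputs.v0:g} mL, peak target {inputs.target:g} mmHg"
        )

    decomposition = decompose_stroke_work(geometry, pressure)
    log.append(
        f"decomposition: SW_PV {decomposition.sw_pv:.3f} J, "
        f"FL total {decomposition.sw_fl_total:.3f} J "
        f"({decomposition.fl_vs_pv_percent:+.1f}%)"
    )

    sweep = None
    if config.sweep:
        if inputs is None:
            raise ConfigError("V0 sweep requires elastance pressure mode")
        sweep = v0_sweep(geometry, inputs)
        log.append(f"v0 sweep: {sweep.v0.size} steps, {len(sweep.errors)} failed")

    return ResultsBundle(
        config=config,
        geometry=geometry,
        pressure=pressure,
        decomposition=decomposition,
        sweep=sweep,
        log=log,
    )


# ---------------------------------------------------------------------------
# phantom subject export


def write_phantom_subject(outdir: str | Path, data, *, n_beats: int = 10) -> Path:
    """Write a complete synthetic subject directory: contour exchange
    JSON, a multi-beat pressure CSV, ground truth and a ready-to-run
    config. Returns the config path."""
    from lvloops.phantom import PhantomData, phantom_pressure_recording

    assert isinstance(data, PhantomData)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contour_exchange(outdir / "contours.json", data.contours, data.tracks)
    write_pressure_csv(
        outdir / "pressure.csv",
        phantom_pressure_recording(data.params, n_beats=n_beats),
    )
    truth = data.truth
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "sv_mL": truth.sv,
                "sv_long_mL": truth.sv_long,
                "sv_rad_mL": truth.sv_rad,
                "sv_long_exact_mL": truth.sv_long_exact,
                "sw_pv_J": truth.sw_pv,
                "wall_volume_mL": truth.wall_volume,
            },
            indent=2,
        )
    )
    params = asdict(data.params)
    (outdir / "params.json").write_text(json.dumps(params, indent=2))
    config = {
        "contours": "contours.json",
        "pressure_mode": "invasive",
        "pressure_csv": "pressure.csv",
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config))
    return cfg_path
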