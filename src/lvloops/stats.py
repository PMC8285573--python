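"""V0 sensitivity sweep and method-agreement statistics.

The equilibrium volume V0 of the elastance model is approximated as
zero when unknown; the sweep recomputes the noninvasive pressure and
the full stroke-work decomposition for every integer V0 from 0 to 90%
of end-systolic volume, to show that the *percent* longitudinal/radial
split is insensitive to V0 even though absolute stroke work is not.

Agreement between force-length-derived and PV-derived stroke work is
quantified with the intraclass correlation coefficient (two-way
random, absolute agreement, single measures — ICC(2,1)), Pearson's r,
and Bland-Altman statistics on percent differences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from lvloops.errors import UndefinedStatisticError, InvalidInputError
from lvloops.geometry import GeometrySeries
from lvloops.loops import WorkDecomposition, decompose_stroke_work
from lvloops.pressure import ElastanceInputs, elastance_pressure

#: ICC agreement bands: label applies up to (and including) the bound.
ICC_BANDS = [
    (0.30, "poor"),
    (0.50, "weak"),
    (0.70, "moderate"),
    (0.90, "strong"),
    (1.00, "excellent"),
]


@dataclass
class V0SweepResult:
    """One decomposition per integer V0 step (mL)."""

    v0: np.ndarray  # mL, strictly increasing from 0
    decompositions: list[WorkDecomposition | None]  # None where the model failed
    errors: dict[int, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v0, d in zip(self.v0, self.decompositions):
            if d is None:
                rows.append({"v0_mL": float(v0)})
                continue
            rows.append(
                {
                    "v0_mL": float(v0),
                    "sw_pv_J": d.sw_pv,
                    "sw_long_J": d.sw_long,
                    "sw_rad_J": d.sw_rad,
                    "frac_long_pct": d.frac_long,
                    "frac_rad_pct": d.frac_rad,
                }
            )
        return pd.DataFrame(rows)


def v0_sweep(
    geometry: GeometrySeries,
    inputs: ElastanceInputs,
    esv: float | None = None,
) -> V0SweepResult:
    """Recompute the decomposition for v0 = 0, 1, ... floor(0.9 * ESV) mL.

    A model-domain failure at one step is recorded and the sweep
    continues; the v0 = 0 step reproduces the baseline run exactly.
    """
    esv = geometry.esv if esv is None else esv
    if esv <= 0:
        raise InvalidInputError("esv must be > 0")
    steps = np.arange(0, int(np.floor(0.9 * esv)) + 1, dtype=float)
    decomps: list[WorkDecomposition | None] = []
    errors: dict[int, str] = {}
    for v0 in steps:
        try:
            mod = dataclasses.replace(inputs, v0=float(v0))
            pressure = elastance_pressure(geometry, mod)
            decomps.append(decompose_stroke_work(geometry, pressure))
        except Exception as exc:  # recorded, sweep continues
            decomps.append(None)
            errors[int(v0)] = f"{type(exc).__name__}: {exc}"
    return V0SweepResult(v0=steps, decompositions=decomps, errors=errors)


# ---------------------------------------------------------------------------
# agreement statistics


@dataclass
class AgreementReport:
    """Method-agreement summary between a reference and a test method."""

    icc: float
    icc_label: str
    pearson_r: float
    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float

    def to_dict(self) -> dict[str, float | str]:
        return {
            "icc": self.icc,
            "icc_label": self.icc_label,
            "pearson_r": self.pearson_r,
            "bias_pct": self.bias_pct,
            "sd_pct": self.sd_pct,
            "loa_low_pct": self.loa_low_pct,
            "loa_high_pct": self.loa_high_pct,
        }


def icc_label(icc: float) -> str:
    """Agreement label for an ICC value (poor ... excellent)."""
    for bound, label in ICC_BANDS:
        if icc <= bound:
            return label
    return "excellent"


def icc_agreement(x, y) -> tuple[float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, for two raters (methods) scoring the same subjects.

    Computed from the two-way ANOVA mean squares:

        ICC = (MS_R - MS_E) /
              (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with n subjects, k = 2 raters, MS_R rows (subjects), MS_C columns
    (raters), MS_E residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("paired samples must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("need at least 3 pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        raise UndefinedStatisticError("zero variance: ICC undefined")
    icc = float((ms_rows - ms_err) / denom)
    return icc, icc_label(icc)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise UndefinedStatisticError("need at least 3 equal-length pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def bland_altman_percent(
    reference, test, *, basis: str = "reference"
) -> tuple[float, float, tuple[float, float]]:
    """Bland-Altman statistics on percent differences.

    d_i = 100 * (test_i - reference_i) / b_i with b the reference value
    (``basis="reference"``, default) or the pair mean
    (``basis="mean"``); returns (bias, SD, (bias - 1.96 SD,
    bias + 1.96 SD)).
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1 or ref.size < 2:
        raise InvalidInputError("need at least 2 equal-length pairs")
    if np.any(ref <= 0):
        raise InvalidInputError("reference values must be > 0")
    if basis == "reference":
        b = ref
    elif basis == "mean":
        b = 0.5 * (ref + tst)
    else:
        raise InvalidInputError(f"unknown basis {basis!r}")
    d = 100.0 * (tst - ref) / b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, (bias - 1.96 * sd, bias + 1.96 * sd)


def agreement_report(reference, test) -> AgreementReport:
    """Full agreement summary (ICC, Pearson, Bland-Altman) of a test
    method against a reference over paired subjects."""
    icc, label = icc_agreement(reference, test)
    r = pearson_r(reference, test)
    bias, sd, (lo, hi) = bland_altman_percent(reference, test)
    return AgreementReport(
        icc=icc, icc_label=label, pearson_r=r,
        bias_pct=bias, sd_pct=sd, loa_low_pct=lo, loa_high_pct=hi,
    )
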