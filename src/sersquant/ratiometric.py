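"""Peak-ratio extraction, linear calibration, inverse quantification, maps.

The non-deep-learning quantification path: extract baseline-subtracted peak
intensities at 542, 628, and 928 cm^-1, form the ratios r1 = I542/I928
(GSH channel) and r2 = I628/I928 (H2O2 channel), calibrate each ratio
against known concentrations by ordinary least squares, and invert the
fitted line per scan point to build spatial concentration maps with an
H2O2/GSH layer.  Ratios cancel global intensity variation, which is the
probe's ratiometric design rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import LabeledSpectrum, Spectrum

GSH_PEAK = 542.0
H2O2_PEAK = 628.0
REF_PEAK = 928.0
DEFAULT_HALF_WINDOW = 6.0  # cm^-1


class ReferencePeakError(ValueError):
    """The 928 cm^-1 reference intensity is non-positive; ratios undefined."""


@dataclass(frozen=True)
class RatioMeasurement:
    r1: float  # I542/I928, GSH channel
    r2: float  # I628/I928, H2O2 channel
    grid_xy: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r1) and np.isfinite(self.r2)):
            raise ValueError("ratios must be finite")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("ratios must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear map ratio = intercept + slope * concentration."""

    metabolite: str            # "GSH" | "H2O2"
    slope: float               # ratio per mM (GSH) or per uM (H2O2)
    intercept: float
    valid_range: tuple[float, float]
    fit_r2: float

    def __post_init__(self) -> None:
        if self.metabolite not in ("GSH", "H2O2"):
            raise ValueError("metabolite must be 'GSH' or 'H2O2'")
        if self.valid_range[0] >= self.valid_range[1]:
            raise ValueError("validity range must be non-empty")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "metabolite": self.metabolite,
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "valid_range": list(self.valid_range),
                    "fit_r2": self.fit_r2,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            metabolite=d["metabolite"],
            slope=d["slope"],
            intercept=d["intercept"],
            valid_range=tuple(d["valid_range"]),
            fit_r2=d["fit_r2"],
        )


def peak_intensity(
    s: Spectrum, center: float, half_window: float = DEFAULT_HALF_WINDOW
) -> float:
    """Baseline-subtracted peak intensity in ``[center-hw, center+hw]``.

    The local baseline is the straight line through the window's endpoint
    samples; the returned value is the maximum of the baseline-subtracted
    intensities in the window (0 if the band is absent).
    """
    w, y = s.wavenumbers, s.intensities
    lo, hi = center - half_window, center + half_window
    if lo < w[0] or hi > w[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] cm^-1 outside axis range [{w[0]}, {w[-1]}]"
        )
    i0 = int(np.searchsorted(w, lo, side="left"))
    i1 = int(np.searchsorted(w, hi, side="right")) - 1
    if i1 <= i0:
        raise ValueError("window contains fewer than 2 axis points")
    baseline = y[i0] + (y[i1] - y[i0]) * (w[i0 : i1 + 1] - w[i0]) / (w[i1] - w[i0])
    return float(np.max(y[i0 : i1 + 1] - baseline))


def compute_ratios(
    s: Spectrum,
    half_window: float = DEFAULT_HALF_WINDOW,
    grid_xy: Optional[tuple[int, int]] = None,
) -> RatioMeasurement:
    """(I542/I928, I628/I928) from baseline-subtracted window peak heights."""
    i928 = peak_intensity(s, REF_PEAK, half_window)
    if i928 <= 0:
        raise ReferencePeakError("I928 <= 0: reference band missing")
    return RatioMeasurement(
        r1=peak_intensity(s, GSH_PEAK, half_window) / i928,
        r2=peak_intensity(s, H2O2_PEAK, half_window) / i928,
        grid_xy=grid_xy,
    )


def fit_calibration(ratios, concentrations, metabolite: str) -> CalibrationModel:
    """OLS line through (concentration, ratio) pairs for one channel.

    Requires >= 3 distinct concentrations.  The GSH channel must calibrate
    with a positive slope and the H2O2 channel with a negative one; a wrong
    sign signals a channel mix-up and raises.
    """
    ratios = np.asarray(ratios, dtype=float)
    concs = np.asarray(concentrations, dtype=float)
    if ratios.shape != concs.shape or ratios.ndim != 1:
        raise ValueError("ratios and concentrations must be equal-length vectors")
    if np.unique(concs).size < 3:
        raise ValueError("need >= 3 distinct concentrations to calibrate")
    fit = stats.linregress(concs, ratios)
    if metabolite == "GSH" and fit.slope <= 0:
        raise ValueError("GSH calibration slope must be positive (channel mix-up?)")
    if metabolite == "H2O2" and fit.slope >= 0:
        raise ValueError("H2O2 calibration slope must be negative (channel mix-up?)")
    return CalibrationModel(
        metabolite=metabolite,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        valid_range=(float(concs.min()), float(concs.max())),
        fit_r2=float(fit.rvalue**2),
    )


def calibrate_from_records(
    records: Sequence[LabeledSpectrum],
    metabolite: str,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> CalibrationModel:
    """Fit one channel from labeled single-analyte sweep spectra."""
    ratios, concs = [], []
    for rec in records:
        m = compute_ratios(rec.spectrum, half_window)
        if metabolite == "GSH":
            if rec.c_gsh is None:
                raise ValueError("record lacks c_gsh label")
            ratios.append(m.r1)
            concs.append(rec.c_gsh)
        else:
            if rec.c_h2o2 is None:
                raise ValueError("record lacks c_h2o2 label")
            ratios.append(m.r2)
            concs.append(rec.c_h2o2)
    return fit_calibration(ratios, concs, metabolite)


def quantify(
    m: RatioMeasurement, cal_gsh: CalibrationModel, cal_h2o2: CalibrationModel
) -> tuple[float, float, list[str]]:
    """Invert both calibration lines: c = (ratio - intercept) / slope.

    Returns (c_gsh mM, c_h2o2 uM, flags); flags mark extrapolation beyond a
    calibration's validity range, boundary hits, and negative inversions
    (clipped to 0).
    """
    if cal_gsh.metabolite != "GSH" or cal_h2o2.metabolite != "H2O2":
        raise ValueError("calibrations passed in the wrong order")
    flags: list[str] = []
    out = []
    for ratio, cal, name in ((m.r1, cal_gsh, "gsh"), (m.r2, cal_h2o2, "h2o2")):
        if cal.slope == 0:
            raise ZeroDivisionError("calibration slope is zero; cannot invert")
        c = (ratio - cal.intercept) / cal.slope
        if c < 0:
            flags.append(f"{name}:clipped_negative")
            c = 0.0
        if c == 0.0:
            flags.append(f"{name}:boundary")
        if not (cal.valid_range[0] <= c <= cal.valid_range[1]):
            flags.append(f"{name}:extrapolated")
        out.append(c)
    return out[0], out[1], flags


@dataclass(frozen=True)
class ConcentrationMap:
    """Gridded per-point quantification with an H2O2/GSH ratio layer.

    ``ratio`` is c_H2O2 (uM) / c_GSH (mM) from the quantified concentrations
    (the default convention for genotype contrast); a raw-ratio mode using
    r2/r1 is available for sensitivity analysis.  ``mask`` is True where a
    point is missing or its reference band failed.
    """

    c_gsh: np.ndarray
    c_h2o2: np.ndarray
    ratio: np.ndarray
    mask: np.ndarray
    flags: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        nx, ny = self.c_gsh.shape
        for x in range(nx):
            for y in range(ny):
                rows.append(
                    {
                        "x": x,
                        "y": y,
                        "c_gsh": self.c_gsh[x, y],
                        "c_h2o2": self.c_h2o2[x, y],
                        "ratio": self.ratio[x, y],
                        "mask": bool(self.mask[x, y]),
                    }
                )
        return pd.DataFrame(rows)


def build_map(
    points: Sequence[RatioMeasurement],
    cal_gsh: CalibrationModel,
    cal_h2o2: CalibrationModel,
    mode: str = "concentration",
) -> ConcentrationMap:
    """Quantify every gridded measurement and assemble the map layers."""
    if mode not in ("concentration", "raw_ratio"):
        raise ValueError("mode must be 'concentration' or 'raw_ratio'")
    coords = [p.grid_xy for p in points]
    if any(c is None for c in coords):
        raise ValueError("all points need grid_xy coordinates")
    if len(set(coords)) != len(coords):
        raise ValueError("duplicate grid coordinates")
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    shape = (max(xs) + 1, max(ys) + 1)
    c_gsh = np.full(shape, np.nan)
    c_h2o2 = np.full(shape, np.nan)
    ratio = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)
    flags: dict = {}
    for p in points:
        g, h, fl = quantify(p, cal_gsh, cal_h2o2)
        x, y = p.grid_xy
        c_gsh[x, y], c_h2o2[x, y] = g, h
        if mode == "concentration":
            ratio[x, y] = h / g if g > 0 else np.nan
        else:
            ratio[x, y] = p.r2 / p.r1
        mask[x, y] = not np.isfinite(ratio[x, y])
        if fl:
            flags[(x, y)] = fl
    # a masked point is masked in every layer
    c_gsh[mask] = np.nan
    c_h2o2[mask] = np.nan
    ratio[mask] = np.nan
    return ConcentrationMap(c_gsh=c_gsh, c_h2o2=c_h2o2, ratio=ratio, mask=mask, flags=flags)
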