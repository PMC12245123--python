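"""Synthetic Au-R12P SERS spectra with the probe's ratiometric response.

The simulator emulates the dual-response reporter chemistry: bands at
542/806/1023 cm^-1 grow affinely with GSH (mM), bands at
628/801/1164/1426/1617 cm^-1 shrink affinely with H2O2 (uM, clipped at a
non-negative floor), and the 928 cm^-1 band is analyte-invariant and serves
as the internal reference.  Line shapes are Lorentzian.  Noise is additive
Gaussian plus a small random quadratic baseline per acquisition.

Calibration datasets reproduce the quantification study design: 6 GSH levels
{2,4,6,8,10,16} mM x 8 H2O2 levels {1,25,50,75,100,125,150,200} uM x 200
replicates = 9600 spectra.  Tissue cohorts draw per-point concentrations from
truncated normals with the reported class statistics (GSH 12.08+-0.53 mM in
IDH1-WT vs 9.20+-0.83 mM in IDH1-MUT tumor, normal brain < 1 mM; H2O2
68.54+-4.51 uM WT vs 109.3+-9.44 uM MUT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .spectra import LabeledSpectrum, Spectrum

GSH_LEVELS_MM = (2.0, 4.0, 6.0, 8.0, 10.0, 16.0)
H2O2_LEVELS_UM = (1.0, 25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 200.0)
REPLICATES = 200

GSH_VALID_MM = (0.5, 20.0)     # validated probe response range
H2O2_VALID_UM = (5.0, 200.0)

GSH_UP_CENTERS = (542.0, 806.0, 1023.0)
H2O2_DOWN_CENTERS = (628.0, 801.0, 1164.0, 1426.0, 1617.0)
REFERENCE_CENTER = 928.0


@dataclass(frozen=True)
class Peak:
    center: float          # cm^-1
    fwhm: float            # cm^-1
    amplitude: float       # peak height at zero analyte, arbitrary units
    response: str          # "gsh_up" | "h2o2_down" | "inert"

    def __post_init__(self) -> None:
        if self.response not in ("gsh_up", "h2o2_down", "inert"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.amplitude < 0 or self.fwhm <= 0:
            raise ValueError("peak amplitude must be >= 0 and fwhm > 0")


def _default_axis() -> np.ndarray:
    return np.arange(400.0, 1800.0 + 1e-9, 2.0)


def _default_peaks() -> tuple[Peak, ...]:
    return (
        Peak(542.0, 8.0, 0.20, "gsh_up"),
        Peak(806.0, 8.0, 0.15, "gsh_up"),
        Peak(1023.0, 8.0, 0.12, "gsh_up"),
        Peak(628.0, 8.0, 1.20, "h2o2_down"),
        Peak(801.0, 8.0, 0.50, "h2o2_down"),
        Peak(1164.0, 8.0, 0.45, "h2o2_down"),
        Peak(1426.0, 8.0, 0.60, "h2o2_down"),
        Peak(1617.0, 8.0, 0.90, "h2o2_down"),
        Peak(928.0, 8.0, 1.00, "inert"),
    )


@dataclass(frozen=True)
class ProbeResponseModel:
    """Peak table plus the affine concentration responses of the reporter.

    A gsh_up peak has height ``amplitude * (1 + gsh_slope * c_gsh)``; an
    h2o2_down peak has ``amplitude * max(floor, 1 - h2o2_slope * c_h2o2)``;
    inert peaks ignore both analytes.  The defaults are simulator parameters
    chosen to span the probe's physiological ratio ranges monotonically, not
    measurements of the real reporter.
    """

    axis: np.ndarray = field(default_factory=_default_axis)
    peaks: tuple[Peak, ...] = field(default_factory=_default_peaks)
    gsh_slope: float = 0.30    # relative amplitude gain per mM GSH
    h2o2_slope: float = 0.004  # relative amplitude loss per uM H2O2
    floor: float = 0.05        # minimum surviving amplitude fraction

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
            raise ValueError("axis must be a strictly increasing 1D grid")
        centers = {p.center: p.response for p in self.peaks}
        ref = centers.get(REFERENCE_CENTER)
        if ref != "inert":
            raise ValueError("the 928 cm^-1 reference peak must be present and inert")
        for c in GSH_UP_CENTERS:
            if centers.get(c) != "gsh_up":
                raise ValueError(f"missing gsh_up peak at {c} cm^-1")
        for c in H2O2_DOWN_CENTERS:
            if centers.get(c) != "h2o2_down":
                raise ValueError(f"missing h2o2_down peak at {c} cm^-1")
        if self.gsh_slope < 0 or self.h2o2_slope < 0 or not (0 <= self.floor < 1):
            raise ValueError("invalid response parameters")
        object.__setattr__(self, "axis", axis)

    def with_axis(self, axis: np.ndarray) -> "ProbeResponseModel":
        return replace(self, axis=np.asarray(axis, dtype=float))

    def amplitudes(self, c_gsh: float, c_h2o2: float) -> np.ndarray:
        """Peak heights at the given concentrations (order of ``self.peaks``)."""
        if c_gsh < 0 or c_h2o2 < 0:
            raise ValueError("concentrations must be non-negative")
        amps = np.empty(len(self.peaks))
        for i, p in enumerate(self.peaks):
            if p.response == "gsh_up":
                amps[i] = p.amplitude * (1.0 + self.gsh_slope * c_gsh)
            elif p.response == "h2o2_down":
                amps[i] = p.amplitude * max(self.floor, 1.0 - self.h2o2_slope * c_h2o2)
            else:
                amps[i] = p.amplitude
        return amps

    def _amplitude_at(self, center: float, c_gsh: float, c_h2o2: float) -> float:
        for p, a in zip(self.peaks, self.amplitudes(c_gsh, c_h2o2)):
            if p.center == center:
                return float(a)
        raise KeyError(center)

    def expected_ratios(self, c_gsh: float, c_h2o2: float) -> tuple[float, float]:
        """Closed-form (I542/I928, I628/I928) amplitude ratios (no noise)."""
        a928 = self._amplitude_at(REFERENCE_CENTER, c_gsh, c_h2o2)
        return (
            self._amplitude_at(542.0, c_gsh, c_h2o2) / a928,
            self._amplitude_at(628.0, c_gsh, c_h2o2) / a928,
        )

    def is_extrapolated(self, c_gsh: float, c_h2o2: float) -> bool:
        return not (
            GSH_VALID_MM[0] <= c_gsh <= GSH_VALID_MM[1]
            and H2O2_VALID_UM[0] <= c_h2o2 <= H2O2_VALID_UM[1]
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise plus a random low-order polynomial baseline.

    ``additive_sd`` is in the same units as peak amplitudes (the reference
    band height is 1.0 by default, so 0.01 is 1% of the reference).  Baseline
    coefficients are drawn uniformly from ``[0, baseline_max]`` per spectrum
    for the constant, linear, and quadratic terms over a [0, 1]-rescaled axis.
    """

    additive_sd: float = 0.01
    baseline_max: float = 0.03

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.baseline_max < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(additive_sd=0.0, baseline_max=0.0)

    @property
    def enabled(self) -> bool:
        return self.additive_sd > 0 or self.baseline_max > 0


def _lorentzian(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return gamma * gamma / ((axis - center) ** 2 + gamma * gamma)


def _clean_intensities(probe: ProbeResponseModel, c_gsh: float, c_h2o2: float) -> np.ndarray:
    amps = probe.amplitudes(c_gsh, c_h2o2)
    y = np.zeros_like(probe.axis)
    for p, a in zip(probe.peaks, amps):
        y += a * _lorentzian(probe.axis, p.center, p.fwhm)
    return y


def _noise_terms(noise: NoiseModel, axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    c0, c1, c2 = rng.uniform(0.0, noise.baseline_max, size=3)
    baseline = c0 + c1 * t + c2 * t * t
    return baseline + rng.normal(0.0, noise.additive_sd, size=axis.size)


def simulate_spectrum(
    c_gsh: float,
    c_h2o2: float,
    probe: Optional[ProbeResponseModel] = None,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> LabeledSpectrum:
    """One simulated acquisition at the given concentrations (mM, uM)."""
    probe = probe or ProbeResponseModel()
    noise = noise or NoiseModel.off()
    if c_gsh < 0 or c_h2o2 < 0:
        raise ValueError("concentrations must be non-negative")
    y = _clean_intensities(probe, c_gsh, c_h2o2)
    if noise.enabled:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + _noise_terms(noise, probe.axis, rng)
    y = np.clip(y, 0.0, None)
    return LabeledSpectrum(
        spectrum=Spectrum(probe.axis, y),
        c_gsh=float(c_gsh),
        c_h2o2=float(c_h2o2),
        extrapolated=probe.is_extrapolated(c_gsh, c_h2o2),
    )


def build_calibration_dataset(
    gsh_levels: Optional[Sequence[float]] = None,
    h2o2_levels: Optional[Sequence[float]] = None,
    replicates: int = REPLICATES,
    probe: Optional[ProbeResponseModel] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
) -> list[LabeledSpectrum]:
    """Full factorial calibration set: every (GSH, H2O2) level pair with the
    given number of noisy replicates; defaults are the 6 x 8 x 200 design."""
    gsh_levels = tuple(gsh_levels) if gsh_levels is not None else GSH_LEVELS_MM
    h2o2_levels = tuple(h2o2_levels) if h2o2_levels is not None else H2O2_LEVELS_UM
    if not gsh_levels or not h2o2_levels or replicates < 1:
        raise ValueError("need non-empty level lists and replicates >= 1")
    if len(set(gsh_levels)) != len(gsh_levels) or len(set(h2o2_levels)) != len(h2o2_levels):
        raise ValueError("duplicate concentration level in calibration design")
    probe = probe or ProbeResponseModel()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    out = []
    for g in gsh_levels:
        for h in h2o2_levels:
            for _ in range(replicates):
                out.append(simulate_spectrum(g, h, probe, noise, rng))
    return out


@dataclass(frozen=True)
class ClassStats:
    gsh_mean: float
    gsh_sd: float
    h2o2_mean: float
    h2o2_sd: float

    def __post_init__(self) -> None:
        if self.gsh_sd < 0 or self.h2o2_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class CohortParams:
    """Per-class concentration statistics for simulated tissue cohorts.

    Tumor defaults are the reported in vivo allograft values; normal-brain
    GSH sits below 1 mM as reported, and its H2O2 (not printed) defaults to a
    low physiological 30 uM.
    """

    classes: dict = field(
        default_factory=lambda: {
            "normal": ClassStats(0.8, 0.15, 30.0, 8.0),
            "WT": ClassStats(12.08, 0.53, 68.54, 4.51),
            "MUT": ClassStats(9.20, 0.83, 109.3, 9.44),
        }
    )


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal draws rejected at <= 0 (concentrations are positive)."""
    if sd == 0:
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[draw > 0]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def simulate_tissue_grid(
    cohort: Optional[CohortParams] = None,
    grid_shape: tuple[int, int] = (10, 10),
    probe: Optional[ProbeResponseModel] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    classes: Optional[Sequence[str]] = None,
) -> list[LabeledSpectrum]:
    """Point-by-point scan simulation: one ``grid_shape`` block per class.

    Per point, (c_gsh, c_h2o2) are drawn from the class's truncated normal and
    a spectrum is simulated.  Blocks are laid side by side along x so that the
    combined coordinates are unique: class k occupies columns
    ``[k*cols, (k+1)*cols)``.
    """
    cohort = cohort or CohortParams()
    probe = probe or ProbeResponseModel()
    noise = noise if noise is not None else NoiseModel()
    classes = tuple(classes) if classes is not None else tuple(cohort.classes)
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid_shape must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for k, cls in enumerate(classes):
        if cls not in cohort.classes:
            raise ValueError(f"unknown tissue class {cls!r}")
        st = cohort.classes[cls]
        npts = rows * cols
        gsh = _truncated_normal(st.gsh_mean, st.gsh_sd, npts, rng)
        h2o2 = _truncated_normal(st.h2o2_mean, st.h2o2_sd, npts, rng)
        for i in range(npts):
            rec = simulate_spectrum(gsh[i], h2o2[i], probe, noise, rng)
            out.append(
                replace(
                    rec,
                    tissue_class=cls,
                    grid_xy=(i // cols, k * cols + i % cols),
                )
            )
    return out
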