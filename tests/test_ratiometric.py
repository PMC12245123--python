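"""Peak extraction, calibration, inverse quantification, and maps."""

import numpy as np
import pytest

from sersquant import simulate as sim
from sersquant.ratiometric import (
    CalibrationModel,
    RatioMeasurement,
    ReferencePeakError,
    build_map,
    calibrate_from_records,
    compute_ratios,
    fit_calibration,
    peak_intensity,
    quantify,
)
from sersquant.spectra import Spectrum, max_normalize


def _lorentzian_spectrum(centers_amps, fwhm=2.0, axis=None):
    axis = axis if axis is not None else np.arange(400.0, 1800.0, 2.0)
    y = np.zeros_like(axis)
    for c, a in centers_amps:
        g = fwhm / 2
        y += a * g * g / ((axis - c) ** 2 + g * g)
    return Spectrum(axis, y)


class TestPeakIntensity:
    def test_recovers_lorentzian_amplitude(self):
        s = _lorentzian_spectrum([(542.0, 3.7)])
        assert peak_intensity(s, 542.0, 15.0) == pytest.approx(3.7, rel=0.01)

    def test_flat_spectrum_zero(self):
        s = Spectrum(np.arange(400.0, 1800.0, 2.0), np.full(700, 5.0))
        assert peak_intensity(s, 542.0, 15.0) == 0.0

    def test_absent_band_near_zero(self):
        s = _lorentzian_spectrum([(1600.0, 10.0)])
        assert peak_intensity(s, 542.0, 15.0) == pytest.approx(0.0, abs=1e-3)

    def test_window_outside_axis(self):
        s = _lorentzian_spectrum([(542.0, 1.0)])
        with pytest.raises(ValueError):
            peak_intensity(s, 405.0, 15.0)


class TestComputeRatios:
    def test_equal_amplitudes_give_unit_ratios(self):
        s = _lorentzian_spectrum([(542.0, 2.0), (628.0, 2.0), (928.0, 2.0)])
        m = compute_ratios(s)
        assert m.r1 == pytest.approx(1.0, rel=1e-3)
        assert m.r2 == pytest.approx(1.0, rel=1e-3)

    def test_global_scaling_invariance(self, probe, noiseless):
        s = sim.simulate_spectrum(8, 60, probe, noiseless).spectrum
        scaled = Spectrum(s.wavenumbers, 13.7 * s.intensities)
        a, b = compute_ratios(s), compute_ratios(scaled)
        assert a.r1 == pytest.approx(b.r1, rel=1e-12)
        assert a.r2 == pytest.approx(b.r2, rel=1e-12)

    def test_matches_closed_form_response(self, probe, noiseless):
        m = compute_ratios(sim.simulate_spectrum(10, 100, probe, noiseless).spectrum)
        e1, e2 = probe.expected_ratios(10, 100)
        assert m.r1 == pytest.approx(e1, rel=1e-3)
        assert m.r2 == pytest.approx(e2, rel=1e-3)

    def test_normalization_does_not_change_ratios(self, probe, noiseless):
        s = sim.simulate_spectrum(4, 30, probe, noiseless).spectrum
        a, b = compute_ratios(s), compute_ratios(max_normalize(s))
        assert a.r1 == pytest.approx(b.r1, rel=1e-12)

    def test_missing_reference_band(self):
        s = _lorentzian_spectrum([(542.0, 1.0), (628.0, 1.0)])
        with pytest.raises(ReferencePeakError):
            compute_ratios(s)


class TestCalibration:
    def test_exact_line(self):
        concs = np.array([2.0, 6.0, 10.0, 16.0])
        cal = fit_calibration(0.2 + 0.05 * concs, concs, "GSH")
        assert cal.slope == pytest.approx(0.05)
        assert cal.intercept == pytest.approx(0.2)
        assert cal.fit_r2 == pytest.approx(1.0)
        assert cal.valid_range == (2.0, 16.0)

    def test_needs_three_distinct_concentrations(self):
        with pytest.raises(ValueError):
            fit_calibration([0.3, 0.4], [2.0, 4.0], "GSH")
        with pytest.raises(ValueError):
            fit_calibration([0.3, 0.4, 0.4], [2.0, 4.0, 4.0], "GSH")

    def test_sign_invariant_enforced(self):
        concs = np.array([2.0, 6.0, 10.0])
        with pytest.raises(ValueError):
            fit_calibration(1.0 - 0.05 * concs, concs, "GSH")
        with pytest.raises(ValueError):
            fit_calibration(0.2 + 0.05 * concs, concs, "H2O2")

    def test_recovers_simulator_slopes(self, probe, noiseless):
        """Noiseless single-analyte sweeps recover the configured affine
        response of the probe (slope = amplitude slope / reference height)."""
        gsh_recs = [sim.simulate_spectrum(g, 0.0, probe, noiseless)
                    for g in (2.0, 4.0, 6.0, 8.0, 10.0, 16.0)]
        cal = calibrate_from_records(gsh_recs, "GSH")
        expected = 0.20 * probe.gsh_slope / 1.0  # base542 * slope / base928
        assert cal.slope == pytest.approx(expected, rel=1e-3)
        assert cal.fit_r2 > 0.99999
        h_recs = [sim.simulate_spectrum(0.0, h, probe, noiseless)
                  for h in (5.0, 50.0, 100.0, 150.0, 200.0)]
        cal_h = calibrate_from_records(h_recs, "H2O2")
        assert cal_h.slope == pytest.approx(-1.20 * probe.h2o2_slope, rel=1e-3)


@pytest.fixture(scope="module")
def calibrations(probe):
    noiseless = sim.NoiseModel.off()
    gsh = calibrate_from_records(
        [sim.simulate_spectrum(g, 0.0, probe, noiseless) for g in sim.GSH_LEVELS_MM],
        "GSH",
    )
    h2o2 = calibrate_from_records(
        [sim.simulate_spectrum(0.0, h, probe, noiseless) for h in sim.H2O2_LEVELS_UM],
        "H2O2",
    )
    return gsh, h2o2


class TestQuantify:
    def test_inverse_linear_map(self):
        cal_g = CalibrationModel("GSH", 0.05, 0.2, (2.0, 16.0), 1.0)
        cal_h = CalibrationModel("H2O2", -0.004, 1.2, (1.0, 200.0), 1.0)
        g, h, flags = quantify(RatioMeasurement(0.7, 0.8), cal_g, cal_h)
        assert g == pytest.approx(10.0)
        assert h == pytest.approx(100.0)
        assert flags == []

    def test_boundary_and_clipping_flags(self):
        cal_g = CalibrationModel("GSH", 0.05, 0.2, (2.0, 16.0), 1.0)
        cal_h = CalibrationModel("H2O2", -0.004, 1.2, (1.0, 200.0), 1.0)
        g, _, flags = quantify(RatioMeasurement(0.2, 0.8), cal_g, cal_h)
        assert g == 0.0 and "gsh:boundary" in flags and "gsh:extrapolated" in flags
        g, _, flags = quantify(RatioMeasurement(0.1, 0.8), cal_g, cal_h)
        assert g == 0.0 and "gsh:clipped_negative" in flags

    def test_monotonicity(self):
        cal_g = CalibrationModel("GSH", 0.05, 0.2, (2.0, 16.0), 1.0)
        cal_h = CalibrationModel("H2O2", -0.004, 1.2, (1.0, 200.0), 1.0)
        g1, h1, _ = quantify(RatioMeasurement(0.5, 0.9), cal_g, cal_h)
        g2, h2, _ = quantify(RatioMeasurement(0.8, 0.6), cal_g, cal_h)
        assert g2 > g1 and h2 > h1  # larger r1 -> more GSH; smaller r2 -> more H2O2

    def test_roundtrip_through_simulator(self, probe, calibrations):
        """quantify(simulate(c)) recovers every grid concentration within 1%."""
        cal_g, cal_h = calibrations
        noiseless = sim.NoiseModel.off()
        for g in sim.GSH_LEVELS_MM:
            for h in sim.H2O2_LEVELS_UM:
                m = compute_ratios(sim.simulate_spectrum(g, h, probe, noiseless).spectrum)
                gq, hq, _ = quantify(m, cal_g, cal_h)
                assert gq == pytest.approx(g, rel=0.01)
                assert hq == pytest.approx(h, rel=0.01)


class TestMap:
    def test_constant_and_masked(self, calibrations):
        cal_g, cal_h = calibrations
        pts = [RatioMeasurement(0.5, 0.9, grid_xy=(i, j)) for i in range(2) for j in range(2)]
        cmap = build_map(pts, cal_g, cal_h)
        vals = cmap.c_gsh[~cmap.mask]
        assert np.allclose(vals, vals[0])
        # a missing grid cell is masked in every layer
        partial = build_map(pts[:3], cal_g, cal_h)
        assert partial.mask[1, 1]
        assert np.isnan(partial.c_gsh[1, 1]) and np.isnan(partial.ratio[1, 1])

    def test_duplicate_coordinates_rejected(self, calibrations):
        cal_g, cal_h = calibrations
        pts = [RatioMeasurement(0.5, 0.9, grid_xy=(0, 0))] * 2
        with pytest.raises(ValueError):
            build_map(pts, cal_g, cal_h)

    def test_mut_half_has_higher_h2o2_gsh_ratio(self, probe, calibrations):
        """Cohort statistics imply the MUT half-grid shows a higher mean
        H2O2/GSH layer than the WT half."""
        cal_g, cal_h = calibrations
        recs = sim.simulate_tissue_grid(
            grid_shape=(4, 4), probe=probe, noise=sim.NoiseModel.off(),
            seed=11, classes=("WT", "MUT"),
        )
        pts = [compute_ratios(r.spectrum, grid_xy=r.grid_xy) for r in recs]
        cmap = build_map(pts, cal_g, cal_h)
        wt = cmap.ratio[:, :4][~cmap.mask[:, :4]]
        mut = cmap.ratio[:, 4:][~cmap.mask[:, 4:]]
        assert np.nanmean(mut) > np.nanmean(wt)

    def test_long_format_export(self, calibrations):
        cal_g, cal_h = calibrations
        pts = [RatioMeasurement(0.5, 0.9, grid_xy=(0, j)) for j in range(3)]
        df = build_map(pts, cal_g, cal_h).to_dataframe()
        assert list(df.columns) == ["x", "y", "c_gsh", "c_h2o2", "ratio", "mask"]
        assert len(df) == 3
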