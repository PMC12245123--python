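"""Synthetic probe response: monotonicity, orthogonality, design sizes."""

import numpy as np
import pytest

from sersquant import simulate as sim
from sersquant.ratiometric import compute_ratios, peak_intensity
from sersquant.spectra import preprocess


def _intensity_at(rec, center):
    s = rec.spectrum
    return s.intensities[np.argmin(np.abs(s.wavenumbers - center))]


class TestProbeResponse:
    def test_reference_band_inert(self, probe, noiseless):
        amps = [probe.amplitudes(g, h) for g, h in ((0.5, 5), (20, 5), (0.5, 200))]
        ref_idx = [p.center for p in probe.peaks].index(928.0)
        assert len({a[ref_idx] for a in amps}) == 1

    def test_gsh_monotone_up_h2o2_monotone_down(self, probe, noiseless):
        lo = sim.simulate_spectrum(0.5, 50, probe, noiseless)
        hi = sim.simulate_spectrum(20.0, 50, probe, noiseless)
        assert _intensity_at(hi, 542) > _intensity_at(lo, 542)
        lo_h = sim.simulate_spectrum(5.0, 200, probe, noiseless)
        hi_h = sim.simulate_spectrum(5.0, 5, probe, noiseless)
        assert _intensity_at(lo_h, 628) < _intensity_at(hi_h, 628)

    def test_orthogonality_of_channels(self, probe, noiseless):
        """I542 tracks GSH only and I628 tracks H2O2 only (no interference)."""
        r_low = compute_ratios(sim.simulate_spectrum(10, 5, probe, noiseless).spectrum)
        r_high = compute_ratios(sim.simulate_spectrum(10, 200, probe, noiseless).spectrum)
        assert r_low.r1 == pytest.approx(r_high.r1, rel=2e-3)  # r1 constant in H2O2
        g_low = compute_ratios(sim.simulate_spectrum(0.5, 100, probe, noiseless).spectrum)
        g_high = compute_ratios(sim.simulate_spectrum(20, 100, probe, noiseless).spectrum)
        assert g_low.r2 == pytest.approx(g_high.r2, rel=2e-3)  # r2 constant in GSH

    def test_negative_concentration_rejected(self, probe):
        with pytest.raises(ValueError):
            sim.simulate_spectrum(-1.0, 10, probe)

    def test_extrapolation_flag(self, probe, noiseless):
        assert sim.simulate_spectrum(0.1, 50, probe, noiseless).extrapolated
        assert not sim.simulate_spectrum(10, 50, probe, noiseless).extrapolated

    def test_validation_requires_reference_peak(self):
        peaks = tuple(p for p in sim.ProbeResponseModel().peaks if p.center != 928.0)
        with pytest.raises(ValueError):
            sim.ProbeResponseModel(peaks=peaks)


class TestCalibrationDataset:
    def test_full_design_count(self, probe128):
        # full 6 x 8 x 200 design = 9600 spectra; use 1 replicate for speed
        recs = sim.build_calibration_dataset(replicates=1, probe=probe128,
                                             noise=sim.NoiseModel.off(), seed=0)
        assert len(recs) == 48
        assert len(sim.GSH_LEVELS_MM) * len(sim.H2O2_LEVELS_UM) * sim.REPLICATES == 9600

    def test_counting_and_label_pairs(self, probe128, noiseless):
        recs = sim.build_calibration_dataset([1, 2], [10, 20], 3, probe128, noiseless, 0)
        assert len(recs) == 12
        assert len({(r.c_gsh, r.c_h2o2) for r in recs}) == 4
        single = sim.build_calibration_dataset([5], [50], 1, probe128, noiseless, 0)
        assert len(single) == 1

    def test_duplicate_levels_rejected(self, probe128):
        with pytest.raises(ValueError):
            sim.build_calibration_dataset([2, 2], [10], 1, probe128, seed=0)

    def test_deterministic_per_seed(self, probe128):
        a = sim.build_calibration_dataset([2], [10], 3, probe128, sim.NoiseModel(), 5)
        b = sim.build_calibration_dataset([2], [10], 3, probe128, sim.NoiseModel(), 5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.spectrum.intensities, rb.spectrum.intensities)

    def test_noise_average_converges_to_clean(self, probe128):
        """Monte-Carlo: the mean of many noisy replicates approaches the
        noiseless spectrum plus the mean baseline."""
        clean = sim.simulate_spectrum(8, 50, probe128, sim.NoiseModel.off())
        noise = sim.NoiseModel(additive_sd=0.01, baseline_max=0.0)
        rng = np.random.default_rng(0)

        def mean_dev(n):
            reps = np.stack([
                sim.simulate_spectrum(8, 50, probe128, noise, rng).spectrum.intensities
                for _ in range(n)
            ])
            # away from zero signal, where the non-negativity clip is inactive
            mask = clean.spectrum.intensities > 5 * noise.additive_sd
            return np.abs(reps.mean(axis=0) - clean.spectrum.intensities)[mask].max()

        d25, d400 = mean_dev(25), mean_dev(400)
        assert d400 < d25
        assert d400 < 5 * 0.01 / np.sqrt(400)

    def test_preprocessed_spectra_valid(self, probe128):
        recs = sim.build_calibration_dataset([2, 16], [1, 200], 2, probe128,
                                             sim.NoiseModel(), seed=1)
        for rec in preprocess(recs):
            assert rec.spectrum.intensities.max() == pytest.approx(1.0)
            assert np.all(rec.spectrum.intensities >= 0)


class TestTissueGrid:
    def test_cohort_means(self, probe128):
        """WT H2O2 draws center on the reported 68.54 uM within 3 SE."""
        recs = sim.simulate_tissue_grid(grid_shape=(10, 10), probe=probe128,
                                        noise=sim.NoiseModel.off(), seed=0,
                                        classes=("WT",))
        vals = np.array([r.c_h2o2 for r in recs])
        assert len(recs) == 100
        assert abs(vals.mean() - 68.54) < 3 * 4.51 / 10

    def test_zero_sd_gives_exact_means(self, probe128):
        cohort = sim.CohortParams(classes={"WT": sim.ClassStats(12.0, 0.0, 70.0, 0.0)})
        recs = sim.simulate_tissue_grid(cohort, (2, 2), probe128,
                                        sim.NoiseModel.off(), 0, classes=("WT",))
        assert {r.c_gsh for r in recs} == {12.0}
        assert {r.c_h2o2 for r in recs} == {70.0}

    def test_deterministic_and_unique_coords(self, probe128):
        a = sim.simulate_tissue_grid(grid_shape=(3, 4), probe=probe128, seed=9)
        b = sim.simulate_tissue_grid(grid_shape=(3, 4), probe=probe128, seed=9)
        assert [r.c_gsh for r in a] == [r.c_gsh for r in b]
        coords = [r.grid_xy for r in a]
        assert len(set(coords)) == len(coords) == 36
        assert {r.tissue_class for r in a} == {"normal", "WT", "MUT"}

    def test_unknown_class_rejected(self, probe128):
        with pytest.raises(ValueError):
            sim.simulate_tissue_grid(grid_shape=(2, 2), probe=probe128, seed=0,
                                     classes=("WT", "other"))

    def test_truncation_keeps_positive(self):
        rng = np.random.default_rng(0)
        draws = sim._truncated_normal(0.5, 1.0, 500, rng)
        assert np.all(draws > 0)
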