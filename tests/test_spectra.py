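"""Spectrum model, table I/O, preprocessing, and dataset splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sersquant import spectra as sp


class TestSpectrumModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            sp.Spectrum(np.array([2.0, 1.0]), np.array([1.0, 1.0]))  # not increasing
        with pytest.raises(ValueError):
            sp.Spectrum(np.array([1.0, 2.0]), np.array([1.0, np.nan]))
        with pytest.raises(sp.SpectraShapeError):
            sp.Spectrum(np.array([1.0, 2.0]), np.array([1.0]))
        with pytest.raises(sp.SpectraShapeError):
            sp.Spectrum(np.array([1.0]), np.array([1.0]))

    def test_labels_validated(self, toy_spectrum):
        with pytest.raises(ValueError):
            sp.LabeledSpectrum(toy_spectrum, c_gsh=-1.0)
        with pytest.raises(ValueError):
            sp.LabeledSpectrum(toy_spectrum, tissue_class="tumour")


class TestTableIO:
    def test_read_two_acquisitions(self, spectra_table):
        table, manifest = spectra_table
        recs = sp.read_spectra_table(table, manifest)
        assert len(recs) == 2 and all(len(r.spectrum) == 3 for r in recs)
        assert np.array_equal(recs[0].spectrum.wavenumbers, [542, 628, 928])
        assert recs[0].c_gsh == 10 and recs[0].c_h2o2 is None
        assert recs[0].tissue_class == "WT" and recs[0].grid_xy == (0, 1)
        assert recs[1].c_h2o2 == 50 and recs[1].c_gsh is None

    def test_non_numeric_cell_names_location(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("wavenumber,s1\n100,1.0\n200,oops\n")
        with pytest.raises(sp.SpectraParseError, match="row 1.*'s1'"):
            sp.read_spectra_table(bad)

    def test_ragged_column_is_shape_error(self, tmp_path):
        bad = tmp_path / "ragged.csv"
        bad.write_text("wavenumber,s1,s2\n100,1.0,2.0\n200,1.0\n")
        with pytest.raises(sp.SpectraShapeError):
            sp.read_spectra_table(bad)

    def test_unknown_manifest_id(self, spectra_table, tmp_path):
        table, _ = spectra_table
        m = tmp_path / "m.csv"
        m.write_text("id,c_gsh_mM\nnope,1\n")
        with pytest.raises(sp.ManifestReferenceError):
            sp.read_spectra_table(table, m)

    def test_tab_delimited_autodetect(self, tmp_path):
        t = tmp_path / "t.tsv"
        t.write_text("wavenumber\ts1\n100\t1.0\n200\t2.0\n")
        recs = sp.read_spectra_table(t)
        assert recs[0].spectrum.intensities[1] == 2.0

    def test_write_read_roundtrip(self, tmp_path, probe128):
        from sersquant.simulate import build_calibration_dataset

        recs = build_calibration_dataset([2.0, 4.0, 8.0], [1.0, 50.0], 1,
                                         probe=probe128, seed=3)
        table, manifest = tmp_path / "s.csv", tmp_path / "m.csv"
        sp.write_spectra_table(table, recs, manifest)
        back = sp.read_spectra_table(table, manifest)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            np.testing.assert_allclose(
                a.spectrum.intensities, b.spectrum.intensities, rtol=1e-12
            )
            assert (a.c_gsh, a.c_h2o2) == (b.c_gsh, b.c_h2o2)


class TestPreprocessing:
    def test_crop_window_protocol_length(self):
        s = sp.Spectrum(np.arange(1044.0), np.ones(1044))
        out = sp.crop_window(s, 50, 336)
        assert len(out) == 287
        assert out.wavenumbers[0] == 49.0  # 50th point, 1-based

    def test_crop_identity_and_single_point(self, toy_spectrum):
        full = sp.crop_window(toy_spectrum, 1, 3)
        assert np.array_equal(full.intensities, toy_spectrum.intensities)
        with pytest.raises(sp.SpectraShapeError):
            sp.crop_window(toy_spectrum, 2, 2)  # single point < min length

    def test_crop_bounds(self, toy_spectrum):
        with pytest.raises(IndexError):
            sp.crop_window(toy_spectrum, 0, 2)
        with pytest.raises(IndexError):
            sp.crop_window(toy_spectrum, 2, 4)

    def test_crop_composes(self):
        s = sp.Spectrum(np.arange(100.0), np.arange(100.0) ** 2)
        once = sp.crop_window(sp.crop_window(s, 10, 60), 5, 20)
        direct = sp.crop_window(s, 14, 29)  # (a+c-1, a+d-1)
        assert np.array_equal(once.intensities, direct.intensities)

    def test_max_normalize(self, toy_spectrum):
        out = sp.max_normalize(toy_spectrum)
        np.testing.assert_allclose(out.intensities, [0.25, 0.5, 1.0])
        assert out.intensities.max() == 1.0
        again = sp.max_normalize(out)
        np.testing.assert_allclose(again.intensities, out.intensities)

    def test_max_normalize_scale_invariant(self, toy_spectrum):
        scaled = sp.Spectrum(toy_spectrum.wavenumbers, 7.3 * toy_spectrum.intensities)
        np.testing.assert_allclose(
            sp.max_normalize(scaled).intensities,
            sp.max_normalize(toy_spectrum).intensities,
        )

    def test_max_normalize_rejects_zero(self):
        s = sp.Spectrum(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            sp.max_normalize(s)


class TestSplit:
    def test_protocol_sizes(self):
        split = sp.split_dataset(9600, 0.2, 0.1, seed=0)
        assert (split.train.size, split.val.size, split.test.size) == (6912, 768, 1920)

    def test_small_n_rounding(self):
        split = sp.split_dataset(10, 0.2, 0.1, seed=1)
        assert (split.train.size, split.val.size, split.test.size) == (7, 1, 2)

    def test_deterministic(self):
        a = sp.split_dataset(100, seed=7)
        b = sp.split_dataset(100, seed=7)
        assert np.array_equal(a.test, b.test) and np.array_equal(a.train, b.train)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            sp.split_dataset(3, 0.2, 0.1, seed=0)

    def test_stratified_covers_every_cell(self):
        strata = np.repeat(np.arange(8), 25)  # 8 cells x 25 replicates
        split = sp.split_dataset(200, seed=2, strata=strata)
        for part in (split.train, split.val, split.test):
            assert set(strata[part]) == set(range(8))

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(min_value=20, max_value=500),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        test_frac=st.floats(min_value=0.1, max_value=0.5),
        val_frac=st.floats(min_value=0.05, max_value=0.4),
    )
    def test_partition_property(self, n, seed, test_frac, val_frac):
        """Split parts are disjoint and exhaustive for any n/fractions/seed."""
        split = sp.split_dataset(n, test_frac, val_frac, seed=seed)
        combined = np.concatenate([split.train, split.val, split.test])
        assert np.array_equal(np.sort(combined), np.arange(n))
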