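"""Spectrum data model, delimited-text I/O, and preprocessing.

A SERS acquisition is a pair of equal-length vectors: a strictly increasing
wavenumber axis (cm^-1) and non-negative intensities (arbitrary counts).
Preprocessing follows the quantification protocol: keep a fixed index window
of the raw instrument axis (1-based, inclusive), then divide each spectrum by
its maximum so the strongest band equals 1.  Datasets are split 20% test and
the remainder 9:1 train:validation, stratified per concentration pair when
labels are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TISSUE_CLASSES = ("normal", "WT", "MUT")

MANIFEST_COLUMNS = ("id", "c_gsh_mM", "c_h2o2_uM", "tissue_class", "grid_x", "grid_y")


class SpectraParseError(ValueError):
    """A cell in a spectra table or manifest could not be interpreted."""


class SpectraShapeError(ValueError):
    """Ragged or otherwise malformed spectra table."""


class ManifestReferenceError(KeyError):
    """Manifest names an acquisition id absent from the spectra table."""


@dataclass(frozen=True)
class Spectrum:
    """One acquisition: wavenumber axis (cm^-1) plus intensity counts."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise SpectraShapeError(
                f"axis and intensities must be equal-length 1D vectors, got {w.shape} vs {y.shape}"
            )
        if w.size < 2:
            raise SpectraShapeError("a spectrum needs at least 2 points")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite value in spectrum")
        if np.any(y < 0):
            raise ValueError("negative intensity in spectrum")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass(frozen=True)
class LabeledSpectrum:
    """Spectrum plus ground truth: concentrations and/or tissue class.

    ``c_gsh`` is in mM, ``c_h2o2`` in uM; either may be missing (None).
    ``grid_xy`` are integer scan coordinates for mapped acquisitions.
    ``extrapolated`` marks simulated points outside the probe's validated
    concentration ranges.
    """

    spectrum: Spectrum
    c_gsh: Optional[float] = None
    c_h2o2: Optional[float] = None
    tissue_class: Optional[str] = None
    grid_xy: Optional[tuple[int, int]] = None
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.c_gsh is not None and self.c_gsh < 0:
            raise ValueError("c_gsh must be >= 0")
        if self.c_h2o2 is not None and self.c_h2o2 < 0:
            raise ValueError("c_h2o2 must be >= 0")
        if self.tissue_class is not None and self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"tissue_class must be one of {TISSUE_CLASSES}")

    def with_spectrum(self, spectrum: Spectrum) -> "LabeledSpectrum":
        return replace(self, spectrum=spectrum)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train/val/test index sets over one dataset."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in (self.train, self.val, self.test)]
        allidx = np.concatenate(parts)
        if allidx.size != np.unique(allidx).size:
            raise ValueError("split parts overlap")
        n = allidx.size
        if not np.array_equal(np.sort(allidx), np.arange(n)):
            raise ValueError("split parts do not cover 0..n-1 exactly")
        object.__setattr__(self, "train", parts[0])
        object.__setattr__(self, "val", parts[1])
        object.__setattr__(self, "test", parts[2])

    @property
    def n(self) -> int:
        return self.train.size + self.val.size + self.test.size


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.ParserError as exc:  # ragged rows
        raise SpectraShapeError(f"{path}: malformed table ({exc})") from exc
    return df

def read_spectra_table(path, manifest=None) -> list[LabeledSpectrum]:
    """Read a delimited spectra table (and optional label manifest).

    The table's first column is the wavenumber axis; every remaining column is
    one acquisition.  Comma or tab delimiters are auto-detected and ``#``
    comment lines skipped.  The manifest is a CSV with columns
    ``id,c_gsh_mM,c_h2o2_uM,tissue_class,grid_x,grid_y`` (blank = missing);
    its ``id`` values must name intensity columns of the table.
    """
    path = Path(path)
    df = _read_table(path)
    if df.shape[1] < 2:
        raise SpectraShapeError(f"{path}: need a wavenumber column plus >= 1 acquisition")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = int(np.where(bad.isna())[0][0])
            if df[col].isna().iloc[row]:
                raise SpectraShapeError(
                    f"{path}: missing value at row {row}, column '{col}' (ragged table?)"
                )
            raise SpectraParseError(
                f"{path}: non-numeric cell {df[col].iloc[row]!r} at row {row}, column '{col}'"
            )
    w = df.iloc[:, 0].to_numpy(dtype=float)

    labels: dict[str, dict] = {}
    if manifest is not None:
        mdf = pd.read_csv(Path(manifest))
        if "id" not in mdf.columns:
            raise SpectraParseError(f"{manifest}: manifest needs an 'id' column")
        for _, row in mdf.iterrows():
            rid = str(row["id"])
            if rid not in df.columns[1:]:
                raise ManifestReferenceError(
                    f"manifest id {rid!r} not found among acquisitions {list(df.columns[1:])}"
                )
            labels[rid] = row.to_dict()

    def _num(row: dict, key: str) -> Optional[float]:
        v = row.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)

    records = []
    for col in df.columns[1:]:
        spec = Spectrum(w, df[col].to_numpy(dtype=float))
        row = labels.get(str(col), {})
        cls = row.get("tissue_class")
        if isinstance(cls, float) and np.isnan(cls):
            cls = None
        gx, gy = _num(row, "grid_x"), _num(row, "grid_y")
        grid = (int(gx), int(gy)) if gx is not None and gy is not None else None
        records.append(
            LabeledSpectrum(
                spectrum=spec,
                c_gsh=_num(row, "c_gsh_mM"),
                c_h2o2=_num(row, "c_h2o2_uM"),
                tissue_class=cls,
                grid_xy=grid,
            )
        )
    return records


def write_spectra_table(path, records: Sequence[LabeledSpectrum], manifest=None) -> None:
    """Write records in the canonical table/manifest format (inverse of read)."""
    path = Path(path)
    w = records[0].spectrum.wavenumbers
    data = {"wavenumber": w}
    rows = []
    for i, rec in enumerate(records):
        if not np.array_equal(rec.spectrum.wavenumbers, w):
            raise SpectraShapeError("all records must share one wavenumber axis")
        rid = f"s{i}"
        data[rid] = rec.spectrum.intensities
        rows.append(
            {
                "id": rid,
                "c_gsh_mM": rec.c_gsh,
                "c_h2o2_uM": rec.c_h2o2,
                "tissue_class": rec.tissue_class,
                "grid_x": rec.grid_xy[0] if rec.grid_xy else None,
                "grid_y": rec.grid_xy[1] if rec.grid_xy else None,
            }
        )
    pd.DataFrame(data).to_csv(path, index=False)
    if manifest is not None:
        pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def crop_window(s: Spectrum, start_index: int, end_index: int) -> Spectrum:
    """Keep points ``start_index..end_index`` (1-based, inclusive).

    The quantification protocol keeps the 50th through 336th points of the raw
    instrument axis, i.e. ``crop_window(s, 50, 336)`` -> 287 points.
    """
    m = len(s)
    if not (1 <= start_index <= end_index <= m):
        raise IndexError(
            f"crop window ({start_index}, {end_index}) out of range for length {m}"
        )
    sl = slice(start_index - 1, end_index)
    return Spectrum(s.wavenumbers[sl], s.intensities[sl])


def max_normalize(s: Spectrum) -> Spectrum:
    """Divide intensities by their maximum; the output maximum is exactly 1."""
    top = float(np.max(s.intensities))
    if top <= 0:
        raise ValueError("cannot max-normalize a spectrum with non-positive maximum")
    return Spectrum(s.wavenumbers, s.intensities / top)


def preprocess(
    records: Sequence[LabeledSpectrum],
    crop: Optional[tuple[int, int]] = None,
    normalize: bool = True,
) -> list[LabeledSpectrum]:
    """Apply the standard crop -> max-normalize chain to every record."""
    out = []
    for rec in records:
        s = rec.spectrum
        if crop is not None:
            s = crop_window(s, crop[0], crop[1])
        if normalize:
            s = max_normalize(s)
        out.append(rec.with_spectrum(s))
    return out


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

def _apportion(counts: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` across strata, proportional to `counts`
    (largest remainder), capped by per-stratum size."""
    counts = np.asarray(counts, dtype=int)
    if total > counts.sum():
        raise ValueError("cannot apportion more than the number of items")
    quota = counts * total / counts.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for i in order:
        if rem == 0:
            break
        if base[i] < counts[i]:
            base[i] += 1
            rem -= 1
    # cap handling is a no-op for base <= counts by construction of quota
    return base

def split_dataset(
    n: int,
    test_frac: float = 0.2,
    val_frac_of_rest: float = 0.1,
    seed: int = 0,
    strata: Optional[Sequence] = None,
    stratify: bool = True,
) -> DatasetSplit:
    """Random train/val/test split: ``test_frac`` of all data held out, then
    the remainder divided train:val at ``(1-val_frac_of_rest):val_frac_of_rest``
    (the protocol's 20% test, 9:1 train:val).

    Sizes use round-half-even on ``|test| = round(n*test_frac)`` first, then
    ``|val| = round((n-|test|)*val_frac_of_rest)``.  When ``strata`` labels are
    given (e.g. the (GSH, H2O2) level pair) and ``stratify`` is True, the
    held-out counts are spread across strata by largest remainder so every
    concentration cell appears in every part where sizes allow.
    """
    if not (0 < test_frac < 1) or not (0 < val_frac_of_rest < 1):
        raise ValueError("fractions must be in (0, 1)")
    n_test = round(n * test_frac)
    n_val = round((n - n_test) * val_frac_of_rest)
    n_train = n - n_test - n_val
    if min(n_test, n_val, n_train) < 1:
        raise ValueError(f"n={n} too small for non-empty train/val/test parts")

    rng = np.random.default_rng(seed)
    if strata is not None and stratify:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise ValueError("strata labels must have length n")
        groups = pd.unique(strata)
        members = [np.flatnonzero(strata == g) for g in groups]
        sizes = np.array([m.size for m in members])
        test_alloc = _apportion(sizes, n_test)
        val_alloc = _apportion(sizes - test_alloc, n_val)
        test_idx, val_idx, train_idx = [], [], []
        for m, nt, nv in zip(members, test_alloc, val_alloc):
            perm = rng.permutation(m)
            test_idx.append(perm[:nt])
            val_idx.append(perm[nt : nt + nv])
            train_idx.append(perm[nt + nv :])
        test_i = np.sort(np.concatenate(test_idx))
        val_i = np.sort(np.concatenate(val_idx))
        train_i = np.sort(np.concatenate(train_idx))
    else:
        perm = rng.permutation(n)
        test_i = np.sort(perm[:n_test])
        val_i = np.sort(perm[n_test : n_test + n_val])
        train_i = np.sort(perm[n_test + n_val :])
    return DatasetSplit(train=train_i, val=val_i, test=test_i, seed=seed)


def concentration_strata(records: Sequence[LabeledSpectrum]) -> Optional[np.ndarray]:
    """Stratum label per record from its (c_gsh, c_h2o2) pair, or None if any
    record lacks a concentration label."""
    keys = []
    for rec in records:
        if rec.c_gsh is None or rec.c_h2o2 is None:
            return None
        keys.append(f"{rec.c_gsh:.6g}|{rec.c_h2o2:.6g}")
    return np.asarray(keys)
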