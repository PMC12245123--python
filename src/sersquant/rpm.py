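"""Relative Position Matrix: the 1D-spectrum -> 2D-image encoding.

A preprocessed spectrum x of length M maps to the M x M matrix of pairwise
differences RPM[i, j] = x_i - x_j.  The image is antisymmetric with a zero
diagonal, invariant to constant intensity offsets, and homogeneous of degree
one in the intensities; it is the input representation of the 2D models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum


@dataclass(frozen=True)
class RPMImage:
    matrix: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RPM matrix must be square")
        if m.shape[0] != self.source_length:
            raise ValueError("source_length does not match matrix size")
        object.__setattr__(self, "matrix", m)


def rpm(s) -> RPMImage:
    """Relative Position Matrix of a spectrum (or raw intensity vector)."""
    x = s.intensities if isinstance(s, Spectrum) else np.asarray(s, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1D intensity vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensity")
    return RPMImage(matrix=x[:, None] - x[None, :], source_length=x.size)


def rpm_batch(X: np.ndarray, dtype=np.float32) -> np.ndarray:
    """Vectorized RPM for a stack of spectra: (N, M) -> (N, M, M)."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a (N, M) array of spectra")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite intensity")
    return (X[:, :, None] - X[:, None, :]).astype(dtype)
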