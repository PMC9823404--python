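"""Wavelet compression of voltammograms.

Each trace is run through an L-level discrete wavelet transform (default
Daubechies-4, level 3, symmetric boundary extension) and only the
approximation coefficients are kept: a 177-point DPV scan compresses to 28
numbers.  Reconstruction inverts the cascade with the detail bands zeroed;
fidelity is scored by the Pearson correlation between original and
reconstructed traces (the "comparison factor").
"""

from __future__ import annotations

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

_MODE = "symmetric"


def coefficient_length(n: int, wavelet: str = "db4", level: int = 3) -> int:
    """Approximation length after ``level`` analysis steps.

    Each full-convolution step maps n -> floor((n + L - 1) / 2) where L is
    the filter length (8 for db4).
    """
    if level < 1:
        raise ValueError("level must be at least 1")
    filt_len = pywt.Wavelet(wavelet).dec_len
    for _ in range(level):
        if n < filt_len:
            raise ValueError(
                f"signal of length {n} too short for {wavelet} (filter length {filt_len})"
            )
        n = (n + filt_len - 1) // 2
    return n


def _coeff_shapes(n: int, wavelet: str, level: int) -> list[int]:
    """Per-band lengths [cA_L, cD_L, ..., cD_1] of the analysis cascade."""
    filt_len = pywt.Wavelet(wavelet).dec_len
    lengths = []
    for _ in range(level):
        if n < filt_len:
            raise ValueError("signal too short for requested level")
        n = (n + filt_len - 1) // 2
        lengths.append(n)
    return [lengths[-1]] + lengths[::-1]


def compress(signal: np.ndarray, wavelet: str = "db4", level: int = 3) -> np.ndarray:
    """Level-``level`` approximation coefficients of one signal."""
    signal = np.asarray(signal, dtype=float)
    coefficient_length(signal.shape[-1], wavelet, level)  # validates length
    coeffs = pywt.wavedec(signal, wavelet, mode=_MODE, level=level, axis=-1)
    return coeffs[0]


def reconstruct(
    coefficients: np.ndarray, wavelet: str, level: int, original_length: int
) -> np.ndarray:
    """Inverse cascade from approximation coefficients only (details zeroed),
    trimmed to the original length."""
    coefficients = np.asarray(coefficients, dtype=float)
    shapes = _coeff_shapes(original_length, wavelet, level)
    if coefficients.shape[-1] != shapes[0]:
        raise ValueError(
            f"expected {shapes[0]} approximation coefficients for length "
            f"{original_length} at level {level}, got {coefficients.shape[-1]}"
        )
    zeros = [
        np.zeros(coefficients.shape[:-1] + (m,), dtype=float) for m in shapes[1:]
    ]
    full = pywt.waverec([coefficients] + zeros, wavelet, mode=_MODE, axis=-1)
    return full[..., :original_length]


def comparison_factor(original: np.ndarray, recovered: np.ndarray) -> float:
    """Pearson correlation between a trace and its reconstruction."""
    original = np.asarray(original, dtype=float).ravel()
    recovered = np.asarray(recovered, dtype=float).ravel()
    if original.shape != recovered.shape:
        raise ValueError("traces must have equal length")
    if np.ptp(original) == 0 or np.ptp(recovered) == 0:
        raise ValueError("comparison factor undefined for zero-variance traces")
    return float(np.corrcoef(original, recovered)[0, 1])


class WaveletCompressor(TransformerMixin, BaseEstimator):
    """Approximation-coefficient compressor with sklearn transformer semantics.

    ``transform`` maps (n_samples, n_points) traces to (n_samples, n_coeff)
    approximation coefficients; ``inverse_transform`` returns the
    approximation-only reconstruction at the original length.

    Parameters
    ----------
    wavelet : str, default "db4"
        Orthogonal wavelet name understood by PyWavelets.
    level : int, default 3
        Number of analysis steps.
    """

    def __init__(self, wavelet: str = "db4", level: int = 3):
        self.wavelet = wavelet
        self.level = level

    def fit(self, X, y=None):
        X = check_array(X)
        self.original_length_ = X.shape[1]
        self.n_coefficients_ = coefficient_length(
            self.original_length_, self.wavelet, self.level
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "original_length_")
        X = check_array(X)
        if X.shape[1] != self.original_length_:
            raise ValueError(
                f"expected traces of length {self.original_length_}, got {X.shape[1]}"
            )
        return compress(X, self.wavelet, self.level)

    def inverse_transform(self, A) -> np.ndarray:
        check_is_fitted(self, "original_length_")
        A = check_array(A)
        return reconstruct(A, self.wavelet, self.level, self.original_length_)

    def comparison_factors(self, X) -> np.ndarray:
        """Per-trace Pearson correlation between input and its
        approximation-only reconstruction."""
        X = check_array(X)
        rec = self.inverse_transform(self.transform(X))
        return np.array(
            [comparison_factor(x, r) for x, r in zip(X, rec)]
        )

    def mean_comparison_factor(self, X) -> float:
        return float(np.mean(self.comparison_factors(X)))
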