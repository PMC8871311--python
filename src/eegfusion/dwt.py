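"""Multilevel discrete wavelet decomposition (orthonormal Haar, level 5).

Backed by PyWavelets with symmetric boundary extension, so level-k
coefficient sequences have length ceil(n / 2^k) and the transform is
orthonormal: for Haar, ``approx_i = (x_{2i} + x_{2i+1})/sqrt(2)`` and
``detail_i = (x_{2i} - x_{2i+1})/sqrt(2)``, giving exact energy
conservation and perfect reconstruction on even-length inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import LengthError

DEFAULT_WAVELET = "haar"
DEFAULT_LEVEL = 5
_MODE = "symmetric"


@dataclass
class WaveletDecomposition:
    """1 approximation + L detail coefficient sequences for one channel.

    ``details`` is ordered deepest-first: cD_L, cD_{L-1}, ..., cD_1.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    level: int
    wavelet_name: str = DEFAULT_WAVELET

    @property
    def sequences(self) -> list[np.ndarray]:
        """All coefficient sequences in the canonical order cA_L, cD_L ... cD_1."""
        return [self.approx, *self.details]

    @property
    def sequence_names(self) -> list[str]:
        return [f"cA{self.level}"] + [f"cD{k}" for k in range(self.level, 0, -1)]


def dwt_single_level(x, wavelet: str = DEFAULT_WAVELET) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: (approximation, detail) from low/high-pass + downsample."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise LengthError(f"need at least 2 samples, got {x.size}")
    approx, detail = pywt.dwt(x, wavelet, mode=_MODE)
    return approx, detail


def wavedec(x, wavelet: str = DEFAULT_WAVELET, level: int = DEFAULT_LEVEL) -> WaveletDecomposition:
    """Recursive decomposition of the approximation branch, ``level`` times."""
    x = np.asarray(x, dtype=float)
    if x.size < 2**level:
        raise LengthError(
            f"level-{level} decomposition needs at least {2**level} samples, got {x.size}"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=_MODE, level=level)
    return WaveletDecomposition(
        approx=coeffs[0], details=list(coeffs[1:]), level=level, wavelet_name=wavelet
    )


def waverec(dec: WaveletDecomposition, length: int | None = None) -> np.ndarray:
    """Inverse transform; ``length`` trims the symmetric-extension surplus."""
    x = pywt.waverec([dec.approx, *dec.details], dec.wavelet_name, mode=_MODE)
    return x[:length] if length is not None else x
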