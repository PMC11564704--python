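"""Multilevel discrete wavelet decomposition (low-pass subbands only).

Each level applies one single-level DWT to the previous approximation and
keeps the approximation (low-pass) coefficients; detail coefficients are
computed and discarded.  With the default db4 wavelet and half-point
symmetric boundary extension, each level has length (n + 7) // 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .pattern import BLOCK_SIZE

__all__ = ["WaveletBandSet", "mdwt_decompose", "min_signal_length"]

DEFAULT_WAVELET = "db4"
DEFAULT_MODE = "symmetric"  # half-point symmetric extension
DEFAULT_LEVELS = 4


@dataclass(frozen=True)
class WaveletBandSet:
    """Ordered low-pass subbands L1..Lk of one signal."""

    levels: tuple[np.ndarray, ...]
    wavelet_name: str
    boundary_mode: str

    def __iter__(self):
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.levels[i]


def _level_length(n: int, wavelet: str, mode: str) -> int:
    return pywt.dwt_coeff_len(n, pywt.Wavelet(wavelet).dec_len, mode)


def min_signal_length(
    levels: int = DEFAULT_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
    min_final: int = BLOCK_SIZE,
) -> int:
    """Smallest input length whose level-``levels`` subband has >= min_final samples."""
    n = min_final
    while True:
        m = n
        for _ in range(levels):
            m = _level_length(m, wavelet, mode)
        if m >= min_final:
            return n
        n += 1


def mdwt_decompose(
    signal: Sequence[float] | np.ndarray,
    levels: int = DEFAULT_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> WaveletBandSet:
    """Iterated single-level DWT keeping only approximation coefficients."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    need = min_signal_length(levels, wavelet, mode)
    if x.size < need:
        raise ValueError(
            f"signal of length {x.size} too short for {levels}-level {wavelet} "
            f"decomposition with usable subbands; minimum length is {need}"
        )
    approx = x
    bands: list[np.ndarray] = []
    for _ in range(levels):
        approx, _detail = pywt.dwt(approx, wavelet, mode=mode)
        bands.append(approx)
    return WaveletBandSet(
        levels=tuple(bands), wavelet_name=wavelet, boundary_mode=mode
    )
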