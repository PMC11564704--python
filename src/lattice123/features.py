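"""Multilevel feature assembly: raw signal + 4 wavelet subbands x 6 categories.

For one channel epoch the transform is applied to the raw signal and to its
four low-pass wavelet subbands; for each category q the five 256-bin
histograms are concatenated (raw, L1, L2, L3, L4) into one length-1280
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lattice import LatticeTopology
from .pattern import N_BINS, N_CATEGORIES, lattice123_transform
from .wavelet import DEFAULT_LEVELS, DEFAULT_MODE, DEFAULT_WAVELET, mdwt_decompose

__all__ = ["ChannelFeatureSet", "extract_channel_features", "extract_feature_matrix"]

N_SOURCES = 1 + DEFAULT_LEVELS  # raw + L1..L4
VECTOR_LENGTH = N_BINS * N_SOURCES  # 1280


@dataclass(frozen=True)
class ChannelFeatureSet:
    """Six concatenated 1280-length feature vectors for one signal."""

    vectors: np.ndarray  # (6, 1280)
    channel_id: int = -1

    def __post_init__(self) -> None:
        if self.vectors.shape != (N_CATEGORIES, VECTOR_LENGTH):
            raise ValueError(
                f"expected shape {(N_CATEGORIES, VECTOR_LENGTH)}, "
                f"got {self.vectors.shape}"
            )


def extract_channel_features(
    signal: Sequence[float] | np.ndarray,
    topology: LatticeTopology | None = None,
    channel_id: int = -1,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> ChannelFeatureSet:
    """Six 1280-length vectors: per-category concatenation over raw, L1..L4."""
    x = np.asarray(signal, dtype=np.float64)
    bands = mdwt_decompose(x, levels=DEFAULT_LEVELS, wavelet=wavelet, mode=mode)
    sources = [x, *bands]
    out = np.empty((N_CATEGORIES, VECTOR_LENGTH), dtype=np.int64)
    for p, src in enumerate(sources):
        hists = lattice123_transform(src, topology=topology)
        for q, h in enumerate(hists):
            out[q, p * N_BINS : (p + 1) * N_BINS] = h.counts
    return ChannelFeatureSet(vectors=out, channel_id=channel_id)


def extract_feature_matrix(
    epochs: np.ndarray,
    topology: LatticeTopology | None = None,
    channel_id: int = -1,
) -> np.ndarray:
    """Feature matrices for a stack of epochs from one channel.

    epochs: (n_epochs, n_samples).  Returns (6, n_epochs, 1280): one
    epochs-by-features matrix per category.
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 2:
        raise ValueError("epochs must be a 2-D (n_epochs, n_samples) array")
    out = np.empty((N_CATEGORIES, epochs.shape[0], VECTOR_LENGTH), dtype=np.float64)
    for e in range(epochs.shape[0]):
        fs = extract_channel_features(epochs[e], topology=topology, channel_id=channel_id)
        out[:, e, :] = fs.vectors
    return out
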