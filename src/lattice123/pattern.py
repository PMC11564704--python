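"""Histogram features from probability-driven lattice walks.

The transform turns a one-dimensional signal into six 256-bin histograms:

1. the signal is min-max normalized to integers 1..100 and the empirical
   probability of each normalized value is tabulated;
2. the signal is scanned with overlapping blocks of 19 samples (stride 1);
   each block's 19 values populate the 19 lattice vertices, giving every
   vertex the global probability of its normalized value;
3. two greedy walking paths (minimum- and maximum-probability descent) are
   generated per block, and three comparison kernels — signum, upper
   ternary, lower ternary — are applied along each path's 8 edges, yielding
   six 8-bit codes per block;
4. each code stream ("map signal", values 0..255) is histogrammed into a
   256-bin feature vector.

Category numbering is fixed throughout the package:
1 = (min, signum), 2 = (max, signum), 3 = (min, upper), 4 = (min, lower),
5 = (max, upper), 6 = (max, lower).

Kernels compare *raw* block values; normalization feeds only the
probability/walk machinery.  The ternary threshold is half the population
standard deviation of the whole signal being transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .lattice import LatticeTopology, WalkingPath, build_default_lattice

__all__ = [
    "BLOCK_SIZE",
    "N_CATEGORIES",
    "CATEGORY_NAMES",
    "SignalBlock",
    "BitArray",
    "FeatureHistogram",
    "normalize_signal",
    "value_probabilities",
    "iter_blocks",
    "block_vertex_probabilities",
    "kernel_signum",
    "kernel_upper_ternary",
    "kernel_lower_ternary",
    "ternary_threshold",
    "extract_bits",
    "bits_to_decimal",
    "lattice123_transform",
]

BLOCK_SIZE = 19
N_LEVELS = 100  # normalized value range 1..100
N_BINS = 256
N_CATEGORIES = 6

#: (path kind, kernel) per category index 1..6
CATEGORY_NAMES: tuple[tuple[str, str], ...] = (
    ("minimum", "signum"),
    ("maximum", "signum"),
    ("minimum", "upper"),
    ("minimum", "lower"),
    ("maximum", "upper"),
    ("maximum", "lower"),
)


@dataclass(frozen=True)
class SignalBlock:
    """One 19-sample overlapping block with its normalized view."""

    raw: np.ndarray
    normalized: np.ndarray
    start_index: int  # 1-based position of the block's first sample

    def __post_init__(self) -> None:
        if len(self.raw) != BLOCK_SIZE or len(self.normalized) != BLOCK_SIZE:
            raise ValueError(f"block must hold exactly {BLOCK_SIZE} samples")


@dataclass(frozen=True)
class BitArray:
    bits: tuple[int, ...]
    category: int

    def __post_init__(self) -> None:
        if len(self.bits) != 8:
            raise ValueError("bit array must hold exactly 8 bits")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")


@dataclass(frozen=True)
class FeatureHistogram:
    """256-bin histogram of one map signal; the unit feature vector."""

    counts: np.ndarray
    category: int

    def __post_init__(self) -> None:
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"histogram must have {N_BINS} bins")


def _as_signal(signal: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if x.size == 0:
        raise ValueError("signal is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or Inf")
    return x


def normalize_signal(signal: Sequence[float] | np.ndarray) -> np.ndarray:
    """Min-max normalize to integers 1..100.

    x maps to ceil((x - min) / (max - min) * 99) + 1; the minimum maps to 1,
    the maximum to 100, and a constant signal maps to all 1s.
    """
    x = _as_signal(signal)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.size, dtype=np.int64)
    n = np.ceil((x - lo) / (hi - lo) * 99.0).astype(np.int64) + 1
    return n


def value_probabilities(normalized: np.ndarray) -> np.ndarray:
    """Empirical probability of each normalized value 1..100.

    Returns a length-100 array where entry i-1 is count(value == i) / n.
    """
    n = np.asarray(normalized)
    if n.size == 0:
        raise ValueError("normalized signal is empty")
    if n.min() < 1 or n.max() > N_LEVELS:
        raise ValueError(f"normalized values must lie in 1..{N_LEVELS}")
    counts = np.bincount(n, minlength=N_LEVELS + 1)[1:]
    return counts / n.size


def iter_blocks(
    signal: Sequence[float] | np.ndarray, normalized: np.ndarray
) -> Iterator[SignalBlock]:
    """Yield the overlapping 19-sample blocks (stride 1, n - 18 of them)."""
    x = _as_signal(signal)
    if x.size < BLOCK_SIZE:
        raise ValueError(
            f"signal of length {x.size} shorter than block size {BLOCK_SIZE}"
        )
    n = np.asarray(normalized)
    for i in range(x.size - BLOCK_SIZE + 1):
        yield SignalBlock(
            raw=x[i : i + BLOCK_SIZE],
            normalized=n[i : i + BLOCK_SIZE],
            start_index=i + 1,
        )


def block_vertex_probabilities(
    block: SignalBlock, table: np.ndarray
) -> dict[int, float]:
    """Assign vertex j (1..19) the probability of the block's j-th value."""
    return {
        j + 1: float(table[int(block.normalized[j]) - 1]) for j in range(BLOCK_SIZE)
    }


def kernel_signum(a: float, b: float) -> int:
    return 1 if a - b >= 0 else 0


def kernel_upper_ternary(a: float, b: float, tr: float) -> int:
    if tr < 0:
        raise ValueError("ternary threshold must be non-negative")
    return 1 if a - b > tr else 0


def kernel_lower_ternary(a: float, b: float, tr: float) -> int:
    if tr < 0:
        raise ValueError("ternary threshold must be non-negative")
    return 1 if a - b < -tr else 0


def ternary_threshold(signal: Sequence[float] | np.ndarray) -> float:
    """Half the population standard deviation of the whole signal."""
    x = _as_signal(signal)
    if x.size < 2:
        raise ValueError("threshold needs at least 2 samples")
    return float(np.std(x)) / 2.0


def extract_bits(
    block: SignalBlock,
    path: WalkingPath,
    kernel: Callable[..., int],
    tr: float | None = None,
    category: int = 1,
) -> BitArray:
    """Apply a kernel along the path's 8 edges over the block's raw values."""
    v = path.vertices
    bits = []
    for t in range(8):
        a = float(block.raw[v[t] - 1])
        b = float(block.raw[v[t + 1] - 1])
        bits.append(kernel(a, b) if tr is None else kernel(a, b, tr))
    return BitArray(bits=tuple(bits), category=category)


def bits_to_decimal(bits: BitArray | Sequence[int]) -> int:
    """Binary-to-decimal with bit 1 least significant: sum of bit(t) * 2^(t-1)."""
    b = bits.bits if isinstance(bits, BitArray) else tuple(bits)
    if len(b) != 8:
        raise ValueError("expected exactly 8 bits")
    return int(sum(int(bit) << t for t, bit in enumerate(b)))


@lru_cache(maxsize=8)
def _children_table(topology: LatticeTopology) -> tuple[np.ndarray, np.ndarray]:
    """Pad per-vertex child lists to a rectangular int table (0 = no child)."""
    n = topology.n_vertices
    width = max(len(topology.children_of(v)) for v in range(1, n + 1))
    tab = np.zeros((n, width), dtype=np.int64)
    count = np.zeros(n, dtype=np.int64)
    for v in range(1, n + 1):
        kids = topology.children_of(v)
        tab[v - 1, : len(kids)] = kids
        count[v - 1] = len(kids)
    return tab, count


def _walk_all_blocks(
    probs: np.ndarray, topology: LatticeTopology, kind: str
) -> np.ndarray:
    """Vectorized greedy walks for every block at once.

    probs: (n_blocks, 19) vertex probabilities per block.
    Returns (n_blocks, 9) vertex ids.

    Uses a two-way select when no vertex has more than 2 children (true of
    the default lattice); falls back to a padded argmin/argmax otherwise.
    """
    n_blocks, n_vertices = probs.shape
    tab, count = _children_table(topology)
    n_tiers = topology.n_tiers
    paths = np.empty((n_blocks, n_tiers), dtype=np.int64)
    cur = np.full(n_blocks, topology.source, dtype=np.int64)
    paths[:, 0] = cur
    flat = probs.ravel()
    base = np.arange(n_blocks) * n_vertices

    if tab.shape[1] <= 2:
        k0 = tab[:, 0]
        k1 = np.where(count > 1, tab[:, 1], tab[:, 0])  # duplicate when single child
        for step in range(1, n_tiers - 1):
            c0 = k0[cur - 1]
            c1 = k1[cur - 1]
            p0 = flat[base + c0 - 1]
            p1 = flat[base + c1 - 1]
            # strict comparison: ties keep the lower-id child c0
            take1 = p1 < p0 if kind == "minimum" else p1 > p0
            cur = np.where(take1, c1, c0)
            paths[:, step] = cur
    else:
        pad = np.inf if kind == "minimum" else -np.inf
        rows = np.arange(n_blocks)
        for step in range(1, n_tiers - 1):
            kids = tab[cur - 1]
            kid_probs = np.where(kids > 0, probs[rows[:, None], kids - 1], pad)
            idx = (
                np.argmin(kid_probs, axis=1)
                if kind == "minimum"
                else np.argmax(kid_probs, axis=1)
            )
            cur = kids[rows, idx]
            paths[:, step] = cur
    paths[:, -1] = topology.sink
    return paths


_BIT_WEIGHTS = (1 << np.arange(8)).astype(np.int64)


def lattice123_transform(
    signal: Sequence[float] | np.ndarray,
    topology: LatticeTopology | None = None,
    engine: str = "auto",
) -> list[FeatureHistogram]:
    """Full transform: six 256-bin histograms for one signal.

    Each histogram sums to n - 18 (the number of 19-sample blocks).
    ``engine`` is "auto" (compiled core when available), "numba" or "numpy";
    both engines are exact and bit-identical.
    """
    x = _as_signal(signal)
    if x.size < BLOCK_SIZE:
        raise ValueError(
            f"signal of length {x.size} shorter than block size {BLOCK_SIZE}"
        )
    topo = topology if topology is not None else build_default_lattice()

    normalized = normalize_signal(x)
    table = value_probabilities(normalized)
    tr = ternary_threshold(x) if x.size >= 2 else 0.0

    if engine != "numpy":
        from ._fast import HAVE_NUMBA, _transform_core

        tab, count = _children_table(topo)
        if HAVE_NUMBA and tab.shape[1] <= 2 and topo.n_vertices == BLOCK_SIZE:
            k0 = tab[:, 0].copy()
            k1 = np.where(count > 1, tab[:, -1], tab[:, 0])
            hists = _transform_core(
                x, normalized, table, k0, k1, tr, topo.n_tiers, topo.sink
            )
            return [
                FeatureHistogram(counts=hists[q], category=q + 1)
                for q in range(N_CATEGORIES)
            ]
        if engine == "numba":
            raise RuntimeError("numba engine unavailable for this configuration")

    raw_win = sliding_window_view(x, BLOCK_SIZE)  # (n_blocks, 19)
    norm_win = sliding_window_view(normalized, BLOCK_SIZE)
    probs = table[norm_win - 1]

    paths = {
        kind: _walk_all_blocks(probs, topo, kind) for kind in ("minimum", "maximum")
    }
    # per-path values along the walk and their successive differences a - b
    diffs = {}
    rows = np.arange(raw_win.shape[0])[:, None]
    for kind, p in paths.items():
        vals = raw_win[rows, p - 1]  # (n_blocks, 9)
        diffs[kind] = vals[:, :-1] - vals[:, 1:]

    histograms: list[FeatureHistogram] = []
    for category, (kind, kernel) in enumerate(CATEGORY_NAMES, start=1):
        d = diffs[kind]
        if kernel == "signum":
            bits = d >= 0
        elif kernel == "upper":
            bits = d > tr
        else:  # lower
            bits = d < -tr
        codes = bits.astype(np.int64) @ _BIT_WEIGHTS
        counts = np.bincount(codes, minlength=N_BINS)
        histograms.append(FeatureHistogram(counts=counts, category=category))
    return histograms
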