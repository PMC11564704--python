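"""Optional numba-compiled core for the per-block transform loop.

Semantically identical to the numpy path in :mod:`lattice123.pattern`
(same greedy walks, tie-breaks and kernel comparisons); used automatically
when numba imports, exercised against the numpy path in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _transform_core(
    x: np.ndarray,  # float64 signal
    norm: np.ndarray,  # int64 normalized values 1..100
    pr: np.ndarray,  # float64 length-100 probability table
    k0: np.ndarray,  # int64 per-vertex first child (0 if none)
    k1: np.ndarray,  # int64 per-vertex second child (== first if single)
    tr: float,
    n_tiers: int,
    sink: int,
) -> np.ndarray:
    """Accumulate the six 256-bin histograms over all 19-sample blocks."""
    n = x.size
    block = sink  # block size equals the vertex count (19)
    n_blocks = n - block + 1
    hists = np.zeros((6, 256), dtype=np.int64)
    path = np.empty(n_tiers, dtype=np.int64)
    for i in range(n_blocks):
        for kind in range(2):  # 0 = minimum, 1 = maximum
            cur = 1
            path[0] = 1
            for step in range(1, n_tiers - 1):
                c0 = k0[cur - 1]
                c1 = k1[cur - 1]
                p0 = pr[norm[i + c0 - 1] - 1]
                p1 = pr[norm[i + c1 - 1] - 1]
                if kind == 0:
                    cur = c1 if p1 < p0 else c0
                else:
                    cur = c1 if p1 > p0 else c0
                path[step] = cur
            path[n_tiers - 1] = sink
            code_sig = 0
            code_up = 0
            code_lo = 0
            for t in range(n_tiers - 1):
                a = x[i + path[t] - 1]
                b = x[i + path[t + 1] - 1]
                d = a - b
                if d >= 0.0:
                    code_sig += 1 << t
                if d > tr:
                    code_up += 1 << t
                if d < -tr:
                    code_lo += 1 << t
            if kind == 0:
                hists[0, code_sig] += 1
                hists[2, code_up] += 1
                hists[3, code_lo] += 1
            else:
                hists[1, code_sig] += 1
                hists[4, code_up] += 1
                hists[5, code_lo] += 1
    return hists
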