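"""The fixed 19-vertex lattice and probability-driven walking paths.

The lattice is a 9-tier directed acyclic graph whose top three tiers hold
1, 2 and 3 vertices (hence "123").  Vertices are numbered 1..19 tier by
tier, left to right; all 28 edges point from one tier to the next, so every
source-to-sink traversal visits exactly one vertex per tier.  A *walking
path* is the greedy traversal that, at each tier, steps to the child whose
assigned probability is smallest (``kind="minimum"``) or largest
(``kind="maximum"``); the walk always starts at vertex 1 and is forced to
terminate at vertex 19.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "LatticeTopology",
    "WalkingPath",
    "build_default_lattice",
    "children",
    "walk",
    "load_topology",
    "dump_topology",
]

DEFAULT_TIERS: tuple[int, ...] = (1, 2, 3, 3, 3, 3, 2, 1, 1)

WalkKind = Literal["minimum", "maximum"]


@dataclass(frozen=True)
class LatticeTopology:
    """Tiered DAG over vertices 1..n with edges only between adjacent tiers."""

    tiers: tuple[int, ...]
    edges: frozenset[tuple[int, int]]
    #: children[v] sorted ascending, computed once at construction
    _children: dict[int, tuple[int, ...]] = field(
        init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        n = self.n_vertices
        kids: dict[int, list[int]] = {v: [] for v in range(1, n + 1)}
        for parent, child in self.edges:
            kids[parent].append(child)
        object.__setattr__(
            self, "_children", {v: tuple(sorted(c)) for v, c in kids.items()}
        )
        self._validate()

    @property
    def n_vertices(self) -> int:
        return sum(self.tiers)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_tiers(self) -> int:
        return len(self.tiers)

    @property
    def source(self) -> int:
        return 1

    @property
    def sink(self) -> int:
        return self.n_vertices

    def tier_of(self, vertex: int) -> int:
        """1-based tier index of a vertex."""
        upper = 0
        for t, size in enumerate(self.tiers, start=1):
            upper += size
            if vertex <= upper:
                return t
        raise KeyError(f"vertex {vertex} not in lattice")

    def children_of(self, vertex: int) -> tuple[int, ...]:
        try:
            return self._children[vertex]
        except KeyError:
            raise KeyError(
                f"unknown vertex id {vertex}; valid ids are 1..{self.n_vertices}"
            ) from None

    def _validate(self) -> None:
        n = self.n_vertices
        indeg = {v: 0 for v in range(1, n + 1)}
        for parent, child in self.edges:
            if not (1 <= parent <= n and 1 <= child <= n):
                raise ValueError(f"edge ({parent},{child}) outside vertex range 1..{n}")
            if self.tier_of(child) != self.tier_of(parent) + 1:
                raise ValueError(
                    f"edge ({parent},{child}) does not connect adjacent tiers"
                )
            indeg[child] += 1
        sources = [v for v in indeg if indeg[v] == 0]
        sinks = [v for v in range(1, n + 1) if not self._children[v]]
        if sources != [self.source]:
            raise ValueError(f"expected unique source vertex 1, found {sources}")
        if sinks != [self.sink]:
            raise ValueError(f"expected unique sink vertex {self.sink}, found {sinks}")


@dataclass(frozen=True)
class WalkingPath:
    """Greedy source-to-sink traversal: one vertex per tier."""

    vertices: tuple[int, ...]
    kind: WalkKind


@lru_cache(maxsize=1)
def build_default_lattice() -> LatticeTopology:
    """Construct the default 19-vertex, 28-edge lattice.

    Tier sizes are (1, 2, 3, 3, 3, 3, 2, 1, 1).  Edge rules between tier t
    (size a) and tier t+1 (size b), with within-tier positions 1-based:

    * expanding (b = a + 1): parent i connects to children i and i + 1;
    * equal (b = a): parent i connects to children i and i + 1, truncated
      at the right edge of the tier;
    * contracting (b = a - 1): child j receives parents j and j + 1.
    """
    return LatticeTopology(tiers=DEFAULT_TIERS, edges=frozenset(_default_edges()))


def _default_edges() -> Iterable[tuple[int, int]]:
    tiers = DEFAULT_TIERS
    offsets = np.concatenate([[0], np.cumsum(tiers)])
    for t in range(len(tiers) - 1):
        a, b = tiers[t], tiers[t + 1]
        po, co = int(offsets[t]), int(offsets[t + 1])
        if b > a:  # expanding
            for i in range(1, a + 1):
                yield (po + i, co + i)
                yield (po + i, co + i + 1)
        elif b == a:
            for i in range(1, a + 1):
                yield (po + i, co + i)
                if i + 1 <= b:
                    yield (po + i, co + i + 1)
        else:  # contracting
            for j in range(1, b + 1):
                yield (po + j, co + j)
                yield (po + j + 1, co + j)


def children(topology: LatticeTopology, vertex: int) -> tuple[int, ...]:
    """Children of ``vertex``, sorted ascending (empty only for the sink)."""
    return topology.children_of(vertex)


def walk(
    topology: LatticeTopology,
    vertex_probabilities: Mapping[int, float] | Sequence[float] | np.ndarray,
    kind: WalkKind,
) -> WalkingPath:
    """Greedy probability descent from vertex 1 to the sink.

    At each tier the walk moves to the child with the smallest
    (``kind="minimum"``) or largest (``kind="maximum"``) probability; ties
    break toward the lowest child id.  The final step is forced to the sink.

    ``vertex_probabilities`` maps every vertex id 1..n to a probability,
    or is a length-n sequence indexed by ``vertex - 1``.
    """
    if kind not in ("minimum", "maximum"):
        raise ValueError(f"kind must be 'minimum' or 'maximum', got {kind!r}")
    n = topology.n_vertices

    def prob(v: int) -> float:
        if isinstance(vertex_probabilities, Mapping):
            try:
                return float(vertex_probabilities[v])
            except KeyError:
                raise KeyError(f"no probability defined for vertex {v}") from None
        if len(vertex_probabilities) != n:
            raise ValueError(
                f"expected {n} probabilities, got {len(vertex_probabilities)}"
            )
        return float(vertex_probabilities[v - 1])

    path = [topology.source]
    current = topology.source
    # choose freely through the next-to-last tier; the last step is forced
    for _ in range(topology.n_tiers - 2):
        kids = topology.children_of(current)
        values = [prob(c) for c in kids]
        idx = int(np.argmin(values)) if kind == "minimum" else int(np.argmax(values))
        current = kids[idx]
        path.append(current)
    path.append(topology.sink)
    if (path[-2], path[-1]) not in topology.edges:
        raise ValueError(
            f"walk reached vertex {path[-2]} with no edge to sink {path[-1]}"
        )
    return WalkingPath(vertices=tuple(path), kind=kind)


def dump_topology(topology: LatticeTopology) -> str:
    """Serialize to the plain-text config: tier sizes then one edge per line."""
    lines = ["tiers " + " ".join(str(t) for t in topology.tiers)]
    lines += [f"{p} {c}" for p, c in sorted(topology.edges)]
    return "\n".join(lines) + "\n"


def load_topology(text: str) -> LatticeTopology:
    """Parse the plain-text topology config produced by :func:`dump_topology`."""
    tiers: tuple[int, ...] | None = None
    edges: set[tuple[int, int]] = set()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "tiers":
            tiers = tuple(int(p) for p in parts[1:])
        else:
            if len(parts) != 2:
                raise ValueError(f"bad topology line: {raw!r}")
            edges.add((int(parts[0]), int(parts[1])))
    if tiers is None:
        raise ValueError("topology config missing 'tiers' line")
    return LatticeTopology(tiers=tiers, edges=frozenset(edges))
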