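"""Bone-marrow lattice geometry.

The marrow is modeled as a connected, locally finite undirected graph
``G = (V, L)`` whose vertices are lattice sites (cells or empty space) and
whose edges link each site to its immediate neighbors.  The shipped geometry
is the two-dimensional rectangular lattice with Moore (8-neighbor)
connectivity, either with hard boundaries (``bounded``) or periodic wrap
(``torus``).  On this lattice the graph shortest-path metric coincides with
the Chebyshev distance, which the module exploits for closed-form distances
and balls.

Directions are indexed 0..7 clockwise starting from the top-right diagonal
(NE), with row 0 at the top of the screen:

    index:     0   1   2   3   4   5   6   7
    compass:   NE  E   SE  S   SW  W   NW  N

This fixed order is what makes the stem-cell round-robin proliferation rule
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

__all__ = [
    "MU",
    "MOORE_DIRECTIONS",
    "Vertex",
    "Grid",
    "neighbors",
    "distance",
    "ball",
]

#: Maximum vertex degree of the 2-D Moore lattice; also the number of
#: proliferation directions available to a stem cell.
MU: int = 8

#: (row, col) offsets of the 8 Moore directions, clockwise from NE.
MOORE_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (-1, +1),  # 0: NE
    (0, +1),   # 1: E
    (+1, +1),  # 2: SE
    (+1, 0),   # 3: S
    (+1, -1),  # 4: SW
    (0, -1),   # 5: W
    (-1, -1),  # 6: NW
    (-1, 0),   # 7: N
)

TOPOLOGIES = ("bounded", "torus")


class Vertex(NamedTuple):
    """A lattice site, 0-based, row 0 at the top."""

    row: int
    col: int


class InvalidVertexError(ValueError):
    """Raised when a coordinate falls outside the lattice."""


@dataclass(frozen=True)
class Grid:
    """A 2-D Moore lattice of ``height`` rows by ``width`` columns."""

    width: int
    height: int
    topology: str = "bounded"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"topology must be one of {TOPOLOGIES}, got {self.topology!r}"
            )

    @property
    def max_degree(self) -> int:
        """The degree bound μ (= ω) of the lattice graph."""
        return MU

    @property
    def n_vertices(self) -> int:
        return self.width * self.height

    def contains(self, v: Vertex) -> bool:
        return 0 <= v[0] < self.height and 0 <= v[1] < self.width

    def check_vertex(self, v: Vertex) -> Vertex:
        if not self.contains(v):
            raise InvalidVertexError(
                f"vertex {tuple(v)} outside {self.height}x{self.width} grid"
            )
        return Vertex(*v)

    def vertices(self) -> Iterator[Vertex]:
        """All vertices in row-major order (the model's priority order)."""
        for r in range(self.height):
            for c in range(self.width):
                yield Vertex(r, c)

    def shift(self, v: Vertex, direction: int) -> Vertex | None:
        """Neighbor of ``v`` along a direction index, or None if off-lattice.

        On a torus coordinates wrap, so the result is never None.
        """
        dr, dc = MOORE_DIRECTIONS[direction]
        r, c = v[0] + dr, v[1] + dc
        if self.topology == "torus":
            return Vertex(r % self.height, c % self.width)
        if 0 <= r < self.height and 0 <= c < self.width:
            return Vertex(r, c)
        return None

    def interior(self, v: Vertex, margin: int = 1) -> bool:
        """True if ``v`` is at least ``margin`` sites away from every border.

        On a torus every vertex is interior.
        """
        if self.topology == "torus":
            return True
        r, c = v
        return (
            margin <= r < self.height - margin
            and margin <= c < self.width - margin
        )


def neighbors(grid: Grid, v: Vertex) -> list[Vertex]:
    """Immediate (Moore) neighborhood N(v), in clockwise direction order.

    On bounded grids off-lattice positions are omitted; on a torus all 8
    directions are present (duplicates collapsed on degenerate < 3-wide
    grids, preserving first occurrence).
    """
    grid.check_vertex(v)
    out: list[Vertex] = []
    seen: set[Vertex] = set()
    for k in range(MU):
        u = grid.shift(v, k)
        if u is not None and u != v and u not in seen:
            seen.add(u)
            out.append(u)
    return out


def distance(grid: Grid, u: Vertex, v: Vertex) -> int:
    """Shortest-path distance ρ(u, v) in the lattice graph.

    Equals the Chebyshev distance max(|Δrow|, |Δcol|) on a bounded grid and
    its wrapped counterpart on a torus.
    """
    grid.check_vertex(u)
    grid.check_vertex(v)
    dr = abs(u[0] - v[0])
    dc = abs(u[1] - v[1])
    if grid.topology == "torus":
        dr = min(dr, grid.height - dr)
        dc = min(dc, grid.width - dc)
    return max(dr, dc)


def ball(grid: Grid, v: Vertex, n: int) -> set[Vertex]:
    """Near neighborhood B(v, n) = {u : ρ(u, v) ≤ n}, including v itself."""
    grid.check_vertex(v)
    if n < 0:
        raise ValueError("ball radius must be non-negative")
    out: set[Vertex] = set()
    for dr in range(-n, n + 1):
        for dc in range(-n, n + 1):
            r, c = v[0] + dr, v[1] + dc
            if grid.topology == "torus":
                out.add(Vertex(r % grid.height, c % grid.width))
            elif 0 <= r < grid.height and 0 <= c < grid.width:
                out.add(Vertex(r, c))
    return out
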