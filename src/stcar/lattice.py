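"""Spatial lattices: areal units plus a symmetric neighbour structure.

A :class:`SpatialLattice` is the support of every CAR prior in the package.
It is deliberately minimal — a node count and a set of unordered edges —
because areal models only ever need the 0/1 adjacency matrix and the
neighbour counts.  The temporal random effects reuse the same machinery on
the path graph of length T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialLattice",
    "temporal_path_lattice",
    "make_grid_lattice",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class SpatialLattice:
    """Areal units with symmetric neighbour structure.

    Parameters
    ----------
    n_areas
        Number of areal units (nodes), indexed ``0 .. n_areas - 1``.
    edges
        Unordered index pairs; stored canonically as ``(min, max)`` tuples.
        Self-loops are rejected, duplicates collapse.
    labels
        Optional human-readable area labels, aligned with node indices.
    """

    n_areas: int
    edges: frozenset[tuple[int, int]]
    labels: tuple[str, ...] | None = field(default=None, compare=False)

    def __init__(
        self,
        n_areas: int,
        edges,
        labels=None,
    ) -> None:
        if n_areas < 1:
            raise ValueError(f"n_areas must be positive, got {n_areas}")
        canon = set()
        for a, b in edges:
            a, b = int(a), int(b)
            if a == b:
                raise ValueError(f"self-loop on node {a} is not allowed")
            if not (0 <= a < n_areas and 0 <= b < n_areas):
                raise ValueError(f"edge ({a},{b}) outside 0..{n_areas - 1}")
            canon.add((min(a, b), max(a, b)))
        if labels is not None:
            labels = tuple(str(x) for x in labels)
            if len(labels) != n_areas:
                raise ValueError("labels length must equal n_areas")
        object.__setattr__(self, "n_areas", int(n_areas))
        object.__setattr__(self, "edges", frozenset(canon))
        object.__setattr__(self, "labels", labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def neighbour_counts(self) -> np.ndarray:
        """Per-area degree (number of incident edges)."""
        deg = np.zeros(self.n_areas, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix W (symmetric, zero diagonal)."""
        W = np.zeros((self.n_areas, self.n_areas))
        for a, b in self.edges:
            W[a, b] = W[b, a] = 1.0
        return W

    def area_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        return tuple(str(i) for i in range(self.n_areas))


def temporal_path_lattice(T: int) -> SpatialLattice:
    """Path graph 0—1—…—(T−1), the support of temporal CAR effects.

    Endpoints have degree 1, interior nodes degree 2.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    return SpatialLattice(T, [(t, t + 1) for t in range(T - 1)])


def make_grid_lattice(nx: int, ny: int) -> SpatialLattice:
    """Rook-adjacency rectangular grid with ``nx * ny`` areas.

    Node ``(i, j)`` (row i of ny rows, column j of nx columns) gets index
    ``i * nx + j``; rook neighbours share a grid edge.  Used as the synthetic
    stand-in for an administrative contiguity graph.
    """
    if nx < 1 or ny < 1:
        raise ValueError(f"grid dims must be positive, got ({nx}, {ny})")
    edges = []
    for i in range(ny):
        for j in range(nx):
            k = i * nx + j
            if j + 1 < nx:
                edges.append((k, k + 1))
            if i + 1 < ny:
                edges.append((k, k + nx))
    return SpatialLattice(nx * ny, edges)


def read_edge_list(path, labels=None) -> SpatialLattice:
    """Read a whitespace-separated ``areaA areaB`` edge-list file.

    Labels are arbitrary strings; reversed pairs and duplicates collapse.
    If ``labels`` is given it fixes the label-to-index mapping (areas with no
    edges are then representable); otherwise labels are collected from the
    file and sorted lexicographically.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two labels, got {line!r}")
            pairs.append((parts[0], parts[1]))
    if labels is None:
        labels = sorted({x for p in pairs for x in p})
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    edges = []
    for a, b in pairs:
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ValueError(f"edge label {missing!r} not in area label set")
        edges.append((index[a], index[b]))
    return SpatialLattice(len(labels), edges, labels=labels)


def write_edge_list(lattice: SpatialLattice, path) -> None:
    """Write the lattice as a plain ``areaA areaB`` edge-list file."""
    labs = lattice.area_labels()
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(lattice.edges):
            fh.write(f"{labs[a]} {labs[b]}\n")
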