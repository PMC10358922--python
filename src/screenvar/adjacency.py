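"""Spatial adjacency structures (neighbor lists, GAL text format, polygons)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = ["Adjacency", "build_adjacency", "lattice_adjacency"]


@dataclass
class Adjacency:
    """Symmetric binary contiguity structure over a set of areas.

    ``W`` is the sparse 0/1 neighbor matrix (zero diagonal) and ``D`` its
    row sums (neighbor counts).  Area ids are kept in order so indices
    align with the area table.
    """

    ids: list
    W: sparse.csr_matrix
    D: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = sparse.csr_matrix(self.W)
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.ids):
            raise ValueError("adjacency matrix shape does not match id list")
        if W.diagonal().any():
            W = W - sparse.diags(W.diagonal())
            warnings.warn("self-loops stripped from adjacency")
        asym = (W - W.T)
        if np.abs(asym.data).sum() > 0:
            warnings.warn("asymmetric adjacency symmetrised (union of edges)")
            W = W.maximum(W.T)
        W.data = np.ones_like(W.data)
        W.eliminate_zeros()
        self.W = W.tocsr()
        self.D = np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> list:
        """Ids of areas with zero neighbors."""
        return [self.ids[i] for i in np.flatnonzero(self.D == 0)]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of the neighbors of area index ``i``."""
        return self.W.indices[self.W.indptr[i]: self.W.indptr[i + 1]]

    def degree_sequence(self) -> np.ndarray:
        return self.D.astype(int)

    def is_connected(self) -> bool:
        ncomp, _ = sparse.csgraph.connected_components(self.W, directed=False)
        return ncomp == 1

    @classmethod
    def from_neighbor_lists(cls, neighbors: Mapping) -> "Adjacency":
        ids = list(neighbors)
        index = {a: i for i, a in enumerate(ids)}
        if len(index) != len(ids):
            raise ValueError("duplicate area ids in neighbor lists")
        rows, cols = [], []
        for a, nbrs in neighbors.items():
            for b in nbrs:
                if b not in index:
                    raise ValueError(f"neighbor {b!r} of {a!r} is not a known area")
                rows.append(index[a])
                cols.append(index[b])
        W = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
        )
        return cls(ids=ids, W=W)

    @classmethod
    def from_gal(cls, path: str | Path) -> "Adjacency":
        """Read a GAL-style neighbor list: ``area_id: n1 n2 ...`` per line."""
        neighbors: dict[str, list[str]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'area_id: neighbors'")
            area, _, rest = line.partition(":")
            neighbors[area.strip()] = rest.split()
        return cls.from_neighbor_lists(neighbors)

    def to_gal(self, path: str | Path) -> None:
        lines = []
        for i, a in enumerate(self.ids):
            nbrs = " ".join(str(self.ids[j]) for j in self.neighbors(i))
            lines.append(f"{a}: {nbrs}".rstrip())
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_polygons(cls, geometries: Sequence, ids: Iterable) -> "Adjacency":
        """Contiguity from polygon geometries: areas sharing a boundary
        segment (rook-style; single-point corner contact does not count)."""
        ids = list(ids)
        n = len(ids)
        if n != len(geometries):
            raise ValueError("ids and geometries differ in length")
        rows, cols = [], []
        for i in range(n):
            for j in range(i + 1, n):
                gi, gj = geometries[i], geometries[j]
                if gi.intersects(gj) and gi.intersection(gj).length > 0:
                    rows += [i, j]
                    cols += [j, i]
        W = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return cls(ids=ids, W=W)


def lattice_adjacency(n_rows: int, n_cols: int, ids: Sequence | None = None) -> Adjacency:
    """Rook (edge-sharing) adjacency on an ``n_rows`` x ``n_cols`` grid.

    Areas are ordered row-major; ids default to ``A0000``, ``A0001``, ...
    """
    n = n_rows * n_cols
    if ids is None:
        ids = [f"A{i:04d}" for i in range(n)]
    rows, cols = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                rows += [i, i + 1]
                cols += [i + 1, i]
            if r + 1 < n_rows:
                j = i + n_cols
                rows += [i, j]
                cols += [j, i]
    W = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return Adjacency(ids=list(ids), W=W)


def build_adjacency(source, ids: Iterable | None = None) -> Adjacency:
    """Build an :class:`Adjacency` from a neighbor-list file, a mapping of
    neighbor lists, or a sequence of polygon geometries (with ``ids``)."""
    if isinstance(source, (str, Path)):
        return Adjacency.from_gal(source)
    if isinstance(source, Mapping):
        return Adjacency.from_neighbor_lists(source)
    if ids is None:
        raise ValueError("ids are required when building adjacency from geometries")
    return Adjacency.from_polygons(source, ids)
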