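"""Persistent homology of 3D masked scalar fields.

Network maps are high-intensity structures, so features are tracked under a
*superlevel-set* filtration: the threshold sweeps downward and a component or
loop is "born" at the intensity where it first appears and "dies" at the
intensity where it merges or fills in.  Internally this is implemented as the
sublevel filtration of the negated field; all births and deaths are reported
on the original intensity scale.

The complex is the 2-skeleton of the Freudenthal (Kuhn) triangulation of the
masked voxel lattice: vertices are masked voxels, edges join voxels whose
offset is a nonzero 0/1 vector, and triangles are monotone chains
v, v+d1, v+d1+d2 with d1, d2 nonzero 0/1 offsets of disjoint support.  Cells
touching an unmasked voxel are excluded.  Because attaching 3-cells cannot
change H0 or H1, the truncation at dimension 2 yields exact H0 and H1 for the
full triangulated region; H2 (hollows) is deliberately not computed.

Every finite diagram point carries the *critical voxels* that determine its
birth and death cell values, which is what makes the topological loss
differentiable with respect to voxel intensities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from numba.typed import List as NumbaList

from .volumes import VolumeGrid, flatten

__all__ = [
    "FilteredComplex",
    "PersistencePoint",
    "PersistenceDiagram",
    "build_complex",
    "persistence_diagram",
    "euler_characteristic",
]


# ---------------------------------------------------------------------------
# filtered complex construction

# The 7 edge offsets of the Freudenthal triangulation of Z^3.
_EDGE_DIRS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1),
    (1, 1, 1),
]

# Ordered pairs (d1, d2) of nonzero 0/1 offsets with disjoint support; the
# triangle is (v, v+d1, v+d1+d2).  12 per interior base voxel.
_TRI_DIRS = [
    (d1, d2)
    for d1 in _EDGE_DIRS
    for d2 in _EDGE_DIRS
    if all(a + b <= 1 for a, b in zip(d1, d2))
]


@dataclass
class FilteredComplex:
    """Value-independent combinatorics of the masked lattice triangulation.

    ``edges[i] = (a, b)`` and ``triangles[j] = (a, b, c)`` hold masked-vertex
    ids sorted by voxel linear index; ``tri_edges[j]`` are the ids of the
    three boundary edges of triangle j.  Filtration values are assigned per
    call: under the superlevel convention a cell's value is the *minimum*
    intensity over its vertices and the determining vertex attains it.
    """

    n_vertices: int
    edges: np.ndarray       # (ne, 2) int64
    triangles: np.ndarray   # (nt, 3) int64
    tri_edges: np.ndarray   # (nt, 3) int64 edge ids

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]


_COMPLEX_CACHE: dict = {}


def _vertex_ids(mask: np.ndarray) -> np.ndarray:
    """Full-grid array mapping voxel -> masked-vertex id (or -1)."""
    flat = mask.ravel(order="F")
    ids = np.full(flat.shape, -1, dtype=np.int64)
    ids[flat] = np.arange(int(flat.sum()), dtype=np.int64)
    return ids.reshape(mask.shape, order="F")


def _shifted(vid: np.ndarray, d, span) -> np.ndarray:
    nx, ny, nz = vid.shape
    sx, sy, sz = span
    return vid[d[0]:nx - sx + d[0], d[1]:ny - sy + d[1], d[2]:nz - sz + d[2]]


def build_complex(grid: VolumeGrid) -> FilteredComplex:
    """Freudenthal 2-skeleton of the masked voxel lattice (cached per mask)."""
    mask = grid.mask
    key = (mask.shape, mask.tobytes())
    cached = _COMPLEX_CACHE.get(key)
    if cached is not None:
        return cached
    if not mask.any():
        raise ValueError("empty mask")
    vid = _vertex_ids(mask)
    nv = int(mask.sum())

    edge_list = []
    for d in _EDGE_DIRS:
        a = _shifted(vid, (0, 0, 0), d)
        b = _shifted(vid, d, d)
        ok = (a >= 0) & (b >= 0)
        edge_list.append(np.stack([a[ok], b[ok]], axis=1))
    edges = np.concatenate(edge_list, axis=0) if edge_list else np.empty((0, 2), np.int64)
    # canonical edge order: sort by (a, b); vertex ids grow with linear index
    # and offsets are nonnegative, so a < b always holds.
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges = edges[order]
    edge_keys = edges[:, 0] * np.int64(nv) + edges[:, 1]

    tri_list = []
    for d1, d2 in _TRI_DIRS:
        span = tuple(a + b for a, b in zip(d1, d2))
        a = _shifted(vid, (0, 0, 0), span)
        b = _shifted(vid, d1, span)
        c = _shifted(vid, span, span)
        ok = (a >= 0) & (b >= 0) & (c >= 0)
        tri_list.append(np.stack([a[ok], b[ok], c[ok]], axis=1))
    triangles = (
        np.concatenate(tri_list, axis=0) if tri_list else np.empty((0, 3), np.int64)
    )
    if triangles.size:
        torder = np.lexsort((triangles[:, 2], triangles[:, 1], triangles[:, 0]))
        triangles = triangles[torder]
        face_keys = np.stack(
            [
                triangles[:, 0] * np.int64(nv) + triangles[:, 1],
                triangles[:, 1] * np.int64(nv) + triangles[:, 2],
                triangles[:, 0] * np.int64(nv) + triangles[:, 2],
            ],
            axis=1,
        )
        tri_edges = np.searchsorted(edge_keys, face_keys).astype(np.int64)
    else:
        tri_edges = np.empty((0, 3), np.int64)

    cx = FilteredComplex(nv, edges, triangles, tri_edges)
    _COMPLEX_CACHE[key] = cx
    return cx


# ---------------------------------------------------------------------------
# persistence diagrams


@dataclass(frozen=True)
class PersistencePoint:
    """One homological feature: born at ``birth``, destroyed at ``death``.

    Under the superlevel convention ``birth >= death``.  ``death_voxel`` is
    None for essential features (their death is pinned to the minimum masked
    intensity, the final filtration level, so the loss stays finite).
    """

    birth: float
    death: float
    dim: int
    birth_voxel: int
    death_voxel: Optional[int]

    @property
    def persistence(self) -> float:
        return abs(self.birth - self.death)


@dataclass
class PersistenceDiagram:
    """H0/H1 persistence of one map, stored as parallel arrays.

    ``death_voxels`` uses -1 for essential points.  ``filtration`` records the
    convention so diagrams from different conventions are never matched.
    """

    births: np.ndarray
    deaths: np.ndarray
    dims: np.ndarray
    birth_voxels: np.ndarray
    death_voxels: np.ndarray
    filtration: str = "superlevel"
    min_voxel: int = 0  # masked index of the global minimum (essential deaths)

    def __len__(self) -> int:
        return len(self.births)

    @property
    def points(self) -> list[PersistencePoint]:
        return [
            PersistencePoint(
                float(b), float(d), int(q), int(bv), None if dv < 0 else int(dv)
            )
            for b, d, q, bv, dv in zip(
                self.births, self.deaths, self.dims, self.birth_voxels, self.death_voxels
            )
        ]

    def _sel(self, dim: int) -> "PersistenceDiagram":
        m = self.dims == dim
        return PersistenceDiagram(
            self.births[m], self.deaths[m], self.dims[m],
            self.birth_voxels[m], self.death_voxels[m],
            self.filtration, self.min_voxel,
        )

    @property
    def H0(self) -> "PersistenceDiagram":
        return self._sel(0)

    @property
    def H1(self) -> "PersistenceDiagram":
        return self._sel(1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dim": self.dims,
                "birth": self.births,
                "death": self.deaths,
                "birth_voxel": self.birth_voxels,
                "death_voxel": self.death_voxels,
            }
        )


@njit(cache=True)
def _h0_union_find(rank_of_vertex, ea, eb, edge_order):
    """Sublevel union-find over edges in filtration order.

    Returns per-edge positivity flags and the (birth vertex, death edge)
    pairs, plus the birth vertex of every surviving (essential) component.
    The elder rule keeps the component whose birth vertex has the smaller
    rank (higher intensity; ties to lower voxel index).
    """
    nv = rank_of_vertex.shape[0]
    ne = edge_order.shape[0]
    parent = np.arange(nv)
    comp_birth = np.arange(nv)  # birth vertex of each root's component
    positive = np.zeros(ne, np.bool_)
    pair_birth_vertex = np.empty(ne, np.int64)
    pair_death_edge = np.empty(ne, np.int64)
    n_pairs = 0
    for i in range(ne):
        e = edge_order[i]
        # find with path compression
        ra = ea[e]
        while parent[ra] != ra:
            parent[ra] = parent[parent[ra]]
            ra = parent[ra]
        rb = eb[e]
        while parent[rb] != rb:
            parent[rb] = parent[parent[rb]]
            rb = parent[rb]
        if ra == rb:
            positive[e] = True
        else:
            if rank_of_vertex[comp_birth[ra]] < rank_of_vertex[comp_birth[rb]]:
                elder, young = ra, rb
            else:
                elder, young = rb, ra
            pair_birth_vertex[n_pairs] = comp_birth[young]
            pair_death_edge[n_pairs] = e
            n_pairs += 1
            parent[young] = elder
    # essential components
    ess = np.empty(nv, np.int64)
    n_ess = 0
    for v in range(nv):
        r = v
        while parent[r] != r:
            r = parent[r]
        if r == v:
            ess[n_ess] = comp_birth[v]
            n_ess += 1
    return (
        positive,
        pair_birth_vertex[:n_pairs],
        pair_death_edge[:n_pairs],
        ess[:n_ess],
    )


@njit(cache=True)
def _symdiff(a, b):
    """Symmetric difference of two sorted int64 arrays."""
    na, nb = a.shape[0], b.shape[0]
    out = np.empty(na + nb, np.int64)
    i = j = k = 0
    while i < na and j < nb:
        if a[i] < b[j]:
            out[k] = a[i]; i += 1; k += 1
        elif a[i] > b[j]:
            out[k] = b[j]; j += 1; k += 1
        else:
            i += 1; j += 1
    while i < na:
        out[k] = a[i]; i += 1; k += 1
    while j < nb:
        out[k] = b[j]; j += 1; k += 1
    return out[:k].copy()


@njit(cache=True)
def _reduce_d2(cols, n_edge_positions):
    """Standard column reduction of the triangle boundary matrix over GF(2).

    ``cols[t]`` holds the three boundary-edge *filtration positions* of the
    t-th triangle (triangles already in filtration order, each row sorted
    ascending).  Returns, per triangle, the pivot edge position it kills
    (-1 for positive triangles).
    """
    nt = cols.shape[0]
    pivot_owner = np.full(n_edge_positions, -1, np.int64)
    pair_pos = np.full(nt, -1, np.int64)
    stored = NumbaList()
    stored.append(np.empty(0, np.int64))
    stored.pop()
    for t in range(nt):
        col = cols[t].copy()
        while col.shape[0] > 0:
            piv = col[col.shape[0] - 1]
            o = pivot_owner[piv]
            if o == -1:
                pivot_owner[piv] = t
                pair_pos[t] = piv
                break
            col = _symdiff(col, stored[o])
        stored.append(col)
    return pair_pos


def persistence_diagram(
    grid: VolumeGrid, complex_: Optional[FilteredComplex] = None
) -> PersistenceDiagram:
    """H0/H1 superlevel persistence of a masked scalar field.

    Ties in intensity are resolved by voxel linear index (lower index enters
    the filtration first at a given level), which makes births, deaths and
    critical voxels deterministic.  Zero-persistence points are discarded.
    """
    if complex_ is None:
        complex_ = build_complex(grid)
    vals = grid.flat_values()
    if not np.isfinite(vals).all():
        raise ValueError("non-finite intensity inside the mask")
    nv = complex_.n_vertices
    if vals.shape[0] != nv:
        raise ValueError("grid does not match the complex")

    # total order: descending intensity, ties to lower voxel index
    order = np.lexsort((np.arange(nv), -vals))
    rank = np.empty(nv, dtype=np.int64)
    rank[order] = np.arange(nv)

    min_value = float(vals[order[-1]])
    # global minimum voxel, ties to lower index
    min_voxel = int(np.flatnonzero(vals == vals.min())[0])

    edges = complex_.edges
    ne = edges.shape[0]
    if ne:
        ra, rb = rank[edges[:, 0]], rank[edges[:, 1]]
        edge_rank = np.maximum(ra, rb)
        edge_det = np.where(ra >= rb, edges[:, 0], edges[:, 1])
        edge_order = np.lexsort((np.arange(ne), edge_rank))
    else:
        edge_rank = np.empty(0, np.int64)
        edge_det = np.empty(0, np.int64)
        edge_order = np.empty(0, np.int64)

    positive, h0_bv, h0_de, ess_bv = _h0_union_find(
        rank, edges[:, 0].copy(), edges[:, 1].copy(), edge_order
    )

    births, deaths, dims, bvox, dvox = [], [], [], [], []

    for v, e in zip(h0_bv, h0_de):
        b, d = float(vals[v]), float(vals[edge_det[e]])
        if b != d:
            births.append(b); deaths.append(d); dims.append(0)
            bvox.append(int(v)); dvox.append(int(edge_det[e]))
    for v in ess_bv:
        b = float(vals[v])
        if b != min_value:
            births.append(b); deaths.append(min_value); dims.append(0)
            bvox.append(int(v)); dvox.append(-1)

    # H1: reduce the triangle boundary matrix
    nt = complex_.n_triangles
    if nt:
        tris = complex_.triangles
        tr = np.maximum(np.maximum(rank[tris[:, 0]], rank[tris[:, 1]]), rank[tris[:, 2]])
        tri_det_all = tris[
            np.arange(nt),
            np.argmax(np.stack([rank[tris[:, 0]], rank[tris[:, 1]], rank[tris[:, 2]]], 0), axis=0),
        ]
        tri_order = np.lexsort((np.arange(nt), tr))
        edge_pos = np.empty(ne, dtype=np.int64)
        edge_pos[edge_order] = np.arange(ne)
        cols = np.sort(edge_pos[complex_.tri_edges[tri_order]], axis=1)
        pair_pos = _reduce_d2(cols, ne)
        killed = np.zeros(ne, dtype=bool)
        for t in range(nt):
            p = pair_pos[t]
            if p >= 0:
                e = edge_order[p]
                killed[e] = True
                b = float(vals[edge_det[e]])
                d = float(vals[tri_det_all[tri_order[t]]])
                if b != d:
                    births.append(b); deaths.append(d); dims.append(1)
                    bvox.append(int(edge_det[e])); dvox.append(int(tri_det_all[tri_order[t]]))
        # essential loops: positive edges never killed by a triangle
        for e in np.flatnonzero(positive & ~killed):
            b = float(vals[edge_det[e]])
            if b != min_value:
                births.append(b); deaths.append(min_value); dims.append(1)
                bvox.append(int(edge_det[e])); dvox.append(-1)
    elif ne:
        for e in np.flatnonzero(positive):
            b = float(vals[edge_det[e]])
            if b != min_value:
                births.append(b); deaths.append(min_value); dims.append(1)
                bvox.append(int(edge_det[e])); dvox.append(-1)

    return PersistenceDiagram(
        np.asarray(births, dtype=np.float64),
        np.asarray(deaths, dtype=np.float64),
        np.asarray(dims, dtype=np.int64),
        np.asarray(bvox, dtype=np.int64),
        np.asarray(dvox, dtype=np.int64),
        filtration="superlevel",
        min_voxel=min_voxel,
    )


# ---------------------------------------------------------------------------
# Euler characteristic of binarized maps


def euler_characteristic(grid: VolumeGrid, threshold: float = 0.0) -> int:
    """Euler characteristic chi = V - E + F - C of the thresholded map.

    Masked voxels with intensity strictly greater than ``threshold`` become
    the vertices of a cubical complex (edges between axis-neighbours, square
    faces for 2x2x1 blocks, cubes for 2x2x2 blocks).  By Euler-Poincare the
    alternating cell count equals components - holes + hollows, so hollows
    are accounted for even though H2 persistence is never computed.
    """
    on = (grid.data > threshold) & grid.mask
    return euler_characteristic_binary(on)


def euler_characteristic_binary(on: np.ndarray) -> int:
    """chi of a boolean 3D array under the vertex-cubical construction."""
    on = np.asarray(on, dtype=bool)
    nV = int(on.sum())
    nE = 0
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        nE += int((on[tuple(sl_a)] & on[tuple(sl_b)]).sum())
    nF = 0
    for ax in range(3):
        axes = [a for a in range(3) if a != ax]
        blk = on
        for a in axes:
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[a] = slice(0, -1)
            sl_b[a] = slice(1, None)
            blk = blk[tuple(sl_a)] & blk[tuple(sl_b)]
        nF += int(blk.sum())
    blk = on
    for a in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[a] = slice(0, -1)
        sl_b[a] = slice(1, None)
        blk = blk[tuple(sl_a)] & blk[tuple(sl_b)]
    nC = int(blk.sum())
    return nV - nE + nF - nC
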