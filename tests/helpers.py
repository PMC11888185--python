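"""Independent brute-force oracles for the test suite.

Everything here is deliberately written without reference to the package's
algorithms: cells are enumerated directly from voxel coordinates, persistence
comes from the textbook full boundary-matrix reduction over GF(2) (columns as
Python int bitmasks, no optimizations), and Betti numbers come from boundary
ranks.  These oracles are the ground truth the fast implementation is checked
against on small grids.
"""

from __future__ import annotations

import itertools

import numpy as np


def _linear_index(coord, shape):
    # x fastest (Fortran order), matching the package's documented order
    x, y, z = coord
    nx, ny, nz = shape
    return x + nx * (y + ny * z)


def _vertex_key(coord, data, shape):
    # superlevel total order: higher intensity first, ties to lower index
    return (-float(data[coord]), _linear_index(coord, shape))


def freudenthal_cells(mask: np.ndarray):
    """All vertices, edges and triangles of the Freudenthal 2-skeleton.

    Enumerated from first principles: edges are pairs whose offset is a
    nonzero 0/1 vector; triangles are monotone chains p, q, r with q - p,
    r - q nonzero 0/1 vectors and r - p still a 0/1 vector.
    """
    coords = [tuple(c) for c in np.argwhere(mask)]
    cset = set(coords)
    offsets = [
        o for o in itertools.product((0, 1), repeat=3) if any(o)
    ]
    edges = []
    for p in coords:
        for o in offsets:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            if q in cset:
                edges.append((p, q))
    triangles = []
    for p in coords:
        for o1 in offsets:
            q = (p[0] + o1[0], p[1] + o1[1], p[2] + o1[2])
            if q not in cset:
                continue
            for o2 in offsets:
                if any(a + b > 1 for a, b in zip(o1, o2)):
                    continue
                r = (q[0] + o2[0], q[1] + o2[1], q[2] + o2[2])
                if r in cset:
                    triangles.append((p, q, r))
    return coords, edges, triangles


def oracle_persistence(data: np.ndarray, mask: np.ndarray):
    """H0/H1 superlevel persistence by full boundary-matrix reduction.

    Returns a sorted list of (dim, birth, death) with zero-persistence pairs
    dropped; essential classes die at the minimum masked intensity.
    """
    shape = data.shape
    coords, edges, triangles = freudenthal_cells(mask)
    min_val = float(min(data[c] for c in coords))

    def cell_key(verts):
        return max(_vertex_key(v, data, shape) for v in verts)

    def cell_value(verts):
        return float(min(data[v] for v in verts))

    cells = (
        [(0, (v,)) for v in coords]
        + [(1, e) for e in edges]
        + [(2, t) for t in triangles]
    )
    # filtration order: by level key, then dimension (faces first), then verts
    cells.sort(key=lambda c: (cell_key(c[1]), c[0], c[1]))
    index_of = {}
    for i, (dim, verts) in enumerate(cells):
        index_of[frozenset(verts)] = i

    def boundary(dim, verts):
        if dim == 0:
            return 0
        col = 0
        for face in itertools.combinations(verts, dim):
            col |= 1 << index_of[frozenset(face)]
        return col

    n = len(cells)
    columns = [boundary(dim, verts) for dim, verts in cells]
    low_owner = {}
    pairs = []
    for j in range(n):
        col = columns[j]
        while col:
            low = col.bit_length() - 1
            if low not in low_owner:
                low_owner[low] = j
                pairs.append((low, j))
                break
            col ^= columns[low_owner[low]]
        columns[j] = col

    killed = {i for i, _ in pairs} | {j for _, j in pairs}
    out = []
    for i, j in pairs:
        dim, verts_i = cells[i]
        if dim > 1:
            continue
        birth = cell_value(verts_i)
        death = cell_value(cells[j][1])
        if birth != death:
            out.append((dim, birth, death))
    for i, (dim, verts) in enumerate(cells):
        if dim <= 1 and i not in killed:
            birth = cell_value(verts)
            if birth != min_val:
                out.append((dim, birth, min_val))
    return sorted(out)


def _gf2_rank(columns):
    """Rank of a GF(2) matrix given as a list of int bitmask columns."""
    rank = 0
    pivots = {}
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low not in pivots:
                pivots[low] = col
                rank += 1
                break
            col ^= pivots[low]
    return rank


def cubical_betti(binary: np.ndarray):
    """(b0, b1, b2, b3) of the vertex-cubical complex of a boolean volume.

    Voxels are vertices; edges join axis neighbours; squares and cubes come
    from fully-on 2x2x1 and 2x2x2 blocks.  Includes 3-cells so that
    b0 - b1 + b2 - b3 equals the alternating cell count.
    """
    on = {tuple(c) for c in np.argwhere(binary)}

    def block(p, dims):
        gens = [(0, 1) if d in dims else (0,) for d in range(3)]
        return tuple(
            (p[0] + a, p[1] + b, p[2] + c)
            for a, b, c in itertools.product(*gens)
        )

    cells = {0: [], 1: [], 2: [], 3: []}
    for p in on:
        cells[0].append((p,))
        for dims in [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]:
            verts = block(p, dims)
            if all(v in on for v in verts):
                cells[len(dims)].append(verts)

    index = [{frozenset(c): i for i, c in enumerate(cells[d])} for d in range(4)]

    def faces(verts, d):
        # faces of a d-block: fix one varying axis at each of its two values
        out = []
        arr = np.array(verts)
        varying = [ax for ax in range(3) if len(set(arr[:, ax])) > 1]
        for ax in varying:
            for val in sorted(set(arr[:, ax])):
                sub = tuple(sorted(tuple(v) for v in arr[arr[:, ax] == val]))
                out.append(frozenset(sub))
        return out

    ranks = [0, 0, 0, 0]
    for d in (1, 2, 3):
        cols = []
        for verts in cells[d]:
            col = 0
            for f in faces(verts, d):
                col |= 1 << index[d - 1][f]
            cols.append(col)
        ranks[d] = _gf2_rank(cols)

    n = [len(cells[d]) for d in range(4)]
    b0 = n[0] - ranks[1]
    b1 = n[1] - ranks[1] - ranks[2]
    b2 = n[2] - ranks[2] - ranks[3]
    b3 = n[3] - ranks[3]
    return b0, b1, b2, b3


def structured_fixtures():
    """Named small fixtures with known topology: blobs, rings, shells."""
    out = {}

    def grid(shape):
        return np.zeros(shape), np.ones(shape, dtype=bool)

    d, m = grid((5, 5, 3))
    d[2, 2, 1] = 5.0
    out["single_blob"] = (d, m)

    d, m = grid((7, 5, 3))
    d[1, 2, 1] = 5.0
    d[5, 2, 1] = 3.0
    out["two_blobs"] = (d, m)

    d, m = grid((5, 5, 3))
    d[1:4, 1:4, 1] = 4.0
    d[2, 2, 1] = 0.0
    out["planar_ring"] = (d, m)

    d, m = grid((5, 5, 5))
    d[1:4, 1:4, 1:4] = 1.0
    d[2, 2, 2] = 0.0
    out["hollow_shell"] = (d, m)

    d, m = grid((6, 6, 3))
    d[1:3, 1:3, 1] = 2.0
    d[3:5, 3:5, 1] = 1.0
    out["two_plateaus"] = (d, m)

    d, m = grid((4, 4, 4))
    d[:2, :2, :2] = 3.0
    d[2:, 2:, 2:] = 3.0
    out["diagonal_blocks"] = (d, m)

    d, m = grid((7, 7, 3))
    d[1:6, 1:6, 1] = 2.0
    d[2:5, 2:5, 1] = 0.0
    d[3, 3, 1] = 2.0
    out["ring_with_island"] = (d, m)

    d, m = grid((5, 5, 3))
    d[1:4, 1:4, 1] = 4.0
    d[2, 2, 1] = 1.0
    out["shallow_crater"] = (d, m)

    rng = np.random.default_rng(2024)
    d = rng.normal(size=(4, 4, 3))
    m = np.ones((4, 4, 3), dtype=bool)
    m[0, 0, 0] = False
    out["masked_random"] = (d, m)

    d, m = grid((5, 4, 3))
    d[1, 1, 1] = 3.0
    d[3, 1, 1] = 3.0
    d[2, 1, 1] = 1.0
    out["saddle_merge"] = (d, m)

    return out
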