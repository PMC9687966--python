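"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: volume and inclusion
go through an explicit tetrahedral decomposition, reachability through
breadth-first search, and per-slice displacement sums through a naive
double loop.
"""

import numpy as np


def tetra_decomposition(poly):
    """Tetrahedra (centroid + triangulated facets) covering the hull."""
    centroid = poly.vertex_points[np.unique(poly.facets)].mean(axis=0)
    return [
        np.vstack([centroid, poly.vertex_points[f]]) for f in poly.facets
    ]


def volume_by_tetrahedra(poly):
    """Hull volume (nm³) as a sum of signed tetrahedron volumes."""
    total = 0.0
    for tet in tetra_decomposition(poly):
        a, b, c, d = tet
        total += abs(np.linalg.det(np.array([b - a, c - a, d - a]))) / 6.0
    return total / 1000.0


def point_in_tetra(p, tet, tol=1e-9):
    """Barycentric inside-or-on test for one tetrahedron."""
    a, b, c, d = tet
    m = np.array([b - a, c - a, d - a]).T
    try:
        lam = np.linalg.solve(m, p - a)
    except np.linalg.LinAlgError:
        return False
    return (
        (lam >= -tol).all() and lam.sum() <= 1 + tol
    )


def point_in_hull_by_tetrahedra(p, poly, tol=1e-9):
    return any(point_in_tetra(np.asarray(p, float), tet, tol) for tet in tetra_decomposition(poly))


def bfs_connected(edges, a, b, nodes=()):
    """Breadth-first reachability on an undirected edge list."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if a not in adj or b not in adj:
        raise KeyError("unknown node")
    if a == b:
        return True
    seen, queue = {a}, [a]
    while queue:
        u = queue.pop()
        for v in adj[u]:
            if v == b:
                return True
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return False


def naive_slice_sums(positions, heights_fn, slice_of_fn, inside_fn, k):
    """Per-slice squared-displacement sums via an explicit double loop.

    ``positions``: (n_frames, n_w, 3); functions map a point to its slice /
    inside verdict.  Returns dicts slice -> (sum, count).
    """
    n_frames, n_w, _ = positions.shape
    sums, counts = {}, {}
    for t0 in range(n_frames - k):
        for w in range(n_w):
            p0 = positions[t0, w]
            if not inside_fn(p0):
                continue
            s = slice_of_fn(p0)
            d = positions[t0 + k, w] - p0
            sums[s] = sums.get(s, 0.0) + float(d @ d)
            counts[s] = counts.get(s, 0) + 1
    return sums, counts
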