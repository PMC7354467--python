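"""Internal geometric primitives shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import SurfaceMesh


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle for each query point (paired).

    ``points`` is (M, 3), ``tri`` is (M, 3, 3); returns (closest (M, 3),
    squared distance (M,)).  Vectorized version of the standard region
    classification (Ericson, Real-Time Collision Detection, ch. 5).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.sum(ab * ap, axis=1)
    d2 = np.sum(ac * ap, axis=1)
    bp = points - b
    d3 = np.sum(ab * bp, axis=1)
    d4 = np.sum(ac * bp, axis=1)
    cp = points - c
    d5 = np.sum(ab * cp, axis=1)
    d6 = np.sum(ac * cp, axis=1)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                       # vertex A
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)              # vertex B
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)              # vertex C
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)   # edge AB
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)   # edge AC
    with np.errstate(invalid="ignore", divide="ignore"):
        wv = d2 / (d2 - d6)
    out[m] = a[m] + wv[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    with np.errstate(invalid="ignore", divide="ignore"):
        wv = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + wv[m, None] * (c[m] - b[m])
    done |= m

    m = ~done                                        # interior
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        v = vb / denom
        wv = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + wv[m, None] * ac[m]
    d2_ = np.sum((points - out) ** 2, axis=1)
    return out, d2_


def ray_mesh_first_hit(
    mesh: SurfaceMesh,
    origins: np.ndarray,
    directions: np.ndarray,
    max_dist: float | np.ndarray,
    k_candidates: int = 8,
    n_probes: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """First intersection distance of rays with a mesh (Moller-Trumbore).

    Candidate faces are gathered from the ``k_candidates`` nearest face
    centroids at ``n_probes`` points spaced along each ray up to its
    ``max_dist``; exact whenever the hit face's centroid is near some
    probe, which holds when ``max_dist`` probes at steps comparable to
    the face size.  Returns ``(distance, hit_mask)``; missed rays carry
    NaN distance.
    """
    origins = np.asarray(origins, dtype=np.float64)
    directions = np.asarray(directions, dtype=np.float64)
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    max_dist = np.broadcast_to(np.asarray(max_dist, dtype=np.float64), (len(origins),))
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    tree = cKDTree(centroids)
    k = min(k_candidates, len(centroids))
    M = len(origins)
    steps = np.linspace(0.0, 1.0, n_probes)
    cand = np.empty((M, n_probes * k), dtype=np.int64)
    for j, frac in enumerate(steps):
        probe = origins + (frac * max_dist)[:, None] * directions
        _, idx = tree.query(probe, k=k)
        cand[:, j * k : (j + 1) * k] = np.atleast_2d(idx)

    nc = cand.shape[1]
    a = tri[cand, 0]                                  # (M, nc, 3)
    e1 = tri[cand, 1] - a
    e2 = tri[cand, 2] - a
    d = directions[:, None, :]
    o = origins[:, None, :]
    h = np.cross(d, e2)
    det = np.sum(e1 * h, axis=2)
    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(np.abs(det) > eps, 1.0 / det, np.nan)
        s = o - a
        u = f * np.sum(s * h, axis=2)
        q = np.cross(s, e1)
        v = f * np.sum(d * q, axis=2)
        t = f * np.sum(e2 * q, axis=2)
    tol = 1e-9
    valid = (
        np.isfinite(t)
        & (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol)
        & (t > 1e-9) & (t <= max_dist[:, None] + tol)
    )
    t = np.where(valid, t, np.inf)
    best = t.min(axis=1)
    hit = np.isfinite(best)
    return np.where(hit, best, np.nan), hit


def closest_point_on_mesh(
    mesh: SurfaceMesh, points: np.ndarray, k_candidates: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest surface point per query, via candidate faces.

    Candidates are the ``k_candidates`` faces with nearest centroids (k-d
    tree); the exact point-triangle minimum is taken over them.  Exact
    whenever the true foot's face is among the candidates, which holds for
    queries within a few edge lengths of the surface.  Returns
    ``(feet, distances)``.
    """
    points = np.asarray(points, dtype=np.float64)
    tri_all = mesh.vertices[mesh.faces]           # (F, 3, 3)
    centroids = tri_all.mean(axis=1)
    k = min(k_candidates, len(centroids))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)                    # (M, k)
    M = len(points)
    flat_pts = np.repeat(points, k, axis=0)       # (M*k, 3)
    flat_tri = tri_all[cand.ravel()]              # (M*k, 3, 3)
    feet_all, d2_all = closest_point_on_triangles(flat_pts, flat_tri)
    d2_all = d2_all.reshape(M, k)
    best = np.argmin(d2_all, axis=1)
    feet = feet_all.reshape(M, k, 3)[np.arange(M), best]
    return feet, np.sqrt(d2_all[np.arange(M), best])
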