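"""Systolic wall strain from paired diastole/systole surfaces.

The diastolic surface is the baseline configuration.  Each diastolic
sample point is projected along its outward surface normal onto the
systolic surface; the first-intersection distance is the displacement.
Points whose ray misses (or overshoots a cutoff of three local radii)
fall back to the unsigned closest-point distance, and the number of
fallbacks is reported.  Strain is the dimensionless ratio of that
displacement to the local baseline radius — the distance from the
diastolic point to the vessel centerline — i.e. a radial delta-r over r.

Both phases are assumed to share one frame (CT phases are reconstructed
in the same scanner coordinates), so no alignment is applied between them.

The centerline itself is extracted from the tube geometry: a harmonic
scalar field solved between the two boundary rings provides a
curvature-robust axial coordinate; cross-section centroids of its
iso-bands, refined by perpendicular re-binning and smoothed with a cubic
spline, give the centerline polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, TopologyError
from .mesh_io import SurfaceMesh
from .sampling import PointCloud

#: below this baseline radius (mm) a point's strain is flagged invalid
RADIUS_FLOOR = 0.1
#: ray-length cutoff as a multiple of the local baseline radius
DEFAULT_CUTOFF_FACTOR = 3.0


@dataclass
class Centerline:
    """Ordered 3D polyline (mm) with cumulative arc length."""

    points: np.ndarray           # (k, 3)
    arc_length: np.ndarray = field(default=None)  # (k,) cumulative, mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_length = np.asarray(self.arc_length, dtype=np.float64)
        if len(self.points) >= 2 and np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc length must be strictly increasing (repeated points?)")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def fractions(self) -> np.ndarray:
        return self.arc_length / self.length if self.length > 0 else self.arc_length

    def point_at(self, fraction: float) -> np.ndarray:
        """Point at an arc-length fraction in [0, 1] (linear interpolation)."""
        s = np.clip(fraction, 0.0, 1.0) * self.length
        i = np.clip(np.searchsorted(self.arc_length, s) - 1, 0, len(self.points) - 2)
        t = (s - self.arc_length[i]) / (self.arc_length[i + 1] - self.arc_length[i])
        return (1 - t) * self.points[i] + t * self.points[i + 1]

    def tangent_at(self, fraction: float) -> np.ndarray:
        s = np.clip(fraction, 0.0, 1.0) * self.length
        i = np.clip(np.searchsorted(self.arc_length, s) - 1, 0, len(self.points) - 2)
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)

    def resample(self, n: int) -> "Centerline":
        fr = np.linspace(0.0, 1.0, n)
        return Centerline(np.array([self.point_at(f) for f in fr]))


@dataclass
class StrainField:
    """Per-point systolic strain on the diastolic surface."""

    points: np.ndarray          # (N, 3) diastolic sample points
    displacement: np.ndarray    # (N,) mm
    radius: np.ndarray          # (N,) local baseline radius, mm
    strain: np.ndarray          # (N,) dimensionless
    station: np.ndarray         # (N,) arc-length fraction of nearest centerline point
    valid: np.ndarray           # (N,) bool; False where radius < floor
    n_fallback: int = 0         # points where the normal ray missed


@dataclass
class StationSummary:
    mean: float
    peak: float
    n_points: int


# ---------------------------------------------------------------------------
# Centerline extraction
# ---------------------------------------------------------------------------

def boundary_loops(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Vertex loops of the mesh boundary (edges used by exactly one face)."""
    edges = np.sort(
        np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]),
        axis=1,
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border = uniq[counts == 1]
    if len(border) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in border:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    loops = []
    seen: set[int] = set()
    for start in adj:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = [v for v in adj[cur] if v != prev and v not in seen]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            loop.append(cur)
            seen.add(cur)
        loops.append(np.asarray(loop))
    return loops


def _harmonic_axial_field(mesh: SurfaceMesh, ring_a: np.ndarray, ring_b: np.ndarray) -> np.ndarray:
    """Solve Laplace(u)=0 on the vertex graph with u=0 on ring_a, 1 on ring_b."""
    n = mesh.n_vertices
    edges = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    # symmetrized uniform-weight graph Laplacian
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    A = sparse.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    A.data[:] = 1.0  # collapse duplicate edges
    L = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A

    fixed = np.concatenate([ring_a, ring_b])
    values = np.concatenate([np.zeros(len(ring_a)), np.ones(len(ring_b))])
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    u[fixed] = values
    rhs = -L[free][:, fixed] @ values
    u[free] = sparse.linalg.spsolve(L[free][:, free].tocsc(), rhs)
    return u


def extract_centerline(mesh: SurfaceMesh, n_stations: int = 50, n_refine: int = 2) -> Centerline:
    """Centerline of an open tubular mesh (two boundary rings required).

    Vertices are first binned by a boundary-to-boundary harmonic field
    (iso-bands approximate perpendicular cross-sections even on curved
    tubes); bin centroids are refined by re-binning along the current
    centerline and smoothed with a cubic spline.  Endpoints are pinned to
    the boundary-ring centroids.
    """
    loops = boundary_loops(mesh)
    if len(loops) != 2:
        raise TopologyError(
            f"expected an open tube with exactly 2 boundary rings, found {len(loops)}"
        )
    ring_a, ring_b = loops
    end_a = mesh.vertices[ring_a].mean(axis=0)
    end_b = mesh.vertices[ring_b].mean(axis=0)

    u = _harmonic_axial_field(mesh, ring_a, ring_b)
    centers = _kernel_centroids(mesh.vertices, u, n_stations)
    centers = np.vstack([end_a, centers, end_b])
    return Centerline(_spline_smooth(centers, n_stations))


def _kernel_centroids(vertices: np.ndarray, param: np.ndarray, n_stations: int) -> np.ndarray:
    """Gaussian-kernel-weighted vertex centroids at evenly spaced parameter
    levels.  Soft weighting avoids hard bin edges slicing through a vertex
    ring (which would pull the centroid off-axis)."""
    lo, hi = param.min(), param.max()
    p = (param - lo) / max(hi - lo, 1e-12)
    levels = np.linspace(0.0, 1.0, n_stations + 2)[1:-1]
    h = 1.0 / (n_stations + 1)
    w = np.exp(-0.5 * ((p[None, :] - levels[:, None]) / h) ** 2)  # (stations, verts)
    w /= w.sum(axis=1, keepdims=True)
    return w @ vertices


def _projection_parameter(vertices: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Continuous arc-length fraction of each vertex's nearest point on the
    current centerline polyline."""
    fine = Centerline(centers).resample(max(8 * len(centers), 400))
    _, idx = cKDTree(fine.points).query(vertices)
    return fine.fractions[idx]


def _spline_smooth(centers: np.ndarray, n_out: int) -> np.ndarray:
    # drop consecutive duplicates before parametrizing
    keep = np.concatenate([[True], np.linalg.norm(np.diff(centers, axis=0), axis=1) > 1e-9])
    centers = centers[keep]
    if len(centers) < 4:
        return centers
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    scale = seg.sum()
    tck, _ = splprep(centers.T, s=len(centers) * (1e-3 * scale) ** 2, k=3)
    pts = np.array(splev(np.linspace(0, 1, max(n_out, 10)), tck)).T
    return pts


# ---------------------------------------------------------------------------
# Displacement and strain
# ---------------------------------------------------------------------------

def displacement_field(
    diastole: PointCloud,
    systole: SurfaceMesh,
    cutoff_factor: float = DEFAULT_CUTOFF_FACTOR,
    local_radius: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point diastole -> systole displacement magnitude (mm).

    Primary branch: cast a ray from each diastolic point along its outward
    normal; displacement is the distance to the first systolic
    intersection.  Fallback branch (ray misses, or the hit exceeds
    ``cutoff_factor`` local radii when ``local_radius`` is given): unsigned
    closest-point distance to the systolic surface.

    Returns ``(displacement, fallback_mask)``.
    """
    systole.validate()
    if diastole.normals is None:
        raise ValueError(
            "diastolic cloud carries no normals; sample it with resample_surface "
            "or attach normals explicitly"
        )
    from ._geometry import closest_point_on_mesh, ray_mesh_first_hit

    origins = diastole.points
    directions = diastole.normals / np.linalg.norm(diastole.normals, axis=1, keepdims=True)
    if local_radius is not None:
        cutoff = cutoff_factor * np.asarray(local_radius, dtype=np.float64)
    else:
        cutoff = np.full(
            diastole.n_points, 0.5 * float(np.linalg.norm(np.ptp(systole.vertices, axis=0)))
        )
    # nudge origins backwards so rays starting exactly on the surface still hit
    eps = 1e-6 * max(float(np.ptp(origins)), 1.0)
    t, hit = ray_mesh_first_hit(systole, origins - eps * directions, directions, cutoff + eps)
    disp = np.where(hit, t - eps, np.nan)
    fallback = ~hit
    if fallback.any():
        _, dist = closest_point_on_mesh(systole, origins[fallback])
        disp[fallback] = dist
    return disp, fallback


def strain_field(
    displacements: np.ndarray,
    centerline: Centerline | np.ndarray,
    diastole: PointCloud,
    radius_floor: float = RADIUS_FLOOR,
    n_fallback: int = 0,
) -> StrainField:
    """Dimensionless strain = displacement / local baseline radius.

    The local radius of a diastolic point is its distance to the nearest
    centerline point.  A degenerate "centerline" of a single point (e.g. a
    sphere centre) is accepted; all stations are then reported as 0.
    Points with radius below ``radius_floor`` are flagged invalid and
    excluded from summaries.
    """
    displacements = np.asarray(displacements, dtype=np.float64)
    if isinstance(centerline, Centerline):
        fine = centerline.resample(max(8 * len(centerline.points), 200))
        cpts, fractions = fine.points, fine.fractions
    else:
        cpts = np.atleast_2d(np.asarray(centerline, dtype=np.float64))
        fractions = np.zeros(len(cpts)) if len(cpts) == 1 else Centerline(cpts).fractions
    dist, idx = cKDTree(cpts).query(diastole.points)
    valid = dist >= radius_floor
    strain = np.where(valid, displacements / np.maximum(dist, radius_floor), np.nan)
    return StrainField(
        points=diastole.points,
        displacement=displacements,
        radius=dist,
        strain=strain,
        station=fractions[idx],
        valid=valid & np.isfinite(strain),
        n_fallback=int(n_fallback),
    )


def compute_strain(
    diastole: PointCloud,
    systole: SurfaceMesh,
    centerline: Centerline | np.ndarray,
    cutoff_factor: float = DEFAULT_CUTOFF_FACTOR,
) -> StrainField:
    """Full per-point strain pipeline for one phase pair."""
    if isinstance(centerline, Centerline):
        cpts = centerline.resample(max(4 * len(centerline.points), 100)).points
    else:
        cpts = np.atleast_2d(np.asarray(centerline))
    r, _ = cKDTree(cpts).query(diastole.points)
    disp, fallback = displacement_field(
        diastole, systole, cutoff_factor=cutoff_factor, local_radius=r
    )
    return strain_field(
        disp, centerline, diastole, n_fallback=int(fallback.sum())
    )


def strain_at_station(field_: StrainField, window: tuple[float, float]) -> StationSummary:
    """Mean and peak strain over points whose station lies in ``window``."""
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"window must satisfy 0 <= lo < hi <= 1, got {window}")
    m = field_.valid & (field_.station >= lo) & (field_.station <= hi)
    if not m.any():
        raise DegenerateInputError(f"no valid strain points in window {window}")
    return StationSummary(
        mean=float(np.mean(field_.strain[m])),
        peak=float(np.max(field_.strain[m])),
        n_points=int(m.sum()),
    )
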