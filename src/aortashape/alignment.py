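"""Rigid alignment, unbiased template construction, and point correspondence.

The atlas pipeline aligns every subject cloud to a common frame with rigid
(translation + rotation, never scaling) iterative-closest-point
registration, so that size variation is retained and can emerge as the
dominant shape mode.  The template starts from the subject closest to the
population-mean mid-ascending diameter, then is debiased by iterating
align → correspond → average until the mean shape stops moving.

Correspondence for PCA is established by closest-point projection from the
template onto each aligned subject: for every template point the nearest
subject sample is taken as its correspondent.  This is the minimal
correspondence scheme for unlabelled clouds; no non-rigid warp is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .mesh_io import CohortTable
from .sampling import PointCloud

DEFAULT_MAX_ROUNDS = 10
DEFAULT_ICP_MAX_ITER = 500
DEFAULT_ICP_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation, mm)."""

    rotation: np.ndarray   # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError(
                f"rotation must be proper orthogonal (det=+1), det={np.linalg.det(self.rotation)}"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class ICPResult:
    transform: RigidTransform
    aligned: PointCloud
    rmsd: float
    n_iterations: int
    converged: bool
    rmsd_history: list[float] = field(default_factory=list, repr=False)


@dataclass
class Template:
    """Population mean shape with its build history."""

    points: np.ndarray  # (N, 3)
    iteration_count: int
    converged: bool
    history: list[float] = field(default_factory=list, repr=False)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired ``source`` onto ``target``.

    SVD solution of the orthogonal Procrustes problem, with the determinant
    correction that excludes reflections.
    """
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


def _check_nondegenerate(points: np.ndarray, label: str) -> None:
    if points.shape[0] < 3:
        raise DegenerateInputError(f"{label} cloud has {points.shape[0]} points; need >= 3")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateInputError(f"{label} cloud is collinear (rank < 2)")


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Right-handed principal axes with signs fixed by third central moments."""
    centered = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axes = Vt.copy()
    for i in range(3):
        skew = np.mean((centered @ axes[i]) ** 3)
        if skew < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def _initial_transforms(source: np.ndarray, target: np.ndarray) -> list[RigidTransform]:
    """Candidate starts: centroids superposed, principal axes pre-aligned.

    Near-symmetric anatomies (a curved tube is almost invariant under an
    end-to-end flip) make any single axis-sign choice unreliable, so all
    four proper sign combinations are returned and ICP keeps the best.
    """
    As, At = _principal_axes(source), _principal_axes(target)
    ct, cs = target.mean(axis=0), source.mean(axis=0)
    candidates = []
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = At.T @ np.diag(signs) @ As
        candidates.append(RigidTransform(R, ct - R @ cs))
    return candidates


def _icp_loop(source_pts, tree, target_pts, transform, max_iter, tol):
    moved = transform.apply(source_pts)
    d, idx = tree.query(moved)
    rmsd = float(np.sqrt(np.mean(d**2)))
    history = [rmsd]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        step = kabsch(moved, target_pts[idx])
        transform = step.compose(transform)
        moved = transform.apply(source_pts)
        d, idx = tree.query(moved)
        new_rmsd = float(np.sqrt(np.mean(d**2)))
        history.append(new_rmsd)
        if rmsd - new_rmsd < tol:
            rmsd = new_rmsd
            converged = True
            break
        rmsd = new_rmsd
    return transform, rmsd, n_iter, converged, history


def icp_rigid(
    source: PointCloud,
    target: PointCloud,
    max_iter: int = DEFAULT_ICP_MAX_ITER,
    tol: float = DEFAULT_ICP_TOL,
    init: str | RigidTransform = "auto",
) -> ICPResult:
    """Rigidly register ``source`` onto ``target`` by iterative closest point.

    Alternates k-d-tree closest-point matching with a Kabsch rigid fit until
    the RMSD improvement falls below ``tol`` (mm) or ``max_iter`` is hit.
    The matching RMSD is non-increasing across iterations.  Non-convergence
    is flagged on the result, not raised.

    ``init="auto"`` multi-starts from the four proper principal-axis
    alignments and keeps the lowest-RMSD convergent; ``init="identity"``
    (for already-roughly-aligned clouds) or an explicit
    :class:`RigidTransform` skips the multi-start.
    """
    _check_nondegenerate(source.points, "source")
    _check_nondegenerate(target.points, "target")
    tree = cKDTree(target.points)

    if isinstance(init, RigidTransform):
        starts = [init]
    elif init == "identity":
        starts = [RigidTransform.identity()]
    elif init == "auto":
        starts = _initial_transforms(source.points, target.points)
    else:
        raise ValueError(f"unknown init {init!r}")

    if len(starts) > 1:
        # coarse pass per candidate, then refine only the winner
        coarse = [
            _icp_loop(source.points, tree, target.points, s, min(40, max_iter), max(tol, 1e-5))
            for s in starts
        ]
        start = coarse[int(np.argmin([c[1] for c in coarse]))][0]
    else:
        start = starts[0]
    transform, rmsd, n_iter, converged, history = _icp_loop(
        source.points, tree, target.points, start, max_iter, tol
    )
    aligned = source.transformed(transform.rotation, transform.translation)
    return ICPResult(transform, aligned, rmsd, n_iter, converged, history)


@dataclass
class TubeFrameLandmarks:
    """Ordered anatomical landmarks of a tubular mesh.

    ``centers`` are cross-section centroids at stations spaced a fixed
    arc-length step apart, centred on the arc midpoint (``offsets`` holds
    the signed arc-length offset of each station, in mm — wall dilatation
    shifts the tube's cut ends axially and so stretches any
    fraction-of-length grid, while the interior geometry at a given
    distance from the midpoint is unchanged); ``axis_tips`` sit a fixed
    offset along the cross-section ellipse major axis (sign-continuous
    along the tube), pinning the roll angle; ``good`` flags stations whose
    ellipse moment gap makes the axis direction reliable; ``radii`` is the
    mean wall distance per station, whose profile decides end-to-end
    orientation.
    """

    centers: np.ndarray     # (M, 3)
    axis_tips: np.ndarray   # (M, 3)
    good: np.ndarray        # (M,) bool
    radii: np.ndarray       # (M,)
    offsets: np.ndarray     # (M,) signed arc-length from the midpoint, mm

    def reversed(self) -> "TubeFrameLandmarks":
        return TubeFrameLandmarks(
            self.centers[::-1].copy(), self.axis_tips[::-1].copy(),
            self.good[::-1].copy(), self.radii[::-1].copy(),
            -self.offsets[::-1].copy(),
        )


def tube_frame_landmarks(
    mesh,
    station_spacing: float = 3.0,
    tip_length: float = 6.0,
    min_axis_gap: float = 0.05,
    span_fraction: float = 0.42,
) -> TubeFrameLandmarks:
    """Arc-length-ordered landmarks for rigid registration of tubes.

    Closest-point criteria cannot pin the pose of a tube inside a wider or
    narrower template — the cost is nearly flat as the tube slides along
    the curved channel.  Arc-length parametrization restores point
    identity: the centerline fixes five degrees of freedom, and the
    cross-section ellipse major axis (real aortic sections are mildly
    oval) fixes the roll.  Stations are laid out every
    ``station_spacing`` mm from the arc midpoint out to
    ``span_fraction`` of the tube length on either side.
    """
    from .strain import extract_centerline

    cl = extract_centerline(mesh, n_stations=50)
    fine = cl.resample(400)
    dist, idx = cKDTree(fine.points).query(mesh.vertices)
    s = fine.fractions[idx]
    n_side = int(np.floor(span_fraction * cl.length / station_spacing))
    offsets = np.arange(-n_side, n_side + 1) * station_spacing
    stations = 0.5 + offsets / cl.length
    n_stations = len(stations)
    half = 0.55 * station_spacing / cl.length
    centers = np.array([cl.point_at(f) for f in stations])
    tangents = np.array([cl.tangent_at(f) for f in stations])
    axes = np.zeros((n_stations, 3))
    good = np.zeros(n_stations, dtype=bool)
    radii = np.zeros(n_stations)
    for j, (sj, c, t) in enumerate(zip(stations, centers, tangents)):
        band = np.abs(s - sj) <= half
        if band.sum() < 8:
            continue
        v = mesh.vertices[band] - c
        v_perp = v - np.outer(v @ t, t)
        radii[j] = float(np.linalg.norm(v_perp, axis=1).mean())
        M = v_perp.T @ v_perp / band.sum()
        evals, evecs = np.linalg.eigh(M)
        # largest two in-plane moments; eigh sorts ascending
        gap = (evals[2] - evals[1]) / max(evals[2], 1e-12)
        axes[j] = evecs[:, 2] - (evecs[:, 2] @ t) * t
        norm = np.linalg.norm(axes[j])
        if norm > 1e-9 and gap >= min_axis_gap:
            axes[j] /= norm
            good[j] = True
    # sign continuity of the major axis along the tube
    prev = None
    for j in range(n_stations):
        if not good[j]:
            continue
        if prev is not None and axes[j] @ axes[prev] < 0:
            axes[j] = -axes[j]
        prev = j
    return TubeFrameLandmarks(centers, centers + tip_length * axes, good, radii, offsets)


def tube_frame_pose(
    source: TubeFrameLandmarks,
    target: TubeFrameLandmarks,
    max_axis_dev_deg: float = 25.0,
) -> RigidTransform:
    """Rigid pose mapping ``source`` landmarks onto ``target``.

    End-to-end orientation is decided by the radius-profile correlation.
    A centers-only Kabsch pre-fit pins everything but the roll; the
    ellipse-axis tips are then brought in station by station — each with
    the sign that matches the target and only where the residual axis
    deviation stays below ``max_axis_dev_deg`` (major/minor swaps on
    nearly circular or strongly ovalized sections show up as ~90 degree
    outliers) — and the pose is re-fit on centers plus surviving tips.
    """
    # match stations by absolute arc-length offset from the midpoint
    def _paired(src_lm: TubeFrameLandmarks):
        _, i_s, i_t = np.intersect1d(
            np.round(src_lm.offsets, 6), np.round(target.offsets, 6), return_indices=True
        )
        return i_s, i_t

    i_s, i_t = _paired(source)
    rs = source.radii[i_s] - source.radii[i_s].mean()
    rt = target.radii[i_t] - target.radii[i_t].mean()
    rev = source.reversed()
    i_sr, i_tr = _paired(rev)
    rsr = rev.radii[i_sr] - rev.radii[i_sr].mean()
    rtr = target.radii[i_tr] - target.radii[i_tr].mean()
    if float(rs @ rt) < float(rsr @ rtr):
        source, i_s, i_t = rev, i_sr, i_tr
    T0 = kabsch(source.centers[i_s], target.centers[i_t])

    cos_max = np.cos(np.radians(max_axis_dev_deg))
    src_tips, dst_tips = [], []
    for js, jt in zip(i_s, i_t):
        if not (source.good[js] and target.good[jt]):
            continue
        a_s = T0.rotation @ (source.axis_tips[js] - source.centers[js])
        a_t = target.axis_tips[jt] - target.centers[jt]
        c = float(a_s @ a_t) / (np.linalg.norm(a_s) * np.linalg.norm(a_t))
        if abs(c) >= cos_max:
            sign = 1.0 if c >= 0 else -1.0
            src_tips.append(source.centers[js] + sign * (source.axis_tips[js] - source.centers[js]))
            dst_tips.append(target.axis_tips[jt])
    if not src_tips:
        return T0
    src = np.vstack([source.centers[i_s], np.asarray(src_tips)])
    dst = np.vstack([target.centers[i_t], np.asarray(dst_tips)])
    return kabsch(src, dst)


def centerline_guided_init(
    source_centerline: np.ndarray,
    source_radii: np.ndarray,
    target_centerline: np.ndarray,
    target_radii: np.ndarray,
    n_samples: int = 50,
) -> RigidTransform:
    """Rigid ICP initialization from vessel centerlines and radius profiles.

    A curved tube is nearly symmetric under an end-to-end flip, and on
    strongly deformed subjects point-cloud ICP can fall into the flipped
    basin.  The centerline is invariant to radial dilatation, and the
    radius profile along it (sinus bulge proximally, taper distally) is a
    pose-invariant signature of which end is which: the profile
    correlation decides the orientation, and arc-length-matched centerline
    samples give a Kabsch fit that lands ICP in the correct basin.

    ``source_radii``/``target_radii`` are local radius profiles sampled at
    evenly spaced arc-length fractions (any common length >= 4).
    """
    from .strain import Centerline

    cs = Centerline(np.asarray(source_centerline))
    ct = Centerline(np.asarray(target_centerline))
    rs = np.asarray(source_radii, dtype=np.float64)
    rt = np.asarray(target_radii, dtype=np.float64)
    if len(rs) != len(rt) or len(rs) < 4:
        raise ValueError("radius profiles must share a common length >= 4")
    rs_c, rt_c = rs - rs.mean(), rt - rt.mean()
    fwd = float(rs_c @ rt_c)
    rev = float(rs_c[::-1] @ rt_c)
    fractions = np.linspace(0.0, 1.0, n_samples)
    src = np.array([cs.point_at(f) for f in (fractions if fwd >= rev else 1.0 - fractions)])
    tgt = np.array([ct.point_at(f) for f in fractions])
    return kabsch(src, tgt)


def select_initial_reference(cohort: CohortTable) -> str:
    """Subject whose mid-ascending diameter is closest to the population mean.

    Ties are broken lexicographically on subject_id.
    """
    col = cohort.column("diameter_midaa")
    missing = col.index[col.isna()].tolist()
    if missing:
        raise ValueError(f"diameter_midaa missing for subjects {missing}")
    dev = (col - col.mean()).abs()
    best = dev[dev == dev.min()].index.tolist()
    return sorted(best)[0]


def correspond(
    template_points: np.ndarray,
    aligned_subject: PointCloud | np.ndarray,
    refine: str = "nearest",
    k_patch: int = 12,
) -> np.ndarray:
    """Closest-point correspondence from the template onto a subject cloud.

    For each template point the closest subject point is found (Euclidean,
    k-d tree); a subject point may serve several template points; the
    output order matches the template order.

    ``refine`` selects sub-sample refinements: ``"nearest"`` (default,
    the raw closest sample) can be replaced by the foot point of a local
    surface patch fitted through the ``k_patch`` nearest subject samples —
    ``"plane"`` (first-order patch, removes the half-spacing quantization
    noise at the cost of a small curvature-smoothing bias) or
    ``"quadric"`` (second-order patch, unbiased on curved walls but
    noisier per foot).  The subject must already be
    rigidly aligned to the template frame.
    """
    pts = aligned_subject.points if isinstance(aligned_subject, PointCloud) else np.asarray(aligned_subject)
    template_points = np.asarray(template_points)
    tree = cKDTree(pts)
    if refine == "nearest":
        _, idx = tree.query(template_points)
        return pts[idx]
    if refine not in ("plane", "quadric"):
        raise ValueError(f"unknown refine mode {refine!r}")
    k = min(k_patch, len(pts))
    # two passes: re-anchor the patch at the current foot estimate, since
    # the nearest samples of a far-away probe may sit off to one side
    feet = template_points
    for _ in range(2):
        _, knn = tree.query(feet, k=k)
        neigh = pts[knn]                               # (N, k, 3)
        centroid = neigh.mean(axis=1)                  # (N, 3)
        centered = neigh - centroid[:, None, :]
        U_, S_, Vt = np.linalg.svd(centered, full_matrices=False)
        normals = Vt[:, 2, :]                          # (N, 3)
        delta = template_points - centroid
        h = np.sum(delta * normals, axis=1)
        if refine == "plane":
            feet = template_points - h[:, None] * normals
            continue
        # quadric height field over the tangent frame (e_u, e_v, n)
        e_u, e_v = Vt[:, 0, :], Vt[:, 1, :]
        u = np.einsum("nkj,nj->nk", centered, e_u)
        v = np.einsum("nkj,nj->nk", centered, e_v)
        w_ = np.einsum("nkj,nj->nk", centered, normals)
        A = np.stack([np.ones_like(u), u, v, u * u, u * v, v * v], axis=2)  # (N, k, 6)
        AtA = np.einsum("nki,nkj->nij", A, A)
        Atw = np.einsum("nki,nk->ni", A, w_)
        AtA += 1e-9 * np.eye(6)[None, :, :]
        coef = np.linalg.solve(AtA, Atw[..., None])[..., 0]  # (N, 6)
        u0 = np.sum(delta * e_u, axis=1)
        v0 = np.sum(delta * e_v, axis=1)
        h0 = (
            coef[:, 0] + coef[:, 1] * u0 + coef[:, 2] * v0
            + coef[:, 3] * u0 * u0 + coef[:, 4] * u0 * v0 + coef[:, 5] * v0 * v0
        )
        feet = centroid + u0[:, None] * e_u + v0[:, None] * e_v + h0[:, None] * normals
    return feet


def build_template(
    clouds: list[PointCloud],
    reference: str | int = 0,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    tol: float | None = None,
    icp_max_iter: int = DEFAULT_ICP_MAX_ITER,
    icp_tol: float = DEFAULT_ICP_TOL,
    init_transforms: list[RigidTransform] | None = None,
    refine_poses: bool = True,
) -> tuple[Template, list[RigidTransform]]:
    """Build the unbiased population template by iterated re-alignment.

    Round 0 aligns every cloud to the reference subject, corresponds, and
    averages; each later round re-aligns to the current template,
    re-corresponds and re-averages.  Iteration stops when the template's
    mean point displacement between rounds falls below ``tol`` (default
    1e-3 of the population-mean bounding-box diagonal) or after
    ``max_rounds``.  Each new mean is rigidly anchored onto the previous
    one so the convergence measure sees shape change, not global drift.

    ``init_transforms`` (e.g. from :func:`tube_frame_pose` or
    :func:`centerline_guided_init`) seed the round-0 ICP per subject;
    without them ICP multi-starts from principal axes.

    ``refine_poses=False`` treats the given ``init_transforms`` as final
    poses: no ICP is run and the rounds only re-estimate the mean shape.
    This is the mode the mesh pipeline uses with tube-frame landmark
    poses — closest-point refinement of a tube that is wider or narrower
    than the template slides along the channel instead of improving the
    pose, so proximity-based refinement is deliberately skipped there.

    Returns the template and the per-subject total rigid transforms into
    the template frame.
    """
    if len(clouds) < 2:
        raise DegenerateInputError("template build needs >= 2 clouds")
    sizes = {c.n_points for c in clouds}
    if len(sizes) != 1:
        raise ValueError(f"all clouds must have equal N; got sizes {sorted(sizes)}")
    if len(clouds) == 2:
        import logging

        logging.getLogger(__name__).warning(
            "building a template from only 2 subjects; result is the midpoint shape"
        )
    if tol is None:
        diag = np.mean(
            [np.linalg.norm(c.points.max(0) - c.points.min(0)) for c in clouds]
        )
        tol = 1e-3 * diag

    if isinstance(reference, str):
        ids = [c.subject_id for c in clouds]
        if reference not in ids:
            raise ValueError(f"reference subject {reference!r} not among clouds")
        ref_idx = ids.index(reference)
    else:
        ref_idx = int(reference)

    transforms = [RigidTransform.identity() for _ in clouds]
    aligned = list(clouds)
    target = clouds[ref_idx]
    template_pts = None
    history: list[float] = []
    converged = False
    rounds = 0
    if not refine_poses:
        if init_transforms is None:
            raise ValueError("refine_poses=False requires init_transforms")
    for rounds in range(max_rounds + 1):
        if refine_poses:
            new_aligned = []
            for i, cloud in enumerate(aligned):
                # seeded or multi-start only on the first pass; later rounds
                # refine the already-aligned clouds in place
                if rounds > 0:
                    round_init = "identity"
                elif init_transforms is not None:
                    round_init = init_transforms[i]
                else:
                    round_init = "auto"
                res = icp_rigid(cloud, target, max_iter=icp_max_iter, tol=icp_tol, init=round_init)
                transforms[i] = res.transform.compose(transforms[i])
                new_aligned.append(res.aligned)
            aligned = new_aligned
        elif rounds == 0:
            aligned = [
                c.transformed(t.rotation, t.translation)
                for c, t in zip(aligned, init_transforms)
            ]
            transforms = [t for t in init_transforms]
        ref_pts = target.points if template_pts is None else template_pts
        stacked = np.stack([correspond(ref_pts, c) for c in aligned])
        new_template = stacked.mean(axis=0)
        if template_pts is not None:
            # anchor the new mean onto the previous one (ordered Kabsch) so
            # the convergence measure sees shape change only, not the slow
            # global drift a free generalized-Procrustes mean accumulates
            anchor = kabsch(new_template, template_pts)
            new_template = anchor.apply(new_template)
            change = float(np.mean(np.linalg.norm(new_template - template_pts, axis=1)))
            history.append(change)
            template_pts = new_template
            if change < tol:
                converged = True
                break
        else:
            template_pts = new_template
        if rounds == max_rounds:
            break
        target = PointCloud(template_pts, subject_id="__template__")

    return Template(template_pts, rounds, converged, history), transforms
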