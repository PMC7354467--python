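"""Synthetic aortic-surface populations with known ground truth.

Every downstream stage of the pipeline — alignment, PCA mode recovery,
strain estimation, morphometrics, and the shape-based surgery-risk model —
is testable against this generator, which emulates the study conditions of
an ascending-aorta cohort:

* an open curved tube (the ascending aorta cut near the brachiocephalic
  artery) with station diameters ~36-45 mm, centerline tortuosity ~0.12
  and curvature ~0.025/mm;
* population shape variation as weighted sums of mutually orthogonal
  wall-normal deformation fields (inflation, mid-tube bulge,
  cross-section ovalization; bow-deepening and minor nuisance variants
  available) with known per-subject weights;
* a random rigid perturbation per subject (rotations up to 30 deg,
  translations up to 50 mm) so alignment is exercised;
* paired diastole/systole surfaces with a prescribed radial strain
  profile;
* covariates with a known logistic link from mode weights to the surgery
  label (default prevalence ~0.2, matching reported surgical fractions).

Everything is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .alignment import RigidTransform
from .errors import DegenerateInputError
from .mesh_io import CohortTable, SurfaceMesh
from .strain import Centerline

#: logistic link (intercept, per-mm coefficients on the mode weights)
DEFAULT_LOGISTIC_BETA = (-2.0, 0.30, 0.50, 0.60)
#: generating-mode weight SDs in mm
DEFAULT_MODE_SDS = (4.0, 2.0, 1.0)
DEFAULT_MAX_ROTATION_DEG = 30.0
DEFAULT_MAX_TRANSLATION = 50.0


@dataclass
class AortaSpec:
    """Parameters of one synthetic aorta (lengths in mm)."""

    centerline_length: float = 70.0
    base_radius: float = 18.0
    tortuosity_amplitude: float = 6.0
    arc_angle_deg: float = 100.0
    ellipticity: float = 0.10
    dilatation_pattern: str = "ataa"  # {ataa, root, tubular, bulge, none}
    dilatation_amplitude: float = 4.0
    root_amplitude: float = 2.5       # sinus bulge of the "ataa" profile
    taper_amplitude: float = 2.5      # distal narrowing toward the arch cut
    bulge_center: float = 0.5
    bulge_width: float = 0.15
    axial_resolution: int = 60
    circumferential_resolution: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.centerline_length <= 0:
            raise ValueError("length and radius must be positive")
        if self.axial_resolution < 8 or self.circumferential_resolution < 8:
            raise ValueError("axial and circumferential resolutions must be >= 8")
        if self.tortuosity_amplitude < 0 or self.dilatation_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.bulge_center <= 1.0:
            raise ValueError("bulge_center must be in [0, 1]")
        if not 0.0 <= self.ellipticity < 1.0:
            raise ValueError("ellipticity must be in [0, 1)")
        if self.dilatation_pattern not in ("ataa", "root", "tubular", "bulge", "none"):
            raise ValueError(f"unknown dilatation pattern {self.dilatation_pattern!r}")


@dataclass
class GroundTruth:
    """Oracle record stored alongside every generated cohort."""

    weights: np.ndarray                       # (n_subjects, n_modes) mm
    transforms: list[RigidTransform]          # rigid perturbation per subject
    mode_sds: np.ndarray
    seed: int
    logistic_beta: np.ndarray | None = None
    surgery_probability: np.ndarray | None = None
    true_tortuosity: np.ndarray | None = None
    true_diameters: pd.DataFrame | None = None
    true_strain: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_subjects(self) -> int:
        return int(self.weights.shape[0])


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_centerline(
    length: float,
    tortuosity_amplitude: float,
    n_points: int = 100,
    seed: int = 0,
    arc_angle_deg: float = 100.0,
    n_harmonics: int = 2,
    max_curvature: float | None = None,
) -> np.ndarray:
    """Smooth open centerline: a planar circular arc with low-order
    sinusoidal out-of-plane perturbation.

    ``arc_angle_deg=0`` gives the degenerate straight variant;
    ``tortuosity_amplitude=0`` gives the unperturbed (planar) arc.  The
    returned polyline's arc length equals ``length`` (rescaled exactly).
    ``max_curvature`` (1/mm), if given, deterministically shrinks the
    perturbation until the discrete curvature stays below it — unlucky
    harmonic draws could otherwise bend tighter than a swept tube of the
    intended radius tolerates.
    """
    if n_points < 10:
        raise ValueError(f"n_points must be >= 10, got {n_points}")
    t = np.linspace(0.0, 1.0, n_points)
    if arc_angle_deg == 0.0:
        base = np.column_stack([np.zeros_like(t), np.zeros_like(t), length * t])
    else:
        theta = np.radians(arc_angle_deg)
        R = length / theta
        base = np.column_stack(
            [R * np.sin(theta * t), np.zeros_like(t), R * (1.0 - np.cos(theta * t))]
        )
    if tortuosity_amplitude > 0:
        rng = np.random.default_rng(seed)
        # 1/k^2 spectral weighting keeps the bow smooth: curvature is
        # dominated by the fundamental, not the asymmetric overtones
        coeffs = rng.normal(size=n_harmonics) / np.arange(1, n_harmonics + 1) ** 2
        y = sum(c * np.sin((k + 1) * np.pi * t) for k, c in enumerate(coeffs))
        y *= tortuosity_amplitude / max(np.abs(y).max(), 1e-12)
        perturbed = base + np.column_stack([np.zeros_like(t), y, np.zeros_like(t)])
        if max_curvature is not None:
            for _ in range(20):
                pts = perturbed * (length / np.sum(np.linalg.norm(np.diff(perturbed, axis=0), axis=1)))
                if _discrete_curvature(pts).max() <= max_curvature:
                    break
                y = 0.85 * y
                perturbed = base + np.column_stack([np.zeros_like(t), y, np.zeros_like(t)])
        base = perturbed
    arc = np.sum(np.linalg.norm(np.diff(base, axis=0), axis=1))
    return base * (length / arc)


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Twist-free orthonormal frames (t, e1, e2) along a polyline."""
    d = np.gradient(points, axis=0)
    t = d / np.linalg.norm(d, axis=1, keepdims=True)
    e1 = np.empty_like(t)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(t[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1[0] = np.cross(t[0], ref)
    e1[0] /= np.linalg.norm(e1[0])
    for i in range(1, len(t)):
        axis = np.cross(t[i - 1], t[i])
        s = np.linalg.norm(axis)
        c = np.clip(t[i - 1] @ t[i], -1.0, 1.0)
        if s < 1e-12:
            e1[i] = e1[i - 1]
        else:
            axis = axis / s
            v = e1[i - 1]
            e1[i] = v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)
        e1[i] -= (e1[i] @ t[i]) * t[i]
        e1[i] /= np.linalg.norm(e1[i])
    e2 = np.cross(t, e1)
    return t, e1, e2


def make_tube(
    centerline: np.ndarray | Centerline,
    radius_profile: Callable[[np.ndarray], np.ndarray] | float,
    circumferential_resolution: int = 24,
    subject_id: str = "",
    ellipticity: float = 0.0,
) -> SurfaceMesh:
    """Open tube swept along a centerline, cross-sections perpendicular to
    the local tangent, outward-wound faces, two boundary rings.

    ``radius_profile`` maps arc-length fraction in [0, 1] to radius (mm) or
    is a constant.  ``ellipticity`` e makes cross-sections elliptic with
    semi-axes r(1+e) / r(1-e), as aortic cross-sections are mildly oval;
    a non-zero value also removes the axisymmetry that would otherwise
    leave rigid registration free to "roll" the tube about its own axis.
    Raises if the tube would self-intersect (radius not smaller than the
    local radius of curvature).
    """
    if circumferential_resolution < 8:
        raise ValueError(
            f"circumferential_resolution must be >= 8, got {circumferential_resolution}"
        )
    cl = centerline if isinstance(centerline, Centerline) else Centerline(np.asarray(centerline))
    s = cl.fractions
    r = np.full(len(s), float(radius_profile)) if np.isscalar(radius_profile) else np.asarray(
        radius_profile(s), dtype=np.float64
    )
    if np.any(r <= 0):
        raise ValueError("radius_profile must be positive over [0, 1]")
    kappa = _discrete_curvature(cl.points)
    if np.any(r * (1.0 + ellipticity) * kappa >= 1.0):
        worst = float(np.max(r * (1.0 + ellipticity) * kappa))
        raise ValueError(
            f"tube self-intersects: radius x curvature reaches {worst:.3f} >= 1"
        )
    _, e1, e2 = _parallel_transport_frames(cl.points)
    phi = 2.0 * np.pi * np.arange(circumferential_resolution) / circumferential_resolution
    a = 1.0 + ellipticity
    b = 1.0 - ellipticity
    rings = (
        cl.points[:, None, :]
        + r[:, None, None] * (a * np.cos(phi)[None, :, None] * e1[:, None, :]
                              + b * np.sin(phi)[None, :, None] * e2[:, None, :])
    )
    n_ax, n_c = rings.shape[:2]
    vertices = rings.reshape(-1, 3)
    faces = []
    for i in range(n_ax - 1):
        for j in range(n_c):
            a = i * n_c + j
            b = i * n_c + (j + 1) % n_c
            c = (i + 1) * n_c + j
            d = (i + 1) * n_c + (j + 1) % n_c
            faces.append((a, b, c))
            faces.append((b, d, c))
    return SurfaceMesh(vertices, np.asarray(faces), subject_id=subject_id).validate()


def _discrete_curvature(points: np.ndarray) -> np.ndarray:
    kappa = np.zeros(len(points))
    if len(points) < 3:
        return kappa
    a = np.linalg.norm(points[1:-1] - points[:-2], axis=1)
    b = np.linalg.norm(points[2:] - points[1:-1], axis=1)
    c = np.linalg.norm(points[2:] - points[:-2], axis=1)
    area = 0.5 * np.linalg.norm(
        np.cross(points[1:-1] - points[:-2], points[2:] - points[1:-1]), axis=1
    )
    kappa[1:-1] = np.where(area > 1e-12, 4.0 * area / np.maximum(a * b * c, 1e-300), 0.0)
    return kappa


def radius_profile_for(spec: AortaSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Radius profile realizing the spec's dilatation pattern.

    The default "ataa" profile superposes a sinus bulge near the root, a
    mid-ascending dilatation and a distal taper toward the arch cut on the
    base radius, reproducing clinically typical station diameters
    (~41 / ~38 / ~44 mm at sinus / STJ / mid, narrowing to ~31 mm at the
    brachiocephalic cut).  The root-versus-distal asymmetry matters: real
    aortas are nowhere near symmetric under an end-to-end flip, and that
    asymmetry is what anchors rigid registration.
    """
    r0, amp = spec.base_radius, spec.dilatation_amplitude

    def gauss(s, center, width):
        return np.exp(-0.5 * ((s - center) / width) ** 2)

    def profile(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=np.float64)
        if spec.dilatation_pattern == "none":
            return np.full_like(s, r0)
        if spec.dilatation_pattern == "ataa":
            return (
                r0
                + spec.root_amplitude * gauss(s, 0.08, 0.07)
                + amp * gauss(s, 0.5, 0.15)
                - spec.taper_amplitude * gauss(s, 1.0, 0.25)
            )
        if spec.dilatation_pattern == "root":
            center, width = 0.10, 0.10
        elif spec.dilatation_pattern == "tubular":
            center, width = 0.50, 0.25
        else:  # bulge
            center, width = spec.bulge_center, spec.bulge_width
        return r0 + amp * gauss(s, center, width)

    return profile


def make_subject(spec: AortaSpec, subject_id: str = "") -> tuple[SurfaceMesh, Centerline]:
    """One synthetic aorta from its spec; returns (mesh, generating centerline)."""
    r_max = float(np.max(radius_profile_for(spec)(np.linspace(0, 1, 200))))
    pts = make_centerline(
        spec.centerline_length,
        spec.tortuosity_amplitude,
        n_points=spec.axial_resolution,
        seed=spec.seed,
        arc_angle_deg=spec.arc_angle_deg,
        max_curvature=0.9 / (r_max * (1.0 + spec.ellipticity)),
    )
    cl = Centerline(pts)
    mesh = make_tube(
        cl,
        radius_profile_for(spec),
        spec.circumferential_resolution,
        subject_id=subject_id,
        ellipticity=spec.ellipticity,
    )
    return mesh, cl


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def default_mode_basis(
    template: SurfaceMesh, centerline: Centerline, kind: str = "radial"
) -> np.ndarray:
    """Three orthogonal generating fields, shape (3, n_vertices, 3).

    ``kind="radial"`` (default):

    1. uniform wall-normal inflation (overall size),
    2. Gaussian mid-ascending bulge (tubular dilatation),
    3. mid-tube ovalization (cos 2-phi cross-section eccentricity);

    all three displace the wall along its local surface normal, the
    component that closest-point correspondence measures faithfully: a
    normal-offset surface keeps every foot point in place, whereas
    displacing a sloped profile along the centerline-radial direction
    makes foot points slide axially (proportionally to weight x slope),
    which shows up as spurious bilinear artifact modes.  Broad envelopes
    are used for the same reason: bands narrower than the size-mode
    excursion reintroduce sliding bias at steep-slope stations.

    ``kind="bend"`` replaces the second field with an out-of-plane bend
    that drives centerline tortuosity (and demotes the mid bulge to third).
    A bend moves wall points sideways — half its energy is tangential to
    the wall and invisible to closest-point correspondence — so bend
    weights are recovered with attenuation; this basis is the one to use
    when a tortuosity-linked mode is wanted in the cohort.

    Each field is first projected orthogonal to the six rigid-motion
    generators (translations and infinitesimal rotations about the
    centroid): shape modes must carry no pose component, both by the
    definition of a statistical shape model and because any rigid residue
    would couple per-subject alignment jitter directly into the mode
    scores.  The fields are then Gram-Schmidt orthogonalized among
    themselves (as flattened vectors) and scaled to a common flattened
    norm of sqrt(n_vertices), so a weight of w mm produces an RMS vertex
    displacement of w mm.
    """
    fine = centerline.resample(max(4 * len(centerline.points), 200))
    dist, idx = cKDTree(fine.points).query(template.vertices)
    radial = template.vertices - fine.points[idx]
    radial /= np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-12)
    s = fine.fractions[idx]

    # outward vertex normals of the template wall
    normals = np.array(template.to_trimesh().vertex_normals, dtype=np.float64, copy=True)
    flip = np.sum(normals * radial, axis=1) < 0
    normals[flip] = -normals[flip]
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)

    f1 = normals
    bulge_mid = np.exp(-0.5 * ((s - 0.5) / 0.15) ** 2)[:, None] * normals
    # azimuth of each vertex in the twist-free cross-section frame
    _, e1f, e2f = _parallel_transport_frames(fine.points)
    phi = np.arctan2(
        np.sum(radial * e2f[idx], axis=1), np.sum(radial * e1f[idx], axis=1)
    )
    oval = (np.cos(2.0 * phi) * np.exp(-0.5 * ((s - 0.5) / 0.20) ** 2))[:, None] * normals
    # bend: one-sided wall bulge toward the outer curvature.  Thickening
    # one side shifts the cross-section centroids outward and deepens the
    # bow, so centerline tortuosity responds monotonically to the weight,
    # while the displacement stays wall-normal (fully measurable by
    # normal-displacement correspondence; an in-plane lateral field would
    # be half-invisible and largely absorbed as pose).
    chord_mid = 0.5 * (centerline.points[0] + centerline.points[-1])
    sagitta = centerline.point_at(0.5) - chord_mid
    sagitta /= max(np.linalg.norm(sagitta), 1e-12)
    phi_sag = np.arctan2(sagitta @ e2f[idx].T, sagitta @ e1f[idx].T)
    bend = (np.cos(phi - phi_sag) * np.exp(-0.5 * ((s - 0.5) / 0.25) ** 2))[:, None] * normals
    if kind == "radial":
        fields = (f1, bulge_mid, oval)
    elif kind == "bend":
        fields = (f1, bend, bulge_mid)
    elif kind == "extended":
        # three principal fields plus minor nuisance modes, giving the
        # population the longer eigenvalue tail real anatomies show
        bulge_root = np.exp(-0.5 * ((s - 0.15) / 0.10) ** 2)[:, None] * normals
        bulge_distal = np.exp(-0.5 * ((s - 0.80) / 0.10) ** 2)[:, None] * normals
        oval2 = (np.sin(2.0 * phi) * np.exp(-0.5 * ((s - 0.5) / 0.20) ** 2))[:, None] * normals
        fields = (f1, bulge_mid, oval, bulge_root, bulge_distal, oval2)
    else:
        raise ValueError(f"unknown basis kind {kind!r}")

    # orthonormal basis of the rigid-motion generators at the template
    centered = template.vertices - template.vertices.mean(axis=0)
    rigid_fields = [np.tile(e, (template.n_vertices, 1)) for e in np.eye(3)]
    rigid_fields += [np.cross(np.tile(e, (template.n_vertices, 1)), centered) for e in np.eye(3)]
    rigid_basis: list[np.ndarray] = []
    for rf in rigid_fields:
        v = rf.ravel().astype(np.float64)
        for b in rigid_basis:
            v = v - (v @ b) * b
        rigid_basis.append(v / np.linalg.norm(v))

    basis: list[np.ndarray] = []
    for f in fields:
        v = f.ravel().astype(np.float64)
        for b in rigid_basis + basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise DegenerateInputError("mode basis fields are linearly dependent")
        basis.append(v / norm)
    scale = np.sqrt(template.n_vertices)
    return np.stack([b.reshape(-1, 3) * scale for b in basis])


def _check_orthogonal(basis: np.ndarray) -> None:
    flat = basis.reshape(len(basis), -1)
    G = flat @ flat.T
    d = np.sqrt(np.diag(G))
    C = G / np.outer(d, d)
    off = np.abs(C - np.eye(len(basis)))
    if off.max() > 1e-8:
        raise ValueError(f"mode basis not orthogonal; normalized Gram matrix:\n{C}")


def _random_rigid(
    rng: np.random.Generator, max_rotation_deg: float, max_translation: float
) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = rng.uniform(0.0, max_translation) * direction
    return RigidTransform(R, t)


def make_population(
    template: SurfaceMesh,
    mode_basis: np.ndarray,
    mode_sds: Sequence[float],
    n_subjects: int,
    seed: int = 0,
    max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG,
    max_translation: float = DEFAULT_MAX_TRANSLATION,
    rigid_perturbation: bool = True,
    weight_means: Sequence[float] | None = None,
    id_prefix: str = "s",
) -> tuple[list[SurfaceMesh], GroundTruth]:
    """Population of meshes: template + sum_k w_ik field_k, rigidly perturbed.

    Weights are Normal(mean_k, sd_k^2) per mode (means default to 0); the
    ground truth records weights and perturbations so that alignment, mode
    recovery and risk models can all be scored exactly.
    """
    mode_basis = np.asarray(mode_basis, dtype=np.float64)
    mode_sds = np.asarray(mode_sds, dtype=np.float64)
    if len(mode_basis) != len(mode_sds):
        raise ValueError("one SD per mode field required")
    if np.any(np.diff(mode_sds) > 0):
        raise ValueError(f"mode SDs must be non-increasing, got {mode_sds}")
    _check_orthogonal(mode_basis)
    means = np.zeros(len(mode_sds)) if weight_means is None else np.asarray(weight_means)

    rng = np.random.default_rng(seed)
    weights = means + rng.normal(size=(n_subjects, len(mode_sds))) * mode_sds
    meshes: list[SurfaceMesh] = []
    transforms: list[RigidTransform] = []
    for i in range(n_subjects):
        verts = template.vertices + np.tensordot(weights[i], mode_basis, axes=1)
        tr = (
            _random_rigid(rng, max_rotation_deg, max_translation)
            if rigid_perturbation
            else RigidTransform.identity()
        )
        meshes.append(
            SurfaceMesh(tr.apply(verts), template.faces.copy(), subject_id=f"{id_prefix}{i:03d}")
        )
        transforms.append(tr)
    truth = GroundTruth(weights=weights, transforms=transforms, mode_sds=mode_sds, seed=seed)
    return meshes, truth


def make_phase_pair(
    mesh: SurfaceMesh,
    strain_profile: Callable[[np.ndarray], np.ndarray] | float,
    centerline: Centerline,
) -> tuple[SurfaceMesh, SurfaceMesh, np.ndarray]:
    """Diastole/systole pair with known radial strain.

    Each vertex moves radially away from the centerline by
    ``strain_profile(s) * local_radius``; the returned ``true_strain`` is
    the profile evaluated at each diastolic vertex's station.
    """
    fine = centerline.resample(max(4 * len(centerline.points), 200))
    dist, idx = cKDTree(fine.points).query(mesh.vertices)
    s = fine.fractions[idx]
    eps = (
        np.full(len(s), float(strain_profile))
        if np.isscalar(strain_profile)
        else np.asarray(strain_profile(s), dtype=np.float64)
    )
    if np.any(eps < 0):
        raise ValueError("strain_profile must be >= 0")
    radial = mesh.vertices - fine.points[idx]
    systole = SurfaceMesh(
        mesh.vertices + eps[:, None] * radial,
        mesh.faces.copy(),
        subject_id=f"{mesh.subject_id}_sys",
    )
    diastole = SurfaceMesh(
        mesh.vertices.copy(), mesh.faces.copy(), subject_id=f"{mesh.subject_id}_dia"
    )
    return diastole, systole, eps


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def make_covariates(
    meshes: list[SurfaceMesh],
    ground_truth: GroundTruth,
    logistic_beta: Sequence[float] = DEFAULT_LOGISTIC_BETA,
    seed: int = 0,
    bav_fraction: float = 0.5,
    group: str = "ATAA",
    measure: bool = True,
    n_stations: int = 40,
) -> CohortTable:
    """Cohort table with a known logistic surgery link on the mode weights.

    Surgery labels are Bernoulli(sigmoid(beta0 + beta . w)); valve labels
    are a seeded BAV/TAV split at ``bav_fraction``; station diameters and
    tortuosity are measured from the meshes (never invented); orifice area
    and STJ wall shear stress are drawn with fixed linear links to the
    bulge-mode weight plus noise, emulating descriptor-mode correlations of
    realistic magnitude (|R| ~ 0.3-0.6).
    """
    from .morphometrics import DEFAULT_STATIONS, station_diameter
    from .morphometrics import tortuosity as _tortuosity
    from .strain import extract_centerline

    beta = np.asarray(logistic_beta, dtype=np.float64)
    w = ground_truth.weights
    if len(beta) != w.shape[1] + 1:
        raise ValueError(
            f"logistic_beta must have intercept + {w.shape[1]} coefficients, got {len(beta)}"
        )
    rng = np.random.default_rng(seed)
    prob = _sigmoid(beta[0] + w @ beta[1:])
    surgery = rng.random(len(prob)) < prob

    n = len(meshes)
    n_bav = int(round(bav_fraction * n))
    valve = np.array(["BAV"] * n_bav + ["TAV"] * (n - n_bav))
    rng.shuffle(valve)

    rows = []
    diam_rows = []
    tort = np.full(n, np.nan)
    for i, mesh in enumerate(meshes):
        if measure:
            from .errors import TopologyError

            cl = extract_centerline(mesh, n_stations=n_stations)
            d = {}
            for k, f in DEFAULT_STATIONS.items():
                try:
                    d[k] = station_diameter(mesh, cl, f, multi_loop="nearest")
                except TopologyError:
                    # e.g. the sinus plane exits through the cut boundary on
                    # a strongly dilated root; marked absent, never zero
                    d[k] = np.nan
            tort[i] = _tortuosity(cl)
        else:
            d = {k: np.nan for k in ("sinus", "stj", "midaa")}
        diam_rows.append(d)
        rows.append(
            {
                "subject_id": mesh.subject_id,
                "group": group,
                "valve": valve[i] if group == "ATAA" else "control",
                "surgery": bool(surgery[i]),
                "diameter_sinus": d["sinus"],
                "diameter_stj": d["stj"],
                "diameter_midaa": d["midaa"],
                "tortuosity": tort[i],
            }
        )
    df = pd.DataFrame(rows)
    # functional descriptors with fixed links to the bulge-mode weight
    w2 = w[:, 1] if w.shape[1] > 1 else np.zeros(n)
    df["orifice_area"] = 330.0 - 25.0 * w2 + rng.normal(0.0, 60.0, n)
    df["wss_stj"] = np.maximum(1.5 + 0.10 * w2 + rng.normal(0.0, 0.55, n), 0.05)
    df["flow_jet"] = np.maximum(1.6 + rng.normal(0.0, 0.4, n), 0.3)

    ground_truth.logistic_beta = beta
    ground_truth.surgery_probability = prob
    ground_truth.true_tortuosity = tort
    ground_truth.true_diameters = pd.DataFrame(diam_rows, index=df["subject_id"])
    return CohortTable(df)


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    template_mesh: SurfaceMesh
    centerline: Centerline
    mode_basis: np.ndarray = field(repr=False)
    meshes: list[SurfaceMesh] = field(repr=False)
    cohort: CohortTable = field(repr=False)
    truth: GroundTruth = field(repr=False)


def simulate_cohort(
    n_ataa: int = 80,
    n_control: int = 0,
    spec: AortaSpec | None = None,
    mode_sds: Sequence[float] = DEFAULT_MODE_SDS,
    logistic_beta: Sequence[float] = DEFAULT_LOGISTIC_BETA,
    seed: int = 0,
    rigid_perturbation: bool = True,
    measure: bool = True,
    basis_kind: str = "radial",
) -> SimulatedCohort:
    """Generate a full synthetic cohort (meshes + covariates + ground truth).

    Controls, if requested, share the template and basis but have a
    deflated size mode (weight mean -6 mm, halved SDs) and never undergo
    surgery — emulating non-aneurysmal aortas alongside the ATAA group.
    """
    spec = spec or AortaSpec()
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    template, centerline = make_subject(
        AortaSpec(**{**spec.__dict__, "seed": int(ss[0])}), subject_id="template"
    )
    basis = default_mode_basis(template, centerline, kind=basis_kind)
    meshes, truth = make_population(
        template, basis, mode_sds, n_ataa, seed=int(ss[1]),
        rigid_perturbation=rigid_perturbation,
    )
    cohort = make_covariates(
        meshes, truth, logistic_beta=logistic_beta, seed=int(ss[2]), measure=measure
    )
    if n_control > 0:
        # strictly-decreasing halved SDs, deflated size mode
        ctrl_sds = np.asarray(mode_sds) * 0.5
        ctrl_meshes, ctrl_truth = make_population(
            template, basis, ctrl_sds, n_control, seed=int(ss[3]),
            rigid_perturbation=rigid_perturbation,
            weight_means=[-6.0] + [0.0] * (len(mode_sds) - 1),
            id_prefix="c",
        )
        ctrl_cohort = make_covariates(
            ctrl_meshes, ctrl_truth, logistic_beta=logistic_beta, seed=int(ss[3]),
            group="control", measure=measure,
        )
        ctrl_df = ctrl_cohort.df.copy()
        ctrl_df["surgery"] = False
        meshes = meshes + ctrl_meshes
        cohort = CohortTable(pd.concat([cohort.df, ctrl_df], ignore_index=True))
        truth = GroundTruth(
            weights=np.vstack([truth.weights, ctrl_truth.weights]),
            transforms=truth.transforms + ctrl_truth.transforms,
            mode_sds=truth.mode_sds,
            seed=seed,
            logistic_beta=truth.logistic_beta,
            surgery_probability=np.concatenate(
                [truth.surgery_probability, np.zeros(n_control)]
            ),
            true_tortuosity=np.concatenate([truth.true_tortuosity, ctrl_truth.true_tortuosity]),
        )
    return SimulatedCohort(template, centerline, basis, meshes, cohort, truth)
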