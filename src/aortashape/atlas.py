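"""PCA shape atlas: modes, eigenvalues, per-subject scores, deformation.

Each corresponded subject cloud is flattened to a 3N shape vector; the
population matrix is column-mean-centred and decomposed by SVD (equivalent
to eigendecomposition of the 3N x 3N covariance, but feasible at
N = 15,000).  Eigenvectors are the shape modes, eigenvalues their variance
in mm^2, and the per-subject projections ("shape vectors") are the scores
used by all downstream statistics.  At most n_subjects - 1 modes are
non-null.

Sign convention: each mode is oriented so its inner product with the
template's radial-inflation direction (points minus template centroid,
normalised) is non-negative; exact ties fall back to making the first
nonzero component positive.  PCA eigenvectors are defined only up to sign,
so a fixed convention is required for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .sampling import PointCloud

DEFAULT_VARIANCE_THRESHOLD = 0.90
#: eigenvalues below this fraction of the largest are treated as null
_NULL_EIGENVALUE_REL = 1e-12


@dataclass
class ShapeAtlas:
    template: np.ndarray            # (N, 3) mean shape, mm
    modes: np.ndarray               # (k, 3N) orthonormal rows
    eigenvalues: np.ndarray         # (k,) variance per mode, mm^2, non-increasing
    scores: np.ndarray              # (n_subjects, k) mode scores, mm
    subject_ids: list[str]
    degenerate: bool = False
    variance_fractions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = float(self.eigenvalues.sum())
        if total > 0:
            self.variance_fractions = self.eigenvalues / total
        else:
            self.variance_fractions = np.zeros_like(self.eigenvalues)
            self.degenerate = True

    @property
    def n_points(self) -> int:
        return int(self.template.shape[0])

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[0])

    @property
    def n_subjects(self) -> int:
        return int(self.scores.shape[0])

    @property
    def n_modes_retained_90(self) -> int:
        return modes_for_variance(self, DEFAULT_VARIANCE_THRESHOLD)

    def mode_field(self, mode: int) -> np.ndarray:
        """Deformation field of 1-based ``mode`` as an (N, 3) array."""
        return self.modes[mode - 1].reshape(-1, 3)


def fit_pca(corresponded: np.ndarray | list, subject_ids: list[str] | None = None) -> ShapeAtlas:
    """Fit the shape atlas from corresponded clouds (subjects x N x 3).

    All clouds must be in template point order and in the common aligned
    frame.  A rank-0 population (all subjects identical) yields an atlas
    flagged ``degenerate`` with zero eigenvalues rather than an error.
    """
    X3 = np.stack([c.points if isinstance(c, PointCloud) else np.asarray(c) for c in corresponded])
    n, N, _ = X3.shape
    if n < 2:
        raise DegenerateInputError(f"PCA needs >= 2 subjects, got {n}")
    if subject_ids is None:
        subject_ids = [getattr(c, "subject_id", "") or f"s{i}" for i, c in enumerate(corresponded)]
    X = X3.reshape(n, 3 * N)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    # drop null modes (centering always kills at least one singular value)
    cutoff = _NULL_EIGENVALUE_REL * max(eigenvalues[0], 1.0) if eigenvalues.size else 0.0
    k = min(int((eigenvalues > cutoff).sum()), n - 1)
    modes, eigenvalues, U, s = Vt[:k], eigenvalues[:k], U[:, :k], s[:k]

    template = mean.reshape(N, 3)
    signs = _sign_convention(modes, template)
    modes = modes * signs[:, None]
    scores = (U * s) * signs[None, :]
    return ShapeAtlas(
        template=template,
        modes=modes,
        eigenvalues=eigenvalues,
        scores=scores,
        subject_ids=list(subject_ids),
        degenerate=k == 0,
    )


def _sign_convention(modes: np.ndarray, template: np.ndarray) -> np.ndarray:
    radial = template - template.mean(axis=0)
    nrm = np.linalg.norm(radial)
    radial = (radial / nrm).ravel() if nrm > 0 else np.zeros(template.size)
    signs = np.ones(modes.shape[0])
    for i, mode in enumerate(modes):
        dot = float(mode @ radial)
        if abs(dot) > 1e-12:
            signs[i] = np.sign(dot)
        else:
            nz = mode[np.abs(mode) > 1e-15]
            signs[i] = np.sign(nz[0]) if nz.size else 1.0
    return signs


def modes_for_variance(atlas: ShapeAtlas, threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> int:
    """Smallest k whose cumulative variance fraction reaches ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if atlas.degenerate:
        raise DegenerateInputError("atlas is degenerate (zero total variance)")
    cum = np.cumsum(atlas.variance_fractions)
    if threshold >= cum[-1]:  # threshold 1.0 (or rounding): every non-null mode
        return atlas.n_modes
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def deform_template(atlas: ShapeAtlas, mode: int, c: float) -> PointCloud:
    """Template deformed along 1-based ``mode`` by ``c`` standard deviations.

    The clinically interpretable sweep is c in [-2, +2]; values beyond warn
    (extrapolation outside the observed population) but are permitted.
    """
    if not 1 <= mode <= atlas.n_modes:
        raise ValueError(f"mode must be in 1..{atlas.n_modes}, got {mode}")
    if abs(c) > 2.0:
        import warnings

        warnings.warn(f"|c|={abs(c)} > 2 SD extrapolates beyond the population", stacklevel=2)
    sd = np.sqrt(atlas.eigenvalues[mode - 1])
    pts = atlas.template + c * sd * atlas.mode_field(mode)
    return PointCloud(pts, subject_id=f"template_mode{mode}_{c:+g}sd")


def project_subject(atlas: ShapeAtlas, corresponded_cloud: PointCloud | np.ndarray) -> np.ndarray:
    """Mode scores of a corresponded cloud: modes . (flattened - mean shape)."""
    pts = (
        corresponded_cloud.points
        if isinstance(corresponded_cloud, PointCloud)
        else np.asarray(corresponded_cloud)
    )
    if pts.shape != atlas.template.shape:
        raise ValueError(f"cloud shape {pts.shape} != template shape {atlas.template.shape}")
    return atlas.modes @ (pts - atlas.template).ravel()


def reconstruct_subject(atlas: ShapeAtlas, scores: np.ndarray) -> np.ndarray:
    """Mean shape plus the linear combination of modes given by ``scores``."""
    scores = np.asarray(scores)
    return atlas.template + (scores @ atlas.modes[: len(scores)]).reshape(-1, 3)


def scree_table(atlas: ShapeAtlas) -> pd.DataFrame:
    """Eigenvalue / variance-fraction table (the scree-plot content)."""
    return pd.DataFrame(
        {
            "mode": np.arange(1, atlas.n_modes + 1),
            "eigenvalue_mm2": atlas.eigenvalues,
            "variance_fraction": atlas.variance_fractions,
            "cumulative_fraction": np.cumsum(atlas.variance_fractions),
        }
    )


def save_atlas(atlas: ShapeAtlas, path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("template", data=atlas.template)
        f.create_dataset("modes", data=atlas.modes)
        f.create_dataset("eigenvalues", data=atlas.eigenvalues)
        f.create_dataset("scores", data=atlas.scores)
        f.create_dataset(
            "subject_ids", data=np.array(atlas.subject_ids, dtype=h5py.string_dtype())
        )
        f.attrs["degenerate"] = atlas.degenerate
        for key, value in (metadata or {}).items():
            f.attrs[key] = value
    return path


def load_atlas(path: str | Path) -> ShapeAtlas:
    with h5py.File(path, "r") as f:
        return ShapeAtlas(
            template=f["template"][:],
            modes=f["modes"][:],
            eigenvalues=f["eigenvalues"][:],
            scores=f["scores"][:],
            subject_ids=[s.decode() for s in f["subject_ids"][:]],
            degenerate=bool(f.attrs.get("degenerate", False)),
        )
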