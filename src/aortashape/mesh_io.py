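"""Surface-mesh and cohort-table I/O.

Meshes are triangulated surfaces of the ascending aorta, one per subject,
with vertex coordinates in millimetres (STL/PLY/OBJ carry no unit metadata;
mm is assumed throughout, matching clinical CT conventions).  The cohort
table carries per-subject covariates: valve morphology (BAV/TAV/control),
the surgery end point, station diameters, and optional functional
descriptors (orifice area, flow jet, wall shear stress, strain).

Geometry is validated on read: every analysis stage downstream assumes
finite coordinates, in-range face indices and no zero-area triangles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import CohortError, MeshValidationError

SUPPORTED_FORMATS = ("stl", "ply", "obj")
VALVE_LABELS = ("BAV", "TAV", "control")

#: cross-product norm below which a triangle counts as zero-area (mm^2)
DEGENERATE_AREA_TOL = 1e-10


@dataclass
class SurfaceMesh:
    """A triangulated surface with vertices in mm.

    Face winding is preserved from the source file; generated tubes and
    spheres use outward-pointing winding, which the strain stage relies on.
    """

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray     # (m, 3) int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def validate(self) -> "SurfaceMesh":
        validate_mesh(self.vertices, self.faces)
        return self


def validate_mesh(vertices: np.ndarray, faces: np.ndarray) -> None:
    """Raise :class:`MeshValidationError` naming every defect found."""
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces)
    defects = []
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise MeshValidationError(f"vertices must be (n, 3), got {vertices.shape}")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshValidationError(f"faces must be (m, 3), got {faces.shape}")
    if vertices.shape[0] < 4:
        defects.append(f"mesh has {vertices.shape[0]} vertices; at least 4 required")
    if not np.isfinite(vertices).all():
        bad = np.unique(np.nonzero(~np.isfinite(vertices))[0])
        defects.append(f"non-finite coordinates at vertices {bad.tolist()[:10]}")
    if faces.size and (faces.min() < 0 or faces.max() >= vertices.shape[0]):
        bad = np.unique(np.nonzero((faces < 0) | (faces >= vertices.shape[0]))[0])
        defects.append(f"face indices out of range at faces {bad.tolist()[:10]}")
    elif faces.size and np.isfinite(vertices).all():
        v = vertices[faces]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        bad = np.nonzero(area2 < 2.0 * DEGENERATE_AREA_TOL)[0]
        if bad.size:
            defects.append(f"zero-area triangles at faces {bad.tolist()[:20]}")
    if defects:
        raise MeshValidationError("; ".join(defects))


def _format_from_path(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {SUPPORTED_FORMATS}")
    return fmt


def read_mesh(path: str | Path, fmt: str | None = None, subject_id: str | None = None) -> SurfaceMesh:
    """Read and validate a surface mesh.

    STL stores an unindexed triangle soup, so duplicate vertices are merged
    on read (required for boundary-loop/topology queries downstream); PLY
    and OBJ keep their authored indexing untouched.
    """
    path = Path(path)
    fmt = _format_from_path(path, fmt)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - file-format errors vary by loader
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = _merge_duplicate_vertices(vertices, faces)
    validate_mesh(vertices, faces)
    return SurfaceMesh(vertices, faces, subject_id=subject_id or path.stem)


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray):
    """Merge exactly coincident vertices, keeping first-occurrence order."""
    uniq, first_idx, inverse = np.unique(
        vertices.round(decimals=12), axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first_idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return vertices[first_idx[order]], rank[inverse][faces]


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = _format_from_path(path, fmt)
    mesh.validate()
    mesh.to_trimesh().export(str(path), file_type=fmt)
    return path


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

#: numeric covariates; those in OPTIONAL_COLUMNS may be absent entirely
DIAMETER_COLUMNS = ("diameter_sinus", "diameter_stj", "diameter_midaa")
NUMERIC_COLUMNS = DIAMETER_COLUMNS + ("orifice_area", "flow_jet", "wss_stj", "strain_midaa")
OPTIONAL_COLUMNS = ("orifice_area", "flow_jet", "wss_stj", "strain_midaa", "group")


@dataclass
class CohortTable:
    """Typed per-subject covariate table.

    Missing optional fields are represented as NaN / absent columns, never
    as zero — a 0 mm diameter or 0 Pa WSS would silently poison statistics.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate_cohort_frame(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def has(self, column: str) -> bool:
        """True if *column* exists and has at least one non-missing value."""
        return column in self.df.columns and self.df[column].notna().any()

    def column(self, name: str) -> pd.Series:
        """Column indexed by subject_id; NaN series if entirely absent."""
        idx = pd.Index(self.subject_ids, name="subject_id")
        if name not in self.df.columns:
            return pd.Series(np.nan, index=idx, name=name)
        return pd.Series(self.df[name].to_numpy(), index=idx, name=name)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[mask].reset_index(drop=True))


def _validate_cohort_frame(df: pd.DataFrame) -> None:
    if "subject_id" not in df.columns:
        raise CohortError("cohort table must have a 'subject_id' column")
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise CohortError(f"duplicate subject_id values: {sorted(set(dup))}")
    if "valve" in df.columns:
        bad = df.loc[~df["valve"].isin(VALVE_LABELS) & df["valve"].notna()]
        if len(bad):
            rows = ", ".join(
                f"row {i} (subject {r.subject_id}): valve={r.valve!r}" for i, r in bad.iterrows()
            )
            raise CohortError(f"unknown valve label(s): {rows}; allowed {VALVE_LABELS}")
    for col in DIAMETER_COLUMNS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.loc[vals.notna() & (vals <= 0), "subject_id"].tolist()
            if bad:
                raise CohortError(f"non-positive {col} for subjects {bad}")


def read_cohort(path: str | Path | io.IOBase) -> CohortTable:
    """Read a cohort CSV (comma-separated, UTF-8, header row).

    Recognized columns: subject_id, valve, surgery, diameter_sinus,
    diameter_stj, diameter_midaa, orifice_area, flow_jet, wss_stj,
    strain_midaa, group.  Extra columns are carried through untouched.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if "subject_id" in df.columns:
        df["subject_id"] = df["subject_id"].astype(str)
    if "surgery" in df.columns:
        df["surgery"] = df["surgery"].map(_parse_bool)
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return CohortTable(df)


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def _parse_bool(value):
    if pd.isna(value):
        return np.nan
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise CohortError(f"cannot interpret surgery value {value!r} as boolean")
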