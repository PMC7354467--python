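"""Shared fixtures: all geometry is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import aortashape as ash
from aortashape.mesh_io import SurfaceMesh
from aortashape.pipeline import build_atlas_from_meshes
from aortashape.strain import Centerline

#: fixed cohort seed used by the heavyweight recovery fixtures
COHORT_SEED = 11


@pytest.fixture(scope="session")
def tube_subject():
    """One synthetic aorta (mesh + generating centerline), default spec."""
    return ash.make_subject(ash.AortaSpec(seed=3), "tube")


@pytest.fixture(scope="session")
def straight_cylinder():
    """Straight cylinder, radius 20 mm, fine circumferential resolution."""
    cl = Centerline(np.column_stack([np.zeros(60), np.zeros(60), np.linspace(0, 100, 60)]))
    mesh = ash.make_tube(cl, 20.0, circumferential_resolution=64, subject_id="cyl")
    return mesh, cl


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces), "sphere")


@pytest.fixture(scope="session")
def concentric_spheres():
    """Diastole/systole spheres of radius 10 and 11 mm (same tessellation)."""
    ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    v, f = np.asarray(ico.vertices), np.asarray(ico.faces)
    return SurfaceMesh(10.0 * v, f, "dia"), SurfaceMesh(11.0 * v, f, "sys")


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=80 three-mode cohort with rigid perturbations and measured covariates."""
    return ash.simulate_cohort(
        n_ataa=80, seed=COHORT_SEED, measure=True, rigid_perturbation=True
    )


@pytest.fixture(scope="session")
def recovery_atlas(recovery_cohort):
    """Full pipeline atlas of the recovery cohort at N=2000 points."""
    atlas, template, transforms = build_atlas_from_meshes(
        recovery_cohort.meshes, recovery_cohort.cohort, n_points=2000, seed=COHORT_SEED + 1
    )
    return atlas, template, transforms
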