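"""Generator contracts: geometry closed forms, determinism, ground truth."""

import numpy as np
import pytest

import aortashape as ash
from aortashape.morphometrics import station_diameter, tortuosity
from aortashape.strain import Centerline
from aortashape.synthetic import (
    DEFAULT_LOGISTIC_BETA,
    _sigmoid,
    default_mode_basis,
    make_centerline,
    make_covariates,
    make_phase_pair,
    make_population,
    make_tube,
    radius_profile_for,
    simulate_cohort,
)


class TestMakeCenterline:
    def test_arc_length_matches_request(self):
        pts = make_centerline(70.0, 6.0, n_points=80, seed=1)
        arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert abs(arc - 70.0) < 1e-9

    def test_straight_variant_has_zero_tortuosity(self):
        pts = make_centerline(100.0, 0.0, n_points=50, arc_angle_deg=0.0)
        assert tortuosity(pts) < 1e-12

    def test_semicircle_tortuosity_closed_form(self):
        pts = make_centerline(100.0, 0.0, n_points=400, arc_angle_deg=180.0)
        assert abs(tortuosity(pts) - (np.pi / 2 - 1)) < 2e-4

    def test_deterministic_for_fixed_seed(self):
        a = make_centerline(70.0, 6.0, seed=5)
        b = make_centerline(70.0, 6.0, seed=5)
        assert np.array_equal(a, b)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            make_centerline(70.0, 3.0, n_points=5)


class TestMakeTube:
    def test_cylinder_diameter_and_vertex_count(self, straight_cylinder):
        mesh, cl = straight_cylinder
        assert mesh.n_vertices == 60 * 64
        for st in (0.2, 0.5, 0.8):
            d = station_diameter(mesh, cl, st)
            assert abs(d - 40.0) / 40.0 < 0.005

    def test_bump_profile_peaks_at_center(self):
        cl = Centerline(np.column_stack([np.zeros(80), np.zeros(80), np.linspace(0, 100, 80)]))
        prof = lambda s: 15.0 + 4.0 * np.exp(-0.5 * ((s - 0.5) / 0.1) ** 2)
        mesh = make_tube(cl, prof, 32)
        stations = np.linspace(0.2, 0.8, 25)
        diams = [station_diameter(mesh, cl, s) for s in stations]
        step = 1.0 / 79
        assert abs(stations[int(np.argmax(diams))] - 0.5) <= step + 1e-9

    def test_low_circumferential_resolution_rejected(self):
        cl = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 50, 20)])
        with pytest.raises(ValueError, match=">= 8"):
            make_tube(cl, 10.0, circumferential_resolution=7)

    def test_self_intersecting_tube_rejected(self):
        pts = make_centerline(60.0, 0.0, n_points=60, arc_angle_deg=180.0)  # R ~ 19
        with pytest.raises(ValueError, match="self-intersects"):
            make_tube(pts, 25.0, 16)

    def test_two_boundary_rings(self, tube_subject):
        from aortashape.strain import boundary_loops

        mesh, _ = tube_subject
        assert len(boundary_loops(mesh)) == 2


class TestModeBasis:
    def test_fields_orthogonal_and_rigid_free(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        flat = basis.reshape(3, -1)
        G = flat @ flat.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()
        # no net translation and no net moment about the centroid
        centered = mesh.vertices - mesh.vertices.mean(axis=0)
        for f in basis:
            assert np.abs(f.sum(axis=0)).max() < 1e-8
            assert np.abs(np.cross(centered, f).sum(axis=0)).max() < 1e-6


class TestMakePopulation:
    def test_sample_weight_sds_near_nominal(self, recovery_cohort):
        sds = recovery_cohort.truth.weights.std(axis=0, ddof=1)
        assert np.all(np.abs(sds - (4, 2, 1)) / (4, 2, 1) < 0.25)

    def test_nonorthogonal_basis_rejected(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        skewed = basis.copy()
        skewed[1] = basis[0] + basis[1]
        with pytest.raises(ValueError, match="orthogonal"):
            make_population(mesh, skewed, (4, 2, 1), 5, seed=0)

    def test_increasing_sds_rejected(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        with pytest.raises(ValueError, match="non-increasing"):
            make_population(mesh, basis, (1, 2, 4), 5, seed=0)

    def test_zero_sds_give_congruent_subjects(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        meshes, truth = make_population(mesh, basis, (0.0, 0.0, 0.0), 4, seed=2)
        assert np.allclose(truth.weights, 0.0)
        for m, tr in zip(meshes, truth.transforms):
            assert np.allclose(tr.inverse().apply(m.vertices), mesh.vertices, atol=1e-9)

    def test_rigid_perturbations_within_stated_ranges(self, recovery_cohort):
        for tr in recovery_cohort.truth.transforms:
            assert tr.rotation_angle_deg() <= 30.0 + 1e-9
            assert np.linalg.norm(tr.translation) <= 50.0 + 1e-9


class TestMakePhasePair:
    def test_zero_strain_gives_identical_phases(self, tube_subject):
        mesh, cl = tube_subject
        dia, sys_, eps = make_phase_pair(mesh, 0.0, cl)
        assert np.array_equal(dia.vertices, sys_.vertices)
        assert np.all(eps == 0.0)

    def test_uniform_strain_scales_radius(self):
        cl = Centerline(np.column_stack([np.zeros(40), np.zeros(40), np.linspace(0, 80, 40)]))
        mesh = make_tube(cl, 10.0, 24)
        dia, sys_, eps = make_phase_pair(mesh, 0.1, cl)
        r_dia = np.linalg.norm(dia.vertices[:, :2], axis=1)
        r_sys = np.linalg.norm(sys_.vertices[:, :2], axis=1)
        assert np.allclose(r_sys, 1.1 * r_dia, rtol=1e-9)
        assert np.allclose(eps, 0.1)

    def test_gaussian_profile_true_strain_peaks_at_center(self, tube_subject):
        mesh, cl = tube_subject
        prof = lambda s: 0.15 * np.exp(-0.5 * ((s - 0.5) / 0.1) ** 2)
        _, _, eps = make_phase_pair(mesh, prof, cl)
        # max over discrete vertex stations sits one half-step off s=0.5
        assert abs(eps.max() - 0.15) < 1e-3

    def test_negative_strain_rejected(self, tube_subject):
        mesh, cl = tube_subject
        with pytest.raises(ValueError, match=">= 0"):
            make_phase_pair(mesh, lambda s: s - 0.5, cl)


class TestMakeCovariates:
    def test_null_link_prevalence_within_binomial_interval(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        meshes, truth = make_population(mesh, basis, (4, 2, 1), 200, seed=6,
                                        rigid_perturbation=False)
        beta0 = -1.0
        cohort = make_covariates(meshes, truth, logistic_beta=(beta0, 0, 0, 0),
                                 seed=7, measure=False)
        p = _sigmoid(np.array([beta0]))[0]
        prev = cohort.column("surgery").mean()
        half_width = 1.96 * np.sqrt(p * (1 - p) / 200)
        assert abs(prev - p) < half_width + 1e-12

    def test_strong_link_labels_deterministic_in_sign(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        meshes, truth = make_population(mesh, basis, (4, 2, 1), 60, seed=6,
                                        rigid_perturbation=False)
        cohort = make_covariates(meshes, truth, logistic_beta=(0, 1e6, 0, 0),
                                 seed=7, measure=False)
        labels = cohort.column("surgery").to_numpy().astype(bool)
        assert np.array_equal(labels, truth.weights[:, 0] > 0)

    def test_same_seed_identical_labels(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        meshes, truth = make_population(mesh, basis, (4, 2, 1), 40, seed=6,
                                        rigid_perturbation=False)
        c1 = make_covariates(meshes, truth, seed=9, measure=False)
        c2 = make_covariates(meshes, truth, seed=9, measure=False)
        assert c1.column("surgery").tolist() == c2.column("surgery").tolist()

    def test_beta_length_mismatch_rejected(self, tube_subject):
        mesh, cl = tube_subject
        basis = default_mode_basis(mesh, cl)
        meshes, truth = make_population(mesh, basis, (4, 2, 1), 5, seed=6)
        with pytest.raises(ValueError, match="intercept"):
            make_covariates(meshes, truth, logistic_beta=(0, 1), measure=False)


def test_simulate_cohort_bit_reproducible():
    a = simulate_cohort(n_ataa=6, seed=4, measure=False)
    b = simulate_cohort(n_ataa=6, seed=4, measure=False)
    for ma, mb in zip(a.meshes, b.meshes):
        assert np.array_equal(ma.vertices, mb.vertices)
    assert np.array_equal(a.truth.weights, b.truth.weights)


def test_measured_diameters_match_generator_profile(recovery_cohort):
    """Station diameters of the unperturbed template match its radius profile."""
    spec = ash.AortaSpec(seed=0)
    mesh, cl = ash.make_subject(spec, "t")
    prof = radius_profile_for(spec)
    # area-equivalent diameter of an elliptic section with semi-axes
    # r(1+e), r(1-e) is 2 r sqrt(1-e^2); the residual ~0.6% is the
    # inscribed-polygon area deficit at 24 circumferential vertices
    ellipse = np.sqrt(1.0 - spec.ellipticity**2)
    for st in (0.25, 0.5, 0.75):
        expected = 2.0 * prof(np.array([st]))[0] * ellipse
        measured = station_diameter(mesh, cl, st)
        assert abs(measured - expected) / expected < 0.01


def test_default_link_is_table_scale():
    """Default logistic link gives a realistic ~20% surgical prevalence."""
    sim = simulate_cohort(n_ataa=300, seed=12, measure=False)
    prev = sim.cohort.column("surgery").mean()
    assert 0.10 < prev < 0.35
    assert tuple(sim.truth.logistic_beta) == DEFAULT_LOGISTIC_BETA
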