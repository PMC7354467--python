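"""Statistics: oracle equivalences and null behavior."""

import numpy as np
import pandas as pd
import pytest

import aortashape as ash
from aortashape.errors import DegenerateInputError
from aortashape.pipeline import build_atlas_from_meshes
from aortashape.stats import (
    benjamini_hochberg,
    cluster_scores,
    compare_groups,
    correlate_modes,
    fit_risk_model,
    group_mode_summary,
    rank_auc,
    roc_curve,
)


class TestCorrelateModes:
    def test_pearson_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = 0.3 * x + rng.normal(size=10)
        table = correlate_modes(x[:, None], pd.DataFrame({"y": y}))
        r_bf = ((x - x.mean()) @ (y - y.mean())) / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert abs(table.r.iloc[0] - r_bf) < 1e-12

    def test_exact_linear_relation(self):
        x = np.arange(20.0)
        table = correlate_modes(x[:, None], pd.DataFrame({"d": 2 * x + 3}))
        assert abs(table.r.iloc[0] - 1.0) < 1e-12
        assert table.p.iloc[0] < 1e-30

    def test_independent_descriptor_near_zero(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            table = correlate_modes(x[:, None], pd.DataFrame({"y": y}))
            assert abs(table.r.iloc[0]) < 0.1

    def test_zero_variance_flagged_not_crashed(self):
        x = np.arange(10.0)
        table = correlate_modes(x[:, None], pd.DataFrame({"c": np.ones(10)}))
        assert bool(table.undefined.iloc[0])
        assert np.isnan(table.r.iloc[0])

    def test_pairwise_deletion_and_small_n_guard(self):
        x = np.arange(10.0)
        y = np.full(10, np.nan)
        y[:2] = [1.0, 2.0]
        with pytest.raises(DegenerateInputError, match=">= 3"):
            correlate_modes(x[:, None], pd.DataFrame({"y": y}))

    def test_tortuosity_mode_association(self):
        """A bow-deepening mode's atlas score tracks measured tortuosity."""
        sim = ash.simulate_cohort(
            n_ataa=80, seed=8, measure=True, rigid_perturbation=True,
            basis_kind="bend", spec=ash.AortaSpec(tortuosity_amplitude=1.5),
            mode_sds=(4, 2, 0.7),
        )
        atlas, _, _ = build_atlas_from_meshes(sim.meshes, sim.cohort, n_points=1500, seed=9)
        tort = sim.cohort.column("tortuosity").to_numpy()
        table = correlate_modes(atlas.scores[:, :3], pd.DataFrame({"tortuosity": tort}))
        by_mode = table.set_index("mode").r.abs()
        assert by_mode.loc[2] > 0.8
        assert by_mode.loc[2] == by_mode.max()


def test_benjamini_hochberg_monotone_stepup():
    adj = benjamini_hochberg([0.01, 0.04, 0.02])
    np.testing.assert_allclose(adj, [0.03, 0.04, 0.03])
    assert np.all(benjamini_hochberg([0.5, 0.9, 0.7]) <= 1.0)


class TestCompareGroups:
    def test_exact_mann_whitney_enumeration(self):
        u, p = compare_groups([1, 2], [3, 4])
        assert u == 0.0
        assert abs(p - 1.0 / 3.0) < 1e-12

    def test_identical_groups_p_one(self):
        _, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_chi_square_uniform_table(self):
        stat, p = compare_groups(np.array([[10, 10], [10, 10]]), kind="chi_square")
        assert stat == 0.0 and p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_groups([], [1, 2])

    def test_chi_square_low_counts_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            compare_groups(np.array([[0, 5], [3, 4]]), kind="chi_square")


class TestROC:
    def test_worked_four_point_example(self):
        """Pair enumeration: 3 wins of 4 positive-negative pairs = 0.75."""
        probs, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        fpr, tpr, thr, auc = roc_curve(probs, labels)
        assert auc == 0.75
        assert rank_auc(probs, labels) == 0.75
        assert fpr[0] == 0.0 and tpr[0] == 0.0 and fpr[-1] == 1.0 and tpr[-1] == 1.0

    def test_perfect_and_uninformative(self):
        assert roc_curve([0, 0, 1, 1], [0, 0, 1, 1])[3] == 1.0
        assert roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])[3] == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        probs = rng.random(60)
        labels = rng.random(60) < probs
        base = roc_curve(probs, labels)[3]
        assert abs(roc_curve(np.exp(3 * probs), labels)[3] - base) < 1e-12

    def test_roc_monotone_both_coordinates(self):
        rng = np.random.default_rng(6)
        probs = rng.random(40)
        labels = rng.random(40) < 0.4
        fpr, tpr, _, _ = roc_curve(probs, labels)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_trapezoid_equals_rank_sum_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            probs = rng.integers(0, 5, size=50) / 4.0  # heavy ties
            labels = rng.random(50) < 0.5
            if labels.all() or not labels.any():
                continue
            assert abs(roc_curve(probs, labels)[3] - rank_auc(probs, labels)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([0.2, 0.4], [1, 1])


class TestRiskModel:
    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        eta = -0.4 + X @ [0.7, -0.5, 0.3]
        y = rng.random(300) < 1 / (1 + np.exp(-eta))
        res = fit_risk_model(y, scores=X)
        ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        assert np.abs(np.r_[res.intercept, res.coefficients] - ref.params).max() < 1e-6
        assert res.gradient_norm < 1e-6
        assert not res.ridge_active

    def test_separated_labels_auc_one_with_guard(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 1))
        y = X[:, 0] > 0
        res = fit_risk_model(y, scores=X)
        assert res.auc == 1.0
        assert res.ridge_active

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        for seed in (0, 1, 2):
            y = np.random.default_rng(seed).permutation([True] * 100 + [False] * 100)
            res = fit_risk_model(y, scores=X)
            assert 0.4 < res.auc < 0.65  # in-sample fit inflates chance slightly

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_risk_model(np.ones(10, dtype=bool), scores=np.zeros((10, 1)))

    def test_diameter_baseline_path(self, recovery_cohort, recovery_atlas):
        atlas, _, _ = recovery_atlas
        y = recovery_cohort.cohort.column("surgery").to_numpy().astype(bool)
        m = fit_risk_model(
            y, diameter=recovery_cohort.cohort.column("diameter_midaa").to_numpy(),
            predictor="diameter",
        )
        assert m.n_predictors == 1
        assert 0.5 < m.auc <= 1.0


class TestClusterScores:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(5, 0.3, (30, 2))])
        res = cluster_scores(X, k=2, seed=0)
        truth = np.r_[np.zeros(30), np.ones(30)]
        agreement = max(
            (res.labels == truth).mean(), (res.labels == 1 - truth).mean()
        )
        assert agreement >= 0.95
        assert res.silhouette > 0.8

    def test_k_equals_n_degenerate(self):
        X = np.random.default_rng(5).normal(size=(6, 2))
        res = cluster_scores(X, k=6, seed=0)
        assert res.degenerate and np.isnan(res.silhouette)
        assert len(np.unique(res.labels)) == 6

    def test_same_seed_identical(self):
        X = np.random.default_rng(6).normal(size=(40, 2))
        a = cluster_scores(X, k=3, seed=1)
        b = cluster_scores(X, k=3, seed=1)
        assert np.array_equal(a.labels, b.labels)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cluster_scores(np.zeros((4, 2)), k=9, seed=0)

    def test_auto_picks_two_for_two_blobs(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.4, (25, 2)), rng.normal(6, 0.4, (25, 2))])
        res = cluster_scores(X, k="auto", seed=0)
        assert res.k == 2


class TestGroupModeSummary:
    def test_separated_groups_flagged_significant(self):
        rng = np.random.default_rng(0)
        scores = np.r_[rng.normal(0, 1, 20), rng.normal(1.0, 1, 20)]
        groups = ["control"] * 20 + ["ATAA"] * 20
        table = group_mode_summary(scores, groups)
        row = table.set_index("group").loc["ATAA"]
        assert row.p_vs_control < 0.05 and row.significant

    def test_identical_groups_no_stars(self):
        scores = np.r_[np.arange(10.0), np.arange(10.0)]
        groups = ["control"] * 10 + ["ATAA"] * 10
        table = group_mode_summary(scores, groups)
        assert not table.set_index("group").loc["ATAA"].significant

    def test_single_control_runs_with_wide_p(self):
        scores = np.r_[[0.0], np.random.default_rng(9).normal(2, 1, 8)]
        groups = ["control"] + ["ATAA"] * 8
        table = group_mode_summary(scores, groups)
        assert table.set_index("group").loc["ATAA"].p_vs_control > 0.01

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            group_mode_summary(np.arange(6.0), ["a"] * 3 + ["b"] * 3)

    def test_control_group_separates_on_size_mode(self):
        """Non-aneurysmal controls sit below the ATAA group on Mode 1."""
        sim = ash.simulate_cohort(n_ataa=20, n_control=20, seed=13, measure=False)
        atlas, _, _ = build_atlas_from_meshes(sim.meshes, None, n_points=1200, seed=14)
        groups = ["ATAA"] * 20 + ["control"] * 20
        table = group_mode_summary(atlas.scores[:, 0], groups)
        assert table.set_index("group").loc["ATAA"].significant
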