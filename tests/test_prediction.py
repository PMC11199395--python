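"""Feature assembly, family-grouped CV, LASSO/SGL fitting and stability."""

import numpy as np
import pandas as pd
import pytest

from tractokit import (
    TractProfileSet,
    accept_external_features,
    build_features,
    family_folds,
    fit_penalized_cv,
    make_profile_sets,
    repeat_cv,
    sgl_fit,
)
from tractokit.synthetic import default_family_sizes, make_phenotype


def features_with_signal(n_subjects=120, tracts=("A", "B", "C"),
                         metrics=("FA", "MD"), n_nodes=15, noise_sd=0.5,
                         seed=0):
    profs = make_profile_sets(n_subjects, list(tracts), list(metrics),
                              n_nodes, seed=seed)
    res = make_phenotype(profs, [(tracts[0], metrics[0])],
                         np.ones(n_nodes) / np.sqrt(n_nodes),
                         noise_sd=noise_sd, seed=seed + 1)
    fm = build_features(profs)
    fm.family_ids = res.table["family_id"].to_numpy()
    return fm, res.table["value"].to_numpy(), res


class TestBuildFeatures:
    def test_small_matrix_shape_and_groups(self):
        profs = make_profile_sets(4, ["A", "B"], ["FA"], 10, seed=0)
        fm = build_features(profs)
        assert fm.X.shape == (4, 20)
        assert len(fm.group_names) == 2
        assert np.array_equal(np.unique(fm.groups), [0, 1])

    def test_full_scale_feature_count(self):
        # 24 tracts x 4 metrics x 100 nodes -> 9,600 features in 96 groups
        profs = make_profile_sets(2, seed=1)
        fm = build_features(profs)
        assert fm.X.shape[1] == 9600
        assert len(fm.group_names) == 96

    def test_tract_major_order(self):
        profs = make_profile_sets(1, ["A", "B"], ["FA", "MD"], 3, seed=0)
        fm = build_features(profs)
        assert list(fm.feature_info["tract"][:6]) == ["A"] * 6
        assert list(fm.feature_info["metric"][:6]) == ["FA"] * 3 + ["MD"] * 3
        np.testing.assert_array_equal(
            fm.X[0], profs[0].values.reshape(-1)
        )

    def test_missing_values_imputed_by_feature_mean(self):
        profs = make_profile_sets(5, ["A"], ["FA"], 4, seed=0)
        profs[0].values[0, 0, 2] = np.nan
        fm = build_features(profs)
        others = np.stack([p.values[0, 0, 2] for p in profs[1:]])
        assert fm.X[0, 2] == pytest.approx(others.mean())

    def test_all_missing_subject_excluded(self, caplog):
        profs = make_profile_sets(4, ["A"], ["FA"], 4, seed=0)
        profs[2].values[:] = np.nan
        with caplog.at_level("WARNING"):
            fm = build_features(profs)
        assert fm.X.shape[0] == 3
        assert profs[2].subject_id not in fm.subject_ids

    def test_csv_roundtrip_preserves_order(self, tmp_path):
        from tractokit import profiles_from_csv, profiles_to_csv

        profs = make_profile_sets(3, ["A", "B"], ["FA"], 5, seed=2)
        profiles_to_csv(profs, tmp_path / "p.csv")
        back = profiles_from_csv(tmp_path / "p.csv")
        a, b = build_features(profs), build_features(back)
        np.testing.assert_allclose(a.X, b.X)
        assert a.subject_ids == b.subject_ids


class TestAcceptExternalFeatures:
    def test_reimported_matrix_equivalent(self, tmp_path):
        fm, y, _ = features_with_signal(n_subjects=40, seed=3)
        path = tmp_path / "x.csv"
        pd.DataFrame(fm.X).to_csv(path, index=False)
        ext = accept_external_features(str(path), fm.subject_ids,
                                       family_ids=fm.family_ids)
        a = fit_penalized_cv(fm, y, model="lasso", seed=0, n_lambda=10)
        b = fit_penalized_cv(ext, y, model="lasso", seed=0, n_lambda=10)
        assert a.r2 == pytest.approx(b.r2, abs=1e-10)

    def test_wide_matrix_accepted(self):
        X = np.random.default_rng(0).normal(size=(12, 5000))
        fm = accept_external_features(X, [f"s{i}" for i in range(12)])
        assert fm.n_features == 5000
        assert len(fm.group_names) == 1

    def test_subject_count_mismatch_rejected(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError, match="rows"):
            accept_external_features(X, ["a", "b", "c"])


class TestFamilyFolds:
    def test_families_never_split(self):
        fam = np.repeat(np.arange(40), np.random.default_rng(0).integers(
            1, 5, 40))
        folds = family_folds(fam, k=5, seed=3)
        for f in np.unique(fam):
            assert len(np.unique(folds[fam == f])) == 1

    def test_singletons_balanced(self):
        folds = family_folds(np.arange(10), k=5, seed=0)
        assert np.array_equal(np.bincount(folds), [2] * 5)

    def test_greedy_hand_derived_sizes(self):
        # family sizes {4,3,3,2,2,1,1}, k=2: greedy largest-first always
        # yields fold subject counts {8, 8}
        sizes = [4, 3, 3, 2, 2, 1, 1]
        fam = np.repeat(np.arange(len(sizes)), sizes)
        for seed in range(5):
            folds = family_folds(fam, k=2, seed=seed)
            assert sorted(np.bincount(folds)) == [8, 8]

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError, match="families"):
            family_folds(np.array([0, 0, 1, 1]), k=3)

    def test_reproducible(self):
        fam = np.repeat(np.arange(20), 2)
        np.testing.assert_array_equal(family_folds(fam, 5, seed=9),
                                      family_folds(fam, 5, seed=9))


class TestFitPenalizedCV:
    def test_noiseless_single_group_signal_recovered(self):
        fm, y, _ = features_with_signal(n_subjects=100, noise_sd=0.0, seed=4)
        res = fit_penalized_cv(fm, y, model="lasso", seed=0, n_lambda=30)
        assert res.r2 > 0.95

    def test_sgl_also_recovers_signal(self):
        fm, y, _ = features_with_signal(n_subjects=100, noise_sd=0.0, seed=5)
        res = fit_penalized_cv(fm, y, model="sgl", seed=0, n_lambda=30)
        assert res.r2 > 0.9

    def test_infinite_penalty_gives_zero_weights(self):
        fm, y, _ = features_with_signal(n_subjects=60, seed=6)
        from tractokit.prediction import _fit_path

        Z = (fm.X - fm.X.mean(0)) / np.where(fm.X.std(0) > 0, fm.X.std(0), 1)
        coefs = _fit_path(Z, y - y.mean(), np.array([1e9]), "lasso", None,
                          0.95, 1e-5, 1000)
        assert np.all(coefs == 0)

    def test_nonfinite_phenotype_rejected(self):
        fm, y, _ = features_with_signal(n_subjects=40, seed=7)
        y = y.copy()
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_penalized_cv(fm, y)

    def test_family_integrity_in_outer_folds(self):
        fm, y, _ = features_with_signal(n_subjects=80, seed=8)
        res = fit_penalized_cv(fm, y, model="lasso", seed=1, n_lambda=5)
        for fam in np.unique(fm.family_ids):
            assert len(np.unique(res.fold_assign[fm.family_ids == fam])) == 1

    def test_no_leakage_from_test_fold(self):
        """Standardization statistics depend only on training subjects."""
        fm, y, _ = features_with_signal(n_subjects=60, seed=9)
        base = fit_penalized_cv(fm, y, model="lasso", seed=2, n_lambda=5)
        test_rows = base.fold_assign == 0
        fm.X = fm.X.copy()
        fm.X[test_rows] += 1e3  # corrupt held-out subjects of fold 0
        perturbed = fit_penalized_cv(fm, y, model="lasso", seed=2, n_lambda=5)
        np.testing.assert_array_equal(base.scaler_means[0],
                                      perturbed.scaler_means[0])
        np.testing.assert_array_equal(base.scaler_stds[0],
                                      perturbed.scaler_stds[0])

    def test_sgl_single_group_alpha_one_equals_lasso(self):
        """Oracle equivalence of the in-package SGL solver with sklearn."""
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(10)
        X = rng.standard_normal((50, 12))
        X -= X.mean(0)
        y = X[:, 0] - 2 * X[:, 3] + 0.1 * rng.standard_normal(50)
        y -= y.mean()
        for lam in (0.02, 0.2, 1.0):
            ours = sgl_fit(X, y, lam, [np.arange(12)], alpha_mix=1.0,
                           tol=1e-12, max_iter=50_000)
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                        max_iter=200_000).fit(X, y).coef_
            np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_sgl_kills_whole_inactive_groups(self):
        fm, y, _ = features_with_signal(n_subjects=100, noise_sd=0.3, seed=11)
        res = fit_penalized_cv(fm, y, model="sgl", seed=0, n_lambda=20)
        w = np.abs(res.mean_weights)
        active = fm.groups == 0
        assert w[active].sum() > w[~active].sum()


class TestRepeatCV:
    def test_identical_seeds_identical_r2(self):
        fm, y, _ = features_with_signal(n_subjects=50, seed=12)
        res = repeat_cv(fm, y, model="lasso", seeds=[7, 7], n_lambda=5)
        assert res.r2_per_repeat[0] == res.r2_per_repeat[1]
        np.testing.assert_array_equal(res.weights_per_repeat[0],
                                      res.weights_per_repeat[1])
        assert res.weight_variance_summary == 0.0

    def test_weight_summaries_shapes(self):
        fm, y, _ = features_with_signal(n_subjects=50, seed=13)
        res = repeat_cv(fm, y, model="lasso", n_repeats=3, seed=1, n_lambda=5)
        p = fm.n_features
        assert res.mean_weights.shape == (p,)
        assert np.all(res.weight_ci_low <= res.weight_ci_high)
        assert res.results_dataframe().shape == (3, 2)
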