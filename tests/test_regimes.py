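"""Standardization, PCA, k-means, regime labeling and prevalence."""

import numpy as np
import pandas as pd
import pytest

from lesionfocus.regimes import (DEFAULT_FEATURES, cluster_summary,
                                 fit_regimes, kmeans_pc12, label_regimes,
                                 pca3, regime_prevalence,
                                 standardize_features)


def _table(n=30, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, len(DEFAULT_FEATURES))),
                      columns=DEFAULT_FEATURES)
    return df


class TestStandardize:
    def test_two_value_feature(self):
        df = pd.DataFrame({f: [0.0, 2.0] for f in DEFAULT_FEATURES})
        scaled, _ = standardize_features(df)
        np.testing.assert_allclose(scaled.values[:, 0], [-1.0, 1.0])

    def test_constant_feature_guarded_to_zero(self):
        df = _table(10)
        df["LP"] = 5.0
        scaled, _ = standardize_features(df)
        assert (scaled["LP"] == 0).all()

    def test_idempotent(self):
        df = _table(20)
        once, _ = standardize_features(df)
        twice, _ = standardize_features(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_rows_with_undefined_fc_excluded(self):
        df = _table(10)
        df.loc[3, "FC"] = np.nan
        scaled, params = standardize_features(df)
        assert len(scaled) == 9 and params["n_dropped"] == 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            standardize_features(_table(1))


class TestPCA3:
    def test_rank_one_data_aligns_pc1(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=200)
        # one varying axis, everything else constant (guarded to zeros)
        df = pd.DataFrame({f: (t if i == 0 else np.full(200, 5.0))
                           for i, f in enumerate(DEFAULT_FEATURES)})
        scaled, _ = standardize_features(df)
        loadings, scores, evr = pca3(scaled)
        assert evr[0] > 0.999
        assert abs(loadings[0, 0]) > 0.999  # PC1 is the varying axis

    def test_loadings_orthonormal(self):
        scaled, _ = standardize_features(_table(50))
        loadings, _, _ = pca3(scaled)
        np.testing.assert_allclose(loadings @ loadings.T, np.eye(3),
                                   atol=1e-8)

    def test_scores_uncorrelated(self):
        scaled, _ = standardize_features(_table(80))
        _, scores, _ = pca3(scaled)
        cov = np.cov(scores.values.T)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-8)

    def test_sign_convention_deterministic(self):
        scaled, _ = standardize_features(_table(40))
        loadings, _, _ = pca3(scaled)
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_explained_variance_sorted(self):
        scaled, _ = standardize_features(_table(60))
        _, _, evr = pca3(scaled)
        assert evr[0] >= evr[1] >= evr[2]


class TestKMeans:
    def test_planted_gaussians_recovered_exactly(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        pts = np.concatenate([rng.normal(c, 0.5, size=(40, 2))
                              for c in centers])
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"])
        assign, centroids = kmeans_pc12(scores, seed=0)
        truth = np.repeat([0, 1, 2], 40)
        # perfect recovery up to label permutation
        table = pd.crosstab(truth, assign.values)
        assert (table.max(axis=1) == 40).all()

    def test_centroids_are_cluster_means(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.normal(size=(30, 2)),
                              columns=["PC1", "PC2"])
        assign, centroids = kmeans_pc12(scores, seed=1)
        for cid in range(3):
            member_mean = scores.values[assign.values == cid].mean(axis=0)
            np.testing.assert_allclose(centroids[cid], member_mean, atol=1e-6)

    def test_deterministic_under_seed(self):
        scores = pd.DataFrame(np.random.default_rng(4).normal(size=(40, 2)),
                              columns=["PC1", "PC2"])
        a, _ = kmeans_pc12(scores, seed=9)
        b, _ = kmeans_pc12(scores, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_few_rows_rejected(self):
        scores = pd.DataFrame([[0.0, 0.0]], columns=["PC1", "PC2"])
        with pytest.raises(ValueError):
            kmeans_pc12(scores, k=3)


class TestLabelRegimes:
    def test_three_cluster_feature_means(self):
        # cluster means shaped like the published Pred-mode hole clusters
        means = pd.DataFrame(
            {"APIL20": [0.078, 0.020, 0.003],
             "ARIL20": [0.719, 0.758, 0.397],
             "COM_dist": [14.38, 6.24, 7.34]},
            index=[0, 1, 2])
        mapping = label_regimes(means)
        assert mapping == {0: "peri_lesion", 1: "retina_dominant",
                           2: "narrow_coverage"}

    def test_two_clusters_have_no_narrow_coverage(self):
        means = pd.DataFrame({"APIL20": [0.083, 0.017],
                              "ARIL20": [0.684, 0.659],
                              "COM_dist": [16.22, 7.84]}, index=[0, 1])
        mapping = label_regimes(means)
        assert mapping == {0: "peri_lesion", 1: "retina_dominant"}
        assert "narrow_coverage" not in mapping.values()

    def test_aril_tie_broken_by_lower_com_dist(self):
        means = pd.DataFrame({"APIL20": [0.9, 0.1, 0.1],
                              "ARIL20": [0.5, 0.4, 0.4],
                              "COM_dist": [5.0, 9.0, 3.0]}, index=[0, 1, 2])
        mapping = label_regimes(means)
        assert mapping[2] == "retina_dominant"
        assert mapping[1] == "narrow_coverage"


class TestPrevalenceAndSummary:
    def test_published_hole_pred_shares(self):
        assign = pd.Series([0] * 15 + [1] * 71 + [2] * 75)
        labels = {0: "narrow_coverage", 1: "peri_lesion", 2: "retina_dominant"}
        prev = regime_prevalence(assign, labels)
        assert prev == {"narrow_coverage": 9.3, "peri_lesion": 44.1,
                        "retina_dominant": 46.6}

    def test_published_cyst_gt_shares(self):
        assign = pd.Series([0] * 4 + [1] * 113 + [2] * 253)
        labels = {0: "narrow_coverage", 1: "peri_lesion", 2: "retina_dominant"}
        prev = regime_prevalence(assign, labels)
        assert prev["narrow_coverage"] == 1.1
        assert prev["peri_lesion"] == 30.5
        assert prev["retina_dominant"] == 68.4

    def test_equal_thirds(self):
        assign = pd.Series([0, 1, 2] * 10)
        labels = {0: "narrow_coverage", 1: "peri_lesion", 2: "retina_dominant"}
        assert set(regime_prevalence(assign, labels).values()) == {33.3}

    def test_single_row_cluster_summary_equals_row(self):
        df = _table(3)
        assign = pd.Series([0, 1, 2], index=df.index)
        summary = cluster_summary(df, assign)
        np.testing.assert_allclose(summary.loc[1, list(DEFAULT_FEATURES)],
                                   df.loc[1, list(DEFAULT_FEATURES)])

    def test_summary_mean_leakage_identity(self, regime_data):
        _, table = regime_data
        model = fit_regimes(table, seed=3)
        for _, row in model.summary.iterrows():
            assert row["Leak20"] == pytest.approx(1 - row["APIL20"],
                                                  abs=1e-9)


class TestEndToEnd:
    def test_planted_regimes_recovered(self, regime_data):
        _, table = regime_data
        model = fit_regimes(table, seed=3)
        predicted = model.regime_of()
        planted = table.loc[predicted.index, "planted"]
        assert (predicted.values == planted.values).mean() >= 0.90

    def test_row_permutation_changes_nothing_but_order(self, regime_data):
        _, table = regime_data
        rng = np.random.default_rng(5)
        shuffled = table.sample(frac=1.0, random_state=7)
        a = fit_regimes(table, seed=3)
        b = fit_regimes(shuffled, seed=3)
        pred_a = a.regime_of()
        pred_b = b.regime_of().reindex(pred_a.index)
        assert (pred_a == pred_b).all()
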