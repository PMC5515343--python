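import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from fieldscape.io_formats import FieldscapeValidationError, MatrixTable
from fieldscape.expression import (
    assign_subtype,
    assign_subtypes,
    cluster_concordance,
    consensus_cluster,
    derive_centroids,
    filter_differential,
    filter_expressed_mirs,
    nmf_factorize,
    nmf_labels,
    rpm_normalize,
    row_scaled_log_rpm,
    sam_wilcoxon,
    select_variable_features,
    silhouette_from_consensus,
    upper_quartile_normalize,
)


def table(values, kind="count", prefix="f"):
    values = np.asarray(values, dtype=float)
    return MatrixTable(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"s{i}" for i in range(values.shape[1])],
        ),
        kind,
    )


def two_cluster_counts(rng, n_features=120, n_per=15, effect=2.0):
    base = rng.uniform(4, 8, n_features)
    shift = np.zeros(n_features)
    shift[: n_features // 10] = effect
    lam1 = np.exp2(base)[:, None] * np.ones(n_per)
    lam2 = np.exp2(base + shift)[:, None] * np.ones(n_per)
    counts = np.hstack([rng.poisson(lam1), rng.poisson(lam2)]).astype(float)
    labels = np.array([1] * n_per + [2] * n_per)
    return table(counts), labels


class TestNormalization:
    def test_upper_quartile_divisor_over_nonzero_values(self):
        t = table([[4], [8], [12], [16], [0]])
        out = upper_quartile_normalize(t)
        uq = np.percentile([4, 8, 12, 16], 75)
        np.testing.assert_allclose(out.values["s0"], np.array([4, 8, 12, 16, 0]) / uq * uq)

    def test_scalar_multiples_become_identical(self, rng):
        col = rng.poisson(50, 30).astype(float) + 1
        t = table(np.column_stack([col, 3 * col]))
        out = upper_quartile_normalize(t).values
        np.testing.assert_allclose(out["s0"], out["s1"], rtol=1e-12)

    def test_normalized_upper_quartiles_equal_across_samples(self, rng):
        t = table(rng.poisson(40, (50, 6)).astype(float) + 1)
        out = upper_quartile_normalize(t).values
        uqs = [np.percentile(out[c][out[c] > 0], 75) for c in out.columns]
        np.testing.assert_allclose(uqs, uqs[0], rtol=1e-12)

    def test_all_zero_sample_errors(self):
        with pytest.raises(FieldscapeValidationError, match="s1"):
            upper_quartile_normalize(table([[1, 0], [2, 0]]))

    def test_rpm_columns_sum_to_one_million(self, rng):
        t = table(rng.poisson(30, (20, 4)).astype(float) + 1)
        out = rpm_normalize(t)
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-12)
        assert out.value_kind == "rpm"

    def test_zero_count_feature_stays_zero(self):
        out = rpm_normalize(table([[0, 0], [10, 20]]))
        assert (out.values.iloc[0] == 0).all()


class TestFeatureFilters:
    def test_expression_floor_boundary(self):
        vals = np.zeros((2, 12))
        vals[0, :10] = 5.0  # in exactly 10 libraries -> kept
        vals[1, :9] = 5.0   # 9 libraries -> dropped
        out = filter_expressed_mirs(table(vals, "rpm"), min_mean_rpm=1, min_libraries=10)
        assert out.feature_ids == ["f0"]

    def test_survivors_equal_row_scan_oracle(self, rng):
        vals = rng.uniform(0, 3, (80, 20))
        out = filter_expressed_mirs(table(vals, "rpm"), min_mean_rpm=1, min_libraries=5)
        expected = [f"f{i}" for i in range(80) if (vals[i] >= 1).sum() >= 5]
        assert out.feature_ids == expected

    def test_variable_features_full_sort_oracle(self, rng):
        vals = rng.uniform(0, 10, (60, 8))
        t = table(vals)
        got = select_variable_features(t, n=15)
        var = t.values.var(axis=1, ddof=1)
        expected = sorted(t.feature_ids, key=lambda f: (-var[f], f))[:15]
        assert got == expected
        assert len(select_variable_features(t, fraction=0.25)) == 15

    def test_constant_feature_never_selected(self, rng):
        vals = rng.uniform(0, 10, (10, 6))
        vals[3] = 7.0
        got = select_variable_features(table(vals), n=9)
        assert "f3" not in got


class TestNMF:
    def test_rank_one_matrix_reconstructs_exactly(self, rng):
        V = np.outer(rng.uniform(1, 2, 20), rng.uniform(1, 2, 8))
        W, H, trace = nmf_factorize(V, k=1, seed=0, max_iter=5000, tol=1e-14)
        np.testing.assert_allclose(W @ H, V, rtol=1e-4)

    def test_kl_objective_monotone_nonincreasing(self, rng):
        V = rng.uniform(0, 5, (30, 12))
        _, _, trace = nmf_factorize(V, k=3, seed=1, max_iter=300, tol=0.0)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_block_diagonal_recovery(self, rng):
        V = np.zeros((40, 20))
        V[:20, :10] = rng.uniform(5, 10, (20, 10))
        V[20:, 10:] = rng.uniform(5, 10, (20, 10))
        _, H, _ = nmf_factorize(V, k=2, seed=0)
        labels = nmf_labels(H)
        truth = np.array([0] * 10 + [1] * 10)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_out_of_range_errors(self, rng):
        with pytest.raises(FieldscapeValidationError, match="out of range"):
            nmf_factorize(rng.uniform(0, 1, (5, 4)), k=5, seed=0)

    def test_agrees_with_sklearn_kl_nmf_objective(self, rng):
        """Cross-check the final KL objective against sklearn's MU solver."""
        from sklearn.decomposition import NMF

        V = rng.uniform(0.5, 5, (40, 16))
        _, _, trace = nmf_factorize(V, k=3, seed=2, max_iter=3000, tol=1e-10)
        skl = NMF(n_components=3, solver="mu", beta_loss="kullback-leibler",
                  init="random", random_state=2, max_iter=3000, tol=1e-10)
        Ws = skl.fit_transform(V)
        WH = Ws @ skl.components_
        mask = V > 0
        kl_skl = float(np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum())
        assert trace[-1] == pytest.approx(kl_skl, rel=0.02)


class TestConsensus:
    def test_two_separated_clusters_recovered(self, rng):
        t, truth = two_cluster_counts(rng)
        res = consensus_cluster(t, k=2, n_runs=20, seed=0)
        assert adjusted_rand_score(truth, res.assignments) == 1.0
        consensus = res.consensus_matrix.to_numpy()
        assert np.all((consensus > 0.95) | (consensus < 0.05))

    def test_consensus_symmetric_unit_diagonal(self, rng):
        t, _ = two_cluster_counts(rng, n_features=40, n_per=6)
        res = consensus_cluster(t, k=2, n_runs=10, seed=1)
        c = res.consensus_matrix.to_numpy()
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_deterministic_given_seed(self, rng):
        t, _ = two_cluster_counts(rng, n_features=40, n_per=6)
        r1 = consensus_cluster(t, k=2, n_runs=10, seed=7)
        r2 = consensus_cluster(t, k=2, n_runs=10, seed=7)
        pd.testing.assert_frame_equal(r1.consensus_matrix, r2.consensus_matrix)
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)

    def test_sample_shuffle_equivariance(self, rng):
        t, _ = two_cluster_counts(rng, n_features=40, n_per=6)
        perm = rng.permutation(t.sample_ids)
        t_perm = MatrixTable(t.values[perm], t.value_kind)
        r1 = consensus_cluster(t, k=2, n_runs=15, seed=3)
        r2 = consensus_cluster(t_perm, k=2, n_runs=15, seed=3)
        # consensus entries are about sample pairs: compare on aligned ids
        c1 = r1.consensus_matrix.loc[perm, perm].to_numpy()
        c2 = r2.consensus_matrix.to_numpy()
        # restarts consume seeds identically; only sample order changed
        assert np.mean(np.abs(c1 - c2)) < 0.2
        assert adjusted_rand_score(
            r1.assignments[perm].to_numpy(), r2.assignments.to_numpy()
        ) == 1.0


class TestRankSurvey:
    def test_survey_prefers_the_planted_two_clusters(self, rng):
        from fieldscape.expression import rank_survey

        t, _ = two_cluster_counts(rng, n_features=60, n_per=10)
        survey = rank_survey(t, k_range=range(2, 5), n_runs=8, seed=0)
        assert list(survey.index) == [2, 3, 4]
        assert survey["mean_silhouette"].idxmax() == 2
        assert survey.loc[2, "consensus_dispersion"] > survey.loc[3, "consensus_dispersion"]


class TestSilhouette:
    def test_perfect_block_consensus_gives_width_one(self):
        c = np.zeros((6, 6))
        c[:3, :3] = 1.0
        c[3:, 3:] = 1.0
        cdf = pd.DataFrame(c, index=list("abcdef"), columns=list("abcdef"))
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"))
        widths = silhouette_from_consensus(cdf, labels)
        np.testing.assert_allclose(widths, 1.0)

    def test_ambiguous_sample_has_zero_width(self):
        c = np.eye(5)
        c[:2, :2] = 1.0
        c[3:, 3:] = 1.0
        c[2, :] = c[:, 2] = 0.5
        c[2, 2] = 1.0
        cdf = pd.DataFrame(c, index=list("abcde"), columns=list("abcde"))
        labels = pd.Series([1, 1, 1, 2, 2], index=list("abcde"))
        widths = silhouette_from_consensus(cdf, labels)
        assert widths["c"] == pytest.approx(0.0)

    def test_matches_sklearn_on_random_consensus(self, rng):
        n = 12
        raw = rng.uniform(0, 1, (n, n))
        c = (raw + raw.T) / 2
        np.fill_diagonal(c, 1.0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(rng.integers(1, 4, n), index=ids)
        if labels.nunique() < 2:
            labels.iloc[0] = labels.iloc[0] % 3 + 1
        widths = silhouette_from_consensus(pd.DataFrame(c, index=ids, columns=ids), labels)
        counts = labels.value_counts()
        expected = silhouette_samples(1 - c, labels.to_numpy(), metric="precomputed")
        for i, s in enumerate(ids):
            if counts[labels[s]] == 1:
                assert widths[s] == 0.0
            else:
                assert widths[s] == pytest.approx(expected[i], abs=1e-12)


class TestSamWilcoxon:
    def test_rank_preserving_transform_leaves_statistics_unchanged(self, rng):
        X = rng.normal(0, 1, (30, 12))
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=[f"s{i}" for i in range(12)])
        r1 = sam_wilcoxon(table(X, "log_scaled"), labels, n_perms=50, seed=0)
        r2 = sam_wilcoxon(table(np.exp(X), "log_scaled"), labels, n_perms=50, seed=0)
        np.testing.assert_allclose(r1["statistic"], r2["statistic"], atol=1e-12)

    def test_shifted_feature_attains_extreme_statistic(self, rng):
        X = rng.normal(0, 1, (200, 20))
        X[0, 10:] += 5.0
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=[f"s{i}" for i in range(20)])
        res = sam_wilcoxon(table(X, "log_scaled"), labels, n_perms=300, seed=1)
        assert res["statistic"].abs().idxmax() == "f0"
        assert res.loc["f0", "q_value"] < 0.05

    def test_small_cohorts_enumerate_all_label_splits(self, rng):
        X = rng.normal(0, 1, (20, 6))
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)])
        res = sam_wilcoxon(table(X, "log_scaled"), labels, n_perms=1000, seed=0)
        assert res["q_value"].between(0, 1).all()

    def test_class_size_validation(self, rng):
        X = rng.normal(0, 1, (5, 4))
        labels = pd.Series(["a", "b", "b", "b"], index=[f"s{i}" for i in range(4)])
        with pytest.raises(FieldscapeValidationError, match=">= 2 samples"):
            sam_wilcoxon(table(X, "log_scaled"), labels)


class TestDifferentialFilter:
    def frame(self):
        return pd.DataFrame(
            {
                "statistic": [3, -3, 3, 3],
                "q_value": [0.01, 0.01, 0.2, 0.01],
                "mean_rpm_c1": [30.0, 3.0, 40.0, 3.0],
                "mean_rpm_c2": [60.0, 30.0, 80.0, 4.0],
                "fold_change": [2.0, -1.4, 2.0, 2.0],
            },
            index=["keep", "low_fc", "high_q", "low_rpm"],
        )

    def test_filter_rules(self):
        out, top = filter_differential(self.frame())
        assert list(out.index[out["passes_filters"]]) == ["keep"]

    def test_rpm_in_at_least_one_cluster_suffices(self):
        df = self.frame().loc[["low_fc"]].assign(fold_change=2.0)
        out, _ = filter_differential(df)
        assert out["passes_filters"].all()  # 30 RPM in cluster 2 only

    def test_passers_equal_predicate_scan(self, rng):
        df = pd.DataFrame(
            {
                "statistic": rng.normal(size=50),
                "q_value": rng.uniform(0, 0.1, 50),
                "mean_rpm_c1": rng.uniform(0, 50, 50),
                "mean_rpm_c2": rng.uniform(0, 50, 50),
                "fold_change": rng.uniform(-3, 3, 50),
            },
            index=[f"f{i}" for i in range(50)],
        )
        out, _ = filter_differential(df)
        expected = [
            f for f in df.index
            if df.loc[f, "q_value"] < 0.05
            and abs(df.loc[f, "fold_change"]) >= 1.5
            and max(df.loc[f, "mean_rpm_c1"], df.loc[f, "mean_rpm_c2"]) >= 25
        ]
        assert list(out.index[out["passes_filters"]]) == expected


class TestSubtypesAndConcordance:
    def test_sample_equal_to_centroid(self, rng):
        feats = [f"g{i}" for i in range(20)]
        centroids = pd.DataFrame(
            {"active": rng.uniform(0, 10, 20), "inactive": rng.uniform(0, 10, 20)},
            index=feats,
        )
        sample = centroids["active"].rename("s1")
        call = assign_subtype(sample, centroids, distance="euclidean")
        assert call.subtype == "active"
        assert call.distances["active"] == pytest.approx(0.0)

    def test_equidistant_tie_breaks_lexicographically(self):
        centroids = pd.DataFrame({"b": [1.0, 0.0], "a": [0.0, 1.0]}, index=["g1", "g2"])
        sample = pd.Series([0.5, 0.5], index=["g1", "g2"], name="s")
        call = assign_subtype(sample, centroids, distance="euclidean")
        assert call.subtype == "a"
        assert call.tied

    def test_missing_centroid_features_error(self, rng):
        centroids = pd.DataFrame({"a": rng.uniform(0, 1, 10), "b": rng.uniform(0, 1, 10)},
                                 index=[f"g{i}" for i in range(10)])
        sample = pd.Series([1.0, 2.0], index=["g0", "g1"], name="s")
        with pytest.raises(FieldscapeValidationError, match="centroid features"):
            assign_subtype(sample, centroids)

    def test_self_derived_centroids_recover_subtypes(self, rng):
        t, truth = two_cluster_counts(rng, n_features=200, n_per=20, effect=1.0)
        assignments = pd.Series(truth, index=t.sample_ids)
        centroids = derive_centroids(t, assignments, {1: "inactive", 2: "active"})
        calls = assign_subtypes(t, centroids)
        expected = np.where(truth == 2, "active", "inactive")
        assert (calls["subtype"].to_numpy() == expected).mean() >= 0.95

    def test_concordance_label_permutation_invariant(self):
        a = pd.Series([1, 1, 2, 2], index=list("wxyz"))
        assert cluster_concordance(a, a) == 1.0
        assert cluster_concordance(a, a.map({1: 2, 2: 1})) == 1.0
        b = pd.Series([1, 2, 2, 2], index=list("wxyz"))
        assert cluster_concordance(a, b) == 0.75

    def test_row_scaled_export_is_standardized(self, rng):
        t = table(rng.poisson(100, (30, 8)).astype(float), "rpm")
        out = row_scaled_log_rpm(t)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, rtol=1e-9)
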